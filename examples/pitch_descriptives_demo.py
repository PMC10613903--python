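"""Pitch descriptives of a synthetic spoken phrase at two smoothing levels.

Prints the median (octaves above C0 = 16 Hz), range (octaves), mean
absolute slope (octaves/s) and inflections per second, computed on the
contour after 10 Hz smoothing (keeps vibrato-rate modulation) and 1 Hz
smoothing (keeps only slow intonation). Inflections use the 20-cent
hysteresis rule, so tiny wobbles are not counted.
"""

import numpy as np

import vocaldomains as vd
from vocaldomains.pitch import descriptives_by_cutoff

rng = np.random.default_rng(0)
spec = vd.draw_voice_spec("Neutral speech", "f", rng)
wave, truth = vd.synthesize(spec)

contour = vd.track_f0(wave, spec.sample_rate, f0_min=60, f0_max=1200)
for cutoff, d in descriptives_by_cutoff(contour).items():
    print(f"cutoff {cutoff:>4.0f} Hz:  median {d.median_oct:.2f} oct ({d.median_hz:.0f} Hz),"
          f" range {d.range_oct:.2f} oct, slope {d.slope_abs:.2f} oct/s,"
          f" inflections {d.inflections_per_s:.2f} /s")
tv = truth.f0_contour
print(f"ground-truth median: {np.median(tv.f0[tv.voiced]):.0f} Hz")
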