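"""Synthesize the laugh-like demonstration sound and recover its parameters.

The sound has six syllables with f0 rising 100 -> 300 Hz in each, static
equidistant formants from 500 Hz, and 40 Hz amplitude modulation on the
last two syllables. The analysis modules should read all three numbers
back from the audio alone.
"""

import numpy as np

import vocaldomains as vd
from vocaldomains.modspec import PRESETS

SR = 16000

wave, truth = vd.make_fig3_demo(seed=1)

contour = vd.track_f0(wave, SR, f0_min=75, f0_max=600)
print(f"tracked f0 range: {contour.f0[contour.voiced].min():.1f}"
      f" - {contour.f0[contour.voiced].max():.1f} Hz (truth: 100 - 300 Hz)")

m = vd.measure_formants(wave, SR, region=(0.02, 0.23))
print("measured formants:", ", ".join(f"{f:.0f}" for f in m.F),
      "Hz (truth: 500, 1500, 2500, 3500)")

a0, a1 = truth.segments["am"][0]
ms = vd.modulation_spectrum(vd.spectrogram(wave[int(a0 * SR):int(a1 * SR)], SR,
                                           *PRESETS["roughness"]))
sel = ms.temporal_hz > 20
i, j = np.unravel_index(np.argmax(ms.magnitude[:, sel]), ms.magnitude[:, sel].shape)
print(f"temporal-modulation peak above 20 Hz: {ms.temporal_hz[sel][j]:.1f} Hz (truth: 40 Hz)")
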