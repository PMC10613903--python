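"""Apparent vocal-tract length and formant normalization.

Under the quarter-wave tube model, formants sit at (2i-1)c/(4L); the
regression method recovers L from measured formants, and scaling by
L / 17 cm removes speaker size from the vowel space.
"""

import vocaldomains as vd
from vocaldomains.formants import FormantMeasurement

for label, F in [
    ("ideal 17.5 cm tube  ", [500.0, 1500.0, 2500.0, 3500.0]),
    ("small speaker       ", [700.0, 2100.0, 3500.0, 4900.0]),
    ("open vowel, male    ", [700.0, 1300.0, 2500.0, 3500.0]),
]:
    vtl = vd.estimate_vtl(F)
    nv = vd.normalize_formants(FormantMeasurement(region=(0, 1), F=F), vtl)
    print(f"{label} F1-F4 = {F}  ->  VTL {vtl.length_cm:.2f} cm,"
          f"  normalized F1/F2 = {nv.F1n:.0f}/{nv.F2n:.0f} Hz")

print("\nAfter normalization, speakers of different sizes producing the same"
      "\nvowel land on the same point of the F1/F2 plane.")
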