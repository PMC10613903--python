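"""Fit the zero-one-inflated beta model to affected-frame proportions.

Most recordings contain no amplitude modulation at all (exact zeros), some
are partly affected (a value in (0,1)), and a few are modulated
throughout (exact ones) - the zero-one-inflated beta captures this with
zoi (probability of an inflated 0/1 value), coi (probability that an
inflated value is 1), and a beta(mu, phi) for the rest.
"""

import numpy as np

import vocaldomains as vd
from vocaldomains.nonlinear import ZOIBParams, fit_zoib, simulate_zoib

true = ZOIBParams(zoi=0.55, coi=0.05, mu=0.25, phi=6.0)
values = simulate_zoib(true, 500, seed=3)
print(f"simulated 500 proportions: {np.mean(values == 0):.0%} zeros,"
      f" {np.mean(values == 1):.0%} ones, mean of the rest"
      f" {values[(values > 0) & (values < 1)].mean():.3f}")

(params, loglik, converged), = fit_zoib(values).values()
print(f"fitted: zoi={params.zoi:.3f} (true {true.zoi}), coi={params.coi:.3f}"
      f" (true {true.coi}), mu={params.mu:.3f} (true {true.mu}),"
      f" phi={params.phi:.2f} (true {true.phi}); loglik={loglik:.1f}")
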