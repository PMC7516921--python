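"""Least-squares fitting of the three model families.

Fits noiseless data generated from known parameters and prints the
recovered values: the polynomial solve is exact (linear in parameters);
the exponential and power-law fits use damped least squares with a
seeded multi-start grid.
"""

import numpy as np

from gofselect import Dataset, ModelSpec, evaluate_model, fit_model

rng = np.random.default_rng(3)
x = rng.uniform(0.1, 10, 400)

cases = [
    ("power_law", {"c": 1.0, "a": 3.0, "b": -1.0}, rng.uniform(0.5, 10, 400)),
    ("exponential", {"a": 2.0, "b": -0.5, "c": 0.1, "d": -1.0, "e": -0.3,
                     "f": 0.2, "g": 5.0}, rng.uniform(-10, 10, 400)),
    ("polynomial", {"p00": 1.0, "p10": 2.0, "p20": 0.5, "p01": -1.0,
                    "p02": 0.3, "p03": 0.1, "p11": -0.2, "p21": 0.05,
                    "p12": 0.02}, rng.uniform(-10, 10, 400)),
]

for family, params, y in cases:
    truth = ModelSpec(family, params)
    data = Dataset(x, y, evaluate_model(truth, x, y))
    fit = fit_model(family, data, seed=0)
    err = np.max(np.abs(fit.theta - truth.theta))
    print(f"{family:<12} max |fitted - true| = {err:.2e} "
          f"(converged={fit.converged})")

# On noiseless data each family recovers its generating parameters to
# numerical precision, so any later criterion differences come from the
# noise model, not from optimiser failure.
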