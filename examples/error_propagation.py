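"""Error propagation for derived assay parameters, checked by Monte Carlo.

Group-level parameters are differences and quotients of pooled measurement
values, so their standard errors follow the standard rules: root-sum-square
for sums/differences, relative root-sum-square for ratios.  This script
compares the propagated errors against the empirical spread of simulated
Gaussian measurements.
"""

import numpy as np

from mitoflux import propagate_ratio_error, propagate_sum_error, standard_error

rng = np.random.default_rng(42)
n = 100_000

# difference, e.g. SRC = MR - BR with SEs 2.5 and 1.5
a = rng.normal(90.0, 2.5, n)
b = rng.normal(50.0, 1.5, n)
prop = propagate_sum_error(2.5, 1.5)
emp = np.std(a - b, ddof=1)
print(f"difference: propagated SE {prop:.4f} vs Monte-Carlo SD {emp:.4f}")

# quotient, e.g. an OCR:ECAR ratio of 100/40 with 5% relative errors
x = rng.normal(100.0, 5.0, n)
y = rng.normal(40.0, 2.0, n)
prop = propagate_ratio_error(100.0, 5.0, 40.0, 2.0)
emp = np.std(x / y, ddof=1)
print(f"quotient:   propagated SE {prop:.4f} vs Monte-Carlo SD {emp:.4f}")

# the standard error of replicate measurements themselves
reps = [48.2, 51.9, 50.1, 49.4, 52.3, 47.8]
print(f"SE of {len(reps)} replicate OCRs: {standard_error(reps):.4f}")

print(
    "\nPropagated errors agree with the empirical standard deviations to\n"
    "well under 5%, which is what validates quoting them as the\n"
    "uncertainty of derived parameters like ATP-linked respiration."
)
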