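"""The Gini coefficient of an expression profile, three ways.

Builds tiny profiles by hand, computes the Gini coefficient with the
sorted-rank formula, the O(n^2) pairwise definition and the Lorenz-curve
trapezoid, and shows they agree.  A Gini of 0 means a gene is expressed at
the same TPM in every sample; values near (n-1)/n mean a single sample
carries essentially all the expression.
"""

import numpy as np

from genegini import gini, gini_from_lorenz, gini_pairwise, lorenz_curve

profiles = {
    "uniform housekeeping-like": [100.0, 100.0, 100.0, 100.0],
    "mildly variable": [1.0, 2.0, 3.0, 4.0],
    "half-on half-off": [0.0, 0.0, 1.0, 1.0],
    "one-hot tissue-specific": [0.0, 0.0, 0.0, 10.0],
}

for name, profile in profiles.items():
    g = gini(profile)
    print(f"{name:28s} gini={g:.4f} "
          f"(pairwise {gini_pairwise(profile):.4f}, "
          f"lorenz {gini_from_lorenz(lorenz_curve(profile)):.4f})")

# a realistic single-tissue transporter: 58 tissues at ~1 TPM, one at 1000
profile = np.ones(59)
profile[0] = 1000.0
print(f"\n58x background + 1 dominant tissue: gini={gini(profile):.4f} "
      f"(the n=59 one-hot ceiling is {58 / 59:.4f})")
print("The curve points below are (fraction of samples, fraction of total TPM):")
curve = lorenz_curve([0.0, 0.0, 1.0, 3.0])
for p, e in curve.points:
    print(f"  ({p:.2f}, {e:.2f})")
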