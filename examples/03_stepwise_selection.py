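"""Stepwise F-test feature selection with planted signal.

Builds a response driven by 3 of 20 noise features and shows that the
stepwise filter (entry p < 0.01, exit p > 0.02) recovers exactly those
columns, reporting the admission history.
"""

import numpy as np

from hrctex import stepwise_select

rng = np.random.default_rng(7)
X = rng.standard_normal((300, 20))
y = X[:, 2] + 0.8 * X[:, 7] + 0.6 * X[:, 11] + rng.standard_normal(300)

res = stepwise_select(X, y)
print("selected columns:", res.selected)
print("step history:")
for action, j, p in res.history:
    print(f"  {action:6s} column {j:2d}   p = {p:.3g}")
print("final p-values:", {j: f"{p:.2g}" for j, p in res.p_values.items()})
print(
    "\nThe three planted predictors (columns 2, 7, 11) enter in order of"
    "\nstrength; pure-noise columns stay out at the 0.01 entrance tolerance."
)
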