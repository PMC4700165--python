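"""Multiscale differential-lacunarity curves per lung pattern.

Averages normalized DLac curves (box r = 4, windows w = 5..35) over 15
phantom patches of each class and prints the curve values at a few
scales.  Higher values mean stronger gap structure at that scale.
"""

import numpy as np

from hrctex import DlacConfig, dlac_curve
from hrctex.phantoms import CLASS_SPECS, generate_patch

cfg = DlacConfig()  # r=4, w=5..35, Hounsfield scale [-1000, 1000], normalized
show_w = (6, 10, 20, 35)

print("mean normalized DLac curve value at window side w")
print("class " + "".join(f"  w={w:<5d}" for w in show_w))
for label in ("NOR", "GG", "HC", "EMP"):
    curves = np.array([
        dlac_curve(generate_patch(CLASS_SPECS[label], seed), cfg).lam
        for seed in range(15)
    ])
    mean = curves.mean(axis=0)
    row = {w: mean[cfg.w_range.index(w)] for w in show_w}
    print(f"{label:5s} " + "".join(f"  {row[w]:7.4f}" for w in show_w))

print(
    "\nEvery curve equals 1 at the smallest window by normalization; how"
    "\nfast it falls with scale separates the patterns: emphysema and normal"
    "\nparenchyma average out quickly over large windows, while honeycombing"
    "\ncysts/walls and the ground-glass haze retain relative heterogeneity."
)
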