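"""Contingency-table performance metrics.

The classifier is scored through an actual-vs-predicted count matrix
``A`` with ``A[i, j]`` the number of instances of true class ``i``
predicted as class ``j``.  Per-class sensitivity, precision and
specificity and the overall accuracy derive from it:

    sensitivity_i = a_ii / row_i          (recall of class i)
    precision_i   = a_ii / col_i          (correctness of predictions i)
    specificity_i = TN_i / (TN_i + FP_i)  (recall of "not class i")
    accuracy      = trace(A) / total

Ratios with a zero denominator (a class absent from the truth or never
predicted) are reported as NaN rather than 0, so aggregation can treat
them as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencyTable", "contingency", "metrics"]


@dataclass(frozen=True)
class ContingencyTable:
    """n x n counts of actual (rows) vs predicted (columns) class."""

    A: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] != len(self.classes):
            raise ValueError("table must be square and match the class list")
        if np.any(A < 0) or not np.issubdtype(A.dtype, np.integer):
            raise ValueError("table entries must be non-negative integers")
        object.__setattr__(self, "A", A)

    @property
    def total(self) -> int:
        return int(self.A.sum())


def contingency(y_true, y_pred, classes) -> ContingencyTable:
    """Count actual-vs-predicted pairs into a contingency table."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = tuple(classes)
    index = {c: k for k, c in enumerate(classes)}
    n = len(classes)
    A = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the declared classes: {t!r}/{p!r}")
        A[index[t], index[p]] += 1
    return ContingencyTable(A=A, classes=classes)


def metrics(table: ContingencyTable) -> dict:
    """Per-class sensitivity/precision/specificity and overall accuracy."""
    A = table.A.astype(float)
    total = A.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    rows = A.sum(axis=1)
    cols = A.sum(axis=0)
    diag = np.diag(A)
    tn = total - rows - cols + diag
    fp = cols - diag

    def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    sens = _ratio(diag, rows)
    prec = _ratio(diag, cols)
    spec = _ratio(tn, tn + fp)
    return {
        "overall_accuracy": float(diag.sum() / total),
        "per_class": {
            c: {
                "sensitivity": float(sens[k]),
                "precision": float(prec[k]),
                "specificity": float(spec[k]),
            }
            for k, c in enumerate(table.classes)
        },
    }
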