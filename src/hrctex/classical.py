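"""Classical statistical texture analysis of quantized patches.

Three families of descriptors, all computed on a patch quantized to L gray
levels:

* first-order statistics of the normalized gray-level histogram;
* second-order co-occurrence statistics (spatial gray-level dependence
  method, SGLDM) from symmetric pixel-pair matrices at distance d = 1 in
  the four canonical directions;
* run-length statistics (GLRLM) counting maximal runs of constant gray
  level per direction, with the eleven standard Galloway/Chu emphasis
  features.

Directional features are concatenated per direction, never averaged, so
anisotropic texture information is preserved; downstream feature selection
prunes any redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import QuantizedPatch

__all__ = [
    "DIRECTIONS",
    "Histogram",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "histogram",
    "first_order_features",
    "cooccurrence_matrix",
    "haralick_features",
    "run_length_matrix",
    "run_length_features",
]

#: Direction angle (degrees) -> (row, col) offset.  Rows grow downward,
#: so 45 deg points up-right.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

FIRST_ORDER_NAMES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
HARALICK_NAMES = ("asm", "entropy", "idm", "correlation", "contrast", "variance")
RUN_LENGTH_NAMES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)


@dataclass(frozen=True)
class Histogram:
    """Normalized gray-level histogram h(z_i), 0 <= i < L."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 1 or np.any(h < 0) or abs(h.sum() - 1.0) > 1e-12:
            raise ValueError("histogram must be a 1-D probability vector")
        object.__setattr__(self, "h", h)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Pair-probability matrix p(i, j | offset); symmetric when the opposite
    offset is pooled in."""

    P: np.ndarray
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("co-occurrence matrix must be a probability matrix")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts R[a, r-1]: runs of gray level a with length r, one direction."""

    R: np.ndarray
    theta: int
    n_pixels: int


def histogram(q: QuantizedPatch) -> Histogram:
    """Normalized histogram of a quantized patch."""
    counts = np.bincount(q.levels.ravel(), minlength=q.L).astype(float)
    return Histogram(h=counts / counts.sum())


def first_order_features(hist: Histogram) -> dict[str, float]:
    """Mean, variance, skewness, kurtosis, energy and entropy of a histogram.

    Skewness and kurtosis are the standardized 3rd/4th central moments and
    are defined as 0 for a degenerate (zero-variance) histogram.  Entropy
    is in bits with the 0*log0 := 0 convention.
    """
    h = hist.h
    z = np.arange(h.size, dtype=float)
    mean = float(z @ h)
    var = float(((z - mean) ** 2) @ h)
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((z - mean) ** 3) @ h) / sd**3
        kurt = float(((z - mean) ** 4) @ h) / var**2
    else:
        skew = kurt = 0.0
    energy = float(h @ h)
    nz = h[h > 0]
    entropy = float(-(nz @ np.log2(nz)))
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": entropy,
    }


def cooccurrence_matrix(
    q: QuantizedPatch, offset: tuple[int, int], symmetric: bool = True
) -> CooccurrenceMatrix:
    """Gray-level co-occurrence matrix for a (row, col) pixel offset.

    All in-bounds ordered pixel pairs at the offset are counted; with
    ``symmetric`` the opposite offset is pooled in as well, making the
    matrix equal to its transpose.  Counts are normalized by the total
    pair count T.
    """
    dr, dc = offset
    rows, cols = q.levels.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError(f"offset {offset} does not fit a {rows}x{cols} patch")
    lv = q.levels
    # source region and shifted region for the ordered pair (p, p+offset)
    r_lo, r_hi = max(0, -dr), rows - max(0, dr)
    c_lo, c_hi = max(0, -dc), cols - max(0, dc)
    a = lv[r_lo:r_hi, c_lo:c_hi].ravel()
    b = lv[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc].ravel()
    counts = np.bincount(a * q.L + b, minlength=q.L * q.L).reshape(q.L, q.L)
    counts = counts.astype(float)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(P=counts / counts.sum(), offset=offset, symmetric=symmetric)


def haralick_features(cm: CooccurrenceMatrix) -> dict[str, float]:
    """Six co-occurrence statistics: ASM, entropy, IDM, correlation,
    contrast and variance.

    Correlation is defined as 0 when either marginal is degenerate (a
    single occupied gray level), where the usual formula is 0/0.
    """
    P = cm.P
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    asm = float((P * P).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff2 = (ii - jj) ** 2
    idm = float((P / (1.0 + diff2)).sum())
    contrast = float((diff2 * P).sum())
    if var_x > 0 and var_y > 0:
        corr = (float((ii * jj * P).sum()) - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        corr = 0.0
    variance = float((((ii - mu_x) ** 2) * P).sum())
    return {
        "asm": asm,
        "entropy": entropy,
        "idm": idm,
        "correlation": corr,
        "contrast": contrast,
        "variance": variance,
    }


def _lines(levels: np.ndarray, theta: int) -> list[np.ndarray]:
    """Decompose a patch into the 1-D lines along a direction."""
    if theta == 0:
        return list(levels)
    if theta == 90:
        return list(levels.T)
    rows, cols = levels.shape
    if theta == 45:
        # up-right diagonals: constant row+col
        flipped = levels[::-1]
        return [np.diagonal(flipped, k) for k in range(-(rows - 1), cols)]
    if theta == 135:
        # up-left diagonals: constant row-col, traversed bottom-up
        return [np.diagonal(levels, k)[::-1] for k in range(-(rows - 1), cols)]
    raise ValueError(f"unsupported direction {theta}; use one of {sorted(DIRECTIONS)}")


def run_length_matrix(q: QuantizedPatch, theta: int) -> RunLengthMatrix:
    """Count maximal constant-gray-level runs along every line in a direction.

    R[a, r-1] is the number of runs of gray level ``a`` with length ``r``.
    The maximum possible run length sets the number of columns.
    """
    levels = q.levels
    lines = _lines(levels, theta)
    n_max = max(len(line) for line in lines)
    R = np.zeros((q.L, n_max), dtype=np.int64)
    for line in lines:
        if line.size == 0:
            continue
        # boundaries where the level changes
        starts = np.flatnonzero(np.diff(line) != 0) + 1
        edges = np.concatenate(([0], starts, [line.size]))
        lengths = np.diff(edges)
        values = line[edges[:-1]]
        np.add.at(R, (values, lengths - 1), 1)
    return RunLengthMatrix(R=R, theta=theta, n_pixels=int(levels.size))


def run_length_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """The eleven standard run-length emphasis features.

    Short/long-run emphasis weights by inverse/direct squared run length;
    low/high gray-level emphasis weights by inverse/direct squared gray
    level, indexed from 1; GLN/RLN measure gray-level and run-length
    nonuniformity; RP is the run percentage (runs per pixel).
    """
    R = rlm.R.astype(float)
    n_runs = R.sum()
    if n_runs == 0:
        raise ValueError("run-length matrix contains no runs")
    a = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]  # 1-based gray level
    r = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]  # run length
    return {
        "sre": float((R / r**2).sum() / n_runs),
        "lre": float((R * r**2).sum() / n_runs),
        "gln": float((R.sum(axis=1) ** 2).sum() / n_runs),
        "rln": float((R.sum(axis=0) ** 2).sum() / n_runs),
        "rp": float(n_runs / rlm.n_pixels),
        "lgre": float((R / a**2).sum() / n_runs),
        "hgre": float((R * a**2).sum() / n_runs),
        "srlge": float((R / (a**2 * r**2)).sum() / n_runs),
        "srhge": float((R * a**2 / r**2).sum() / n_runs),
        "lrlge": float((R * r**2 / a**2).sum() / n_runs),
        "lrhge": float((R * a**2 * r**2).sum() / n_runs),
    }
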