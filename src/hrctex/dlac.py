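"""Differential lacunarity (DLac) of gray-level intensity surfaces.

Lacunarity measures how the gap structure of a pattern deviates from
translational invariance, as a function of scale.  For CT data the binary
gliding-box method is inadequate because of the wide intensity range, so
lacunarity is computed from *differential box counting*: the patch is
scanned by overlapping ``w x w`` windows (stride 1), each window is
scanned by an ``r x r`` gliding box (stride 1), and over each box position
a column of stacked ``r x r x r`` cubes covers the intensity surface.
With the box maximum falling in cube ``v`` and the minimum in cube ``u``
(numbered from the bottom, starting at 1), the differential column height
is ``n = v - u - 1`` (clamped at 0 for flat boxes, where the formula would
go negative).  The box mass of a window is the sum of the column heights
over all box positions; the lacunarity at scale ``w`` is the ratio of the
second moment to the squared first moment of the window-mass distribution,

    Lambda(w, r) = E[M^2] / E[M]^2 >= 1,

with equality exactly when every window carries the same mass.  A
multiscale curve Lambda(w) for fixed small r, normalized by its value at
the smallest window, is the texture descriptor.

Intensities enter on the Hounsfield scale directly: levels are integer HU
offsets from ``hu_min`` over [-1000, +1000] by default (2001 levels) and
cubes are ``r`` levels tall, so the full CT dynamic range contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patches import HUPatch

__all__ = [
    "DlacConfig",
    "LacCurve",
    "column_height",
    "box_mass",
    "lacunarity",
    "lacunarity_from_masses",
    "dlac_curve",
    "dlac_features",
]

DEFAULT_HU_MIN = -1000.0
DEFAULT_HU_MAX = 1000.0


@dataclass(frozen=True)
class DlacConfig:
    """Settings for multiscale DLac curves.

    ``r`` is the gliding-box side (small, to stay sensitive to fine
    detail); ``w_range`` the window sides swept to change the analysis
    scale, each strictly larger than ``r``; intensities are clamped to
    ``[hu_min, hu_max]``.  Defaults are r = 4 with w = 5..35.
    """

    r: int = 4
    w_range: tuple[int, ...] = field(default_factory=lambda: tuple(range(5, 36)))
    hu_min: float = DEFAULT_HU_MIN
    hu_max: float = DEFAULT_HU_MAX
    normalize: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_range", tuple(int(w) for w in self.w_range))
        if self.r < 2:
            raise ValueError("box side r must be >= 2")
        if any(w <= self.r for w in self.w_range):
            raise ValueError("every window side must satisfy r < w")
        if self.hu_min >= self.hu_max:
            raise ValueError("hu_min must be < hu_max")


@dataclass(frozen=True)
class LacCurve:
    """Lambda(w) for fixed box side r, optionally normalized at w_min."""

    r: int
    w_values: tuple[int, ...]
    lam: np.ndarray
    normalized: bool


def _levels(pixels: np.ndarray, hu_min: float, hu_max: float) -> np.ndarray:
    """Integer intensity levels: rounded HU offsets from hu_min, clamped."""
    h = np.clip(np.asarray(pixels, dtype=float), hu_min, hu_max)
    return np.rint(h - hu_min).astype(np.int64)


def column_height(
    box_pixels: np.ndarray,
    r: int,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> int:
    """Differential height of the cube column over one r x r box.

    Levels are binned into stacked cubes of height ``r`` (cube index
    floor(level / r) + 1, counted from the bottom); with the box maximum
    in cube ``v`` and minimum in cube ``u`` the height is
    ``max(v - u - 1, 0)``.
    """
    box = np.asarray(box_pixels)
    if box.shape != (r, r):
        raise ValueError(f"box must be {r}x{r}, got {box.shape}")
    g = _levels(box, hu_min, hu_max)
    v = int(g.max()) // r + 1
    u = int(g.min()) // r + 1
    return max(v - u - 1, 0)


def _height_map(levels: np.ndarray, r: int) -> np.ndarray:
    """Column heights for every r x r box position (stride 1) of a patch."""
    from numpy.lib.stride_tricks import sliding_window_view

    cubes = levels // r  # 0-based cube index; differences match 1-based
    win = sliding_window_view(cubes, (r, r))
    n = win.max(axis=(2, 3)) - win.min(axis=(2, 3)) - 1
    return np.maximum(n, 0)


def _window_sums(arr: np.ndarray, m: int) -> np.ndarray:
    """Sliding m x m sums of a 2-D array via an integral image."""
    S = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=S[1:, 1:])
    return S[m:, m:] - S[:-m, m:] - S[m:, :-m] + S[:-m, :-m]


def box_mass(
    window: np.ndarray,
    r: int,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> int:
    """Box mass of one window: sum of column heights over all box positions."""
    win = np.asarray(window)
    w = win.shape[0]
    if win.shape != (w, w) or r >= w:
        raise ValueError("window must be square with side > r")
    return int(_height_map(_levels(win, hu_min, hu_max), r).sum())


def lacunarity_from_masses(masses: np.ndarray) -> float:
    """Moment-ratio lacunarity E[M^2]/E[M]^2 of an empirical mass sample.

    Defined as 1 when every mass is zero (a perfectly translation-
    invariant, structureless field).
    """
    m = np.asarray(masses, dtype=float)
    mean = m.mean()
    if mean == 0.0:
        return 1.0
    return float((m * m).mean() / mean**2)


def lacunarity(
    patch: HUPatch,
    w: int,
    r: int,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> float:
    """Lambda(w, r) of a patch: windows glide with stride 1 over the patch."""
    side = patch.size
    if not r < w <= side:
        raise ValueError(f"need r < w <= patch side, got r={r}, w={w}, side={side}")
    heights = _height_map(_levels(patch.pixels, hu_min, hu_max), r)
    # a w-window's mass is the sum of heights over its (w-r+1)^2 box positions
    masses = _window_sums(heights, w - r + 1)
    return lacunarity_from_masses(masses)


def dlac_curve(patch: HUPatch, cfg: DlacConfig | None = None) -> LacCurve:
    """Multiscale DLac curve Lambda(w) of a patch for fixed box side r.

    The height map is computed once; each scale only re-aggregates it.
    When ``cfg.normalize`` the curve is divided by its value at the
    smallest window, anchoring every patch to a common reference.
    """
    cfg = cfg or DlacConfig()
    side = patch.size
    if max(cfg.w_range) > side:
        raise ValueError("largest window exceeds patch side")
    heights = _height_map(_levels(patch.pixels, cfg.hu_min, cfg.hu_max), cfg.r)
    lam = np.array(
        [lacunarity_from_masses(_window_sums(heights, w - cfg.r + 1)) for w in cfg.w_range]
    )
    if cfg.normalize:
        lam = lam / lam[int(np.argmin(cfg.w_range))]
    return LacCurve(r=cfg.r, w_values=cfg.w_range, lam=lam, normalized=cfg.normalize)


def dlac_features(curve: LacCurve) -> dict[str, float]:
    """One feature per window side of a normalized curve, excluding w_min.

    The value at the smallest window is 1 by construction and carries no
    information, so it is dropped; the default configuration yields 30
    features named ``dlac.r{r}.w{w}``.
    """
    if not curve.normalized:
        raise ValueError("DLac features are defined on normalized curves")
    w_min = min(curve.w_values)
    return {
        f"dlac.r{curve.r}.w{w}": float(v)
        for w, v in zip(curve.w_values, curve.lam)
        if w != w_min
    }
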