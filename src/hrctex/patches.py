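"""Regions of interest on Hounsfield-unit CT slices.

A radiologist outlines a freehand region (FH-ROI) on a CT slice; the
classifier never sees the freehand region directly.  Instead the region is
covered by a grid of fixed-size square patches (default 40x40 pixels) and
only the patches lying entirely inside the freehand boundary are kept.
Each patch remembers the freehand region it came from (``fh_id``) so that
train/test splits can be made group-aware.

Intensities are kept in Hounsfield Units (HU) end to end; the classical
texture methods operate on a coarse quantization (default 32 gray levels)
computed against the dataset-wide HU range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HUImage",
    "FreehandROI",
    "HUPatch",
    "QuantizedPatch",
    "sample_roi_grid",
    "global_hu_range",
    "quantize",
    "read_dicom_hu",
    "read_raster_hu",
    "read_mask",
    "hu_window_to_uint8",
    "PATCH_SIZE",
    "DEFAULT_LEVELS",
]

#: Side of the square classification patch, in pixels.
PATCH_SIZE = 40

#: Default number of gray levels for the classical texture methods.
DEFAULT_LEVELS = 32

#: Class labels for the four lung-parenchyma patterns: normal, ground
#: glass, honeycombing, emphysema.
CLASS_LABELS = ("NOR", "GG", "HC", "EMP")


@dataclass(frozen=True)
class HUImage:
    """A 2-D CT slice in Hounsfield Units.

    Parameters
    ----------
    pixels
        2-D float array of HU intensities (air is about -1000, water 0).
    pixel_spacing
        Optional (row, col) spacing in millimetres per pixel.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class FreehandROI:
    """A freehand-outlined region on a CT slice, with its pattern label."""

    mask: np.ndarray
    label: str
    fh_id: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class HUPatch:
    """A fixed-size square patch of HU intensities sampled from a FH-ROI."""

    pixels: np.ndarray
    label: str
    fh_id: int
    patch_id: int
    origin: tuple[int, int] = field(default=(0, 0))  # (row, col) in parent image

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("patch must be square")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class QuantizedPatch:
    """Integer gray levels in [0, L-1] obtained from an :class:`HUPatch`."""

    levels: np.ndarray
    L: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if not np.issubdtype(lv.dtype, np.integer):
            raise ValueError("levels must be integers")
        if lv.min(initial=0) < 0 or lv.max(initial=0) > self.L - 1:
            raise ValueError("levels out of [0, L-1]")
        object.__setattr__(self, "levels", lv)


def sample_roi_grid(
    image: HUImage, roi: FreehandROI, size: int = PATCH_SIZE
) -> list[HUPatch]:
    """Tile a freehand region with non-overlapping square patches.

    The grid is anchored at the top-left corner of the mask bounding box
    and steps by ``size`` in both directions; only grid cells that lie
    100% inside the mask are returned.  Patch ids are sequential in
    row-major grid order.
    """
    if roi.mask.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} != image shape {image.pixels.shape}"
        )
    rows_any = roi.mask.any(axis=1)
    if not rows_any.any():
        return []
    cols_any = roi.mask.any(axis=0)
    r0 = int(np.argmax(rows_any))
    r1 = int(len(rows_any) - np.argmax(rows_any[::-1]))  # exclusive
    c0 = int(np.argmax(cols_any))
    c1 = int(len(cols_any) - np.argmax(cols_any[::-1]))

    patches: list[HUPatch] = []
    pid = 0
    for r in range(r0, r1 - size + 1, size):
        for c in range(c0, c1 - size + 1, size):
            cell = roi.mask[r : r + size, c : c + size]
            if cell.all():
                patches.append(
                    HUPatch(
                        pixels=image.pixels[r : r + size, c : c + size].copy(),
                        label=roi.label,
                        fh_id=roi.fh_id,
                        patch_id=pid,
                        origin=(r, c),
                    )
                )
                pid += 1
    return patches


def global_hu_range(patches: list[HUPatch]) -> tuple[float, float]:
    """Dataset-wide (min, max) HU over every pixel of every patch.

    The classical texture features quantize each patch against this common
    range so that gray levels are comparable across the whole dataset.
    """
    if not patches:
        raise ValueError("cannot compute HU range of an empty patch list")
    mn = min(float(p.pixels.min()) for p in patches)
    mx = max(float(p.pixels.max()) for p in patches)
    return mn, mx


def quantize(
    patch: HUPatch,
    min_hu: float,
    max_hu: float,
    L: int = DEFAULT_LEVELS,
) -> QuantizedPatch:
    """Uniform quantization of a patch to ``L`` gray levels.

    Bins have equal width over the integer span ``max_hu - min_hu + 1`` so
    that ``min_hu`` maps to level 0 and ``max_hu`` to level L-1.  Pixels
    outside the range (possible when a stored dataset range is applied to
    new data) are clamped before binning.
    """
    if min_hu >= max_hu:
        raise ValueError(f"degenerate HU range [{min_hu}, {max_hu}]")
    h = np.clip(patch.pixels, min_hu, max_hu)
    levels = np.floor((h - min_hu) / (max_hu - min_hu + 1.0) * L).astype(np.int64)
    return QuantizedPatch(levels=levels, L=L)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_dicom_hu(path: str | Path) -> HUImage:
    """Read a CT slice from DICOM, applying rescale slope/intercept to HU."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return HUImage(pixels=arr * slope + intercept, pixel_spacing=spacing)


def read_raster_hu(path: str | Path, sidecar: str | Path | None = None) -> HUImage:
    """Read an 8/16-bit raster (PNG/PGM) with a JSON sidecar giving the HU map.

    The sidecar holds ``{"slope": s, "intercept": b}`` so that
    ``hu = s * raw + b``; it defaults to ``<path>.json``.  Identity mapping
    is assumed when no sidecar exists.
    """
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(str(path))).astype(float)
    if raw.ndim == 3:  # collapse grayscale-stored-as-RGB
        raw = raw[..., 0]
    slope, intercept = 1.0, 0.0
    sc = Path(sidecar) if sidecar is not None else Path(str(path) + ".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
        slope = float(meta.get("slope", 1.0))
        intercept = float(meta.get("intercept", 0.0))
    return HUImage(pixels=raw * slope + intercept)


def read_mask(path: str | Path, label: str, fh_id: int) -> FreehandROI:
    """Read a freehand-region mask from a raster file (nonzero = inside)."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(str(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return FreehandROI(mask=raw != 0, label=label, fh_id=fh_id)


def hu_window_to_uint8(
    pixels: np.ndarray, center: float = -700.0, width: float = 1500.0
) -> np.ndarray:
    """Map HU to 8-bit display values with a lung window (centre -700, width 1500)."""
    lo = center - width / 2.0
    frac = np.clip((np.asarray(pixels, dtype=float) - lo) / width, 0.0, 1.0)
    return np.round(frac * 255.0).astype(np.uint8)
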