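"""Synthetic HU texture phantoms for the four lung-parenchyma patterns.

Real training data for this problem is hospital HRCT annotated by
radiologists and is not publicly distributable, so every pipeline stage is
exercised on synthetic 40x40 patches that caricature the textures:

* NOR (normal): dark aerated background with sparse bright vessel
  cross-sections;
* GG (ground glass): hazy, raised attenuation, smooth correlated field,
  no discrete structure;
* HC (honeycombing): clustered air cysts (dark holes) separated by thick
  bright fibrotic walls, laid out as a jittered lattice;
* EMP (emphysema): very low attenuation with large destroyed-parenchyma
  blobs approaching air density.

Each class is a smoothed Gaussian random field (mean, standard deviation,
correlation length) with structural elements stamped on top; all values
are clamped to [-1000, +1000] HU.  The parameters below are fixture
choices for qualitative fidelity to HRCT pattern appearance, kept in one
editable block.

Patches are organised into synthetic freehand-ROI groups: a group draws a
jittered copy of its class parameters once, so patches within a group are
correlated the way clinical patches sampled from one freehand region are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .patches import PATCH_SIZE, CLASS_LABELS, HUPatch

__all__ = [
    "PhantomSpec",
    "CLASS_SPECS",
    "CLINICAL_COMPOSITION",
    "generate_patch",
    "generate_dataset",
]

HU_FLOOR = -1000.0
HU_CEIL = 1000.0

#: Composition of the clinical HRCT dataset the protocol is designed
#: around (patients / freehand regions / 40x40 patches per class).  Kept
#: as reference so experiment configurations can mirror its class balance.
CLINICAL_COMPOSITION = {
    "NOR": {"patients": 16, "freehand_rois": 87, "rois": 253},
    "GG": {"patients": 20, "freehand_rois": 166, "rois": 396},
    "HC": {"patients": 7, "freehand_rois": 72, "rois": 217},
    "EMP": {"patients": 14, "freehand_rois": 92, "rois": 395},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one texture class."""

    label: str
    mean_hu: float
    sd_hu: float
    correlation_length: float  # pixels; Gaussian smoothing scale
    structure: str = "none"  # none | bright_dots | dark_holes | large_blobs
    structure_density: float = 0.0  # expected elements per patch
    structure_radius: tuple[float, float] = (0.0, 0.0)
    structure_hu: float = 0.0
    wall_hu: float | None = None  # rim value for dark_holes

    def __post_init__(self) -> None:
        if self.sd_hu <= 0 or self.correlation_length <= 0:
            raise ValueError("sd and correlation length must be positive")
        if self.structure != "none" and self.structure_density <= 0:
            raise ValueError("structured specs need a positive density")


# One editable block of class parameters (fixture values, HU).
CLASS_SPECS: dict[str, PhantomSpec] = {
    "NOR": PhantomSpec(
        label="NOR", mean_hu=-850.0, sd_hu=120.0, correlation_length=2.0,
        structure="bright_dots", structure_density=6.0,
        structure_radius=(1.0, 2.0), structure_hu=-300.0,
    ),
    "GG": PhantomSpec(
        label="GG", mean_hu=-600.0, sd_hu=80.0, correlation_length=4.0,
    ),
    "HC": PhantomSpec(
        label="HC", mean_hu=-900.0, sd_hu=60.0, correlation_length=2.0,
        structure="dark_holes", structure_density=9.0,
        structure_radius=(3.0, 6.0), structure_hu=-950.0, wall_hu=-300.0,
    ),
    "EMP": PhantomSpec(
        label="EMP", mean_hu=-950.0, sd_hu=40.0, correlation_length=3.0,
        structure="large_blobs", structure_density=3.0,
        structure_radius=(6.0, 10.0), structure_hu=-990.0,
    ),
}


def _gaussian_field(
    rng: np.random.Generator, size: int, mean: float, sd: float, corr: float
) -> np.ndarray:
    """Stationary Gaussian random field with the requested moments.

    White noise is smoothed at the correlation length and rescaled to unit
    variance, so ``sd`` is the pointwise standard deviation after
    smoothing.
    """
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=corr, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return mean + sd * smooth


def _disk(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _stamp_structures(
    field: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Overlay class-specific structural elements on a background field."""
    size = field.shape[0]
    out = field.copy()
    r_lo, r_hi = spec.structure_radius

    if spec.structure == "none":
        return out

    if spec.structure == "dark_holes":
        # jittered lattice of air cysts rimmed by fibrotic walls
        pitch = max(int(np.sqrt(size * size / spec.structure_density)), 4)
        for gy in np.arange(pitch / 2, size, pitch):
            for gx in np.arange(pitch / 2, size, pitch):
                cy = gy + rng.uniform(-pitch / 4, pitch / 4)
                cx = gx + rng.uniform(-pitch / 4, pitch / 4)
                radius = rng.uniform(r_lo, r_hi)
                wall = _disk(size, cy, cx, radius + 2.0)
                hole = _disk(size, cy, cx, radius)
                out[wall] = spec.wall_hu + rng.normal(0, 20)
                out[hole] = spec.structure_hu + rng.normal(0, 10)
        return out

    # Poisson-count random placement for dots and blobs
    n_elem = rng.poisson(spec.structure_density)
    for _ in range(n_elem):
        cy, cx = rng.uniform(0, size, size=2)
        radius = rng.uniform(r_lo, r_hi)
        mask = _disk(size, cy, cx, radius)
        out[mask] = spec.structure_hu + rng.normal(0, 15)
    return out


def generate_patch(
    spec: PhantomSpec, rng_seed: int | np.random.Generator
) -> HUPatch:
    """One synthetic 40x40 patch of the given class; deterministic per seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    field = _gaussian_field(
        rng, PATCH_SIZE, spec.mean_hu, spec.sd_hu, spec.correlation_length
    )
    field = _stamp_structures(field, spec, rng)
    field = np.clip(field, HU_FLOOR, HU_CEIL)
    return HUPatch(pixels=field, label=spec.label, fh_id=-1, patch_id=-1)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Group-level parameter draw: patches in one synthetic freehand region
    share a shifted version of the class parameters.

    Freehand regions come from different patients and disease stages, so
    between-region attenuation differences dominate the patch-to-patch
    variation inside one region; the mean shift is sized accordingly.
    """
    return replace(
        spec,
        mean_hu=spec.mean_hu + rng.normal(0, 40.0),
        sd_hu=spec.sd_hu * rng.uniform(0.85, 1.15),
        correlation_length=spec.correlation_length * rng.uniform(0.85, 1.15),
    )


def generate_dataset(
    n_groups_per_class: int,
    patches_per_group: int,
    seed: int,
    classes: tuple[str, ...] = CLASS_LABELS,
) -> list[HUPatch]:
    """Synthetic dataset with freehand-ROI group structure.

    Each group draws one jittered parameter set, then generates its
    patches from it, so within-group patches are correlated.  Groups get
    globally unique ``fh_id`` values and patches sequential ``patch_id``.
    """
    if n_groups_per_class <= 0 or patches_per_group <= 0:
        raise ValueError("counts must be positive")
    root = np.random.SeedSequence(seed)
    patches: list[HUPatch] = []
    fh_id = 0
    patch_id = 0
    for label in classes:
        base = CLASS_SPECS[label]
        class_seq = root.spawn(1)[0]
        for g_seq in class_seq.spawn(n_groups_per_class):
            rng = np.random.default_rng(g_seq)
            spec = _jitter_spec(base, rng)
            for _ in range(patches_per_group):
                p = generate_patch(spec, rng)
                patches.append(
                    HUPatch(pixels=p.pixels, label=label, fh_id=fh_id, patch_id=patch_id)
                )
                patch_id += 1
            fh_id += 1
    return patches
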