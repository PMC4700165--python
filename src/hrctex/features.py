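"""Assembly of per-patch feature tables.

Two feature sets are used throughout:

* ``set1`` — first-order (6) + co-occurrence (4 directions x 6) +
  run-length (4 directions x 11) = 74 features;
* ``set2`` — set1 plus the 30 multiscale DLac curve features.

Columns are namespaced (``fo.mean``, ``sgldm.d1.a45.contrast``,
``glrlm.a90.sre``, ``dlac.r4.w12``) so sets can be sliced by prefix.
Classical features are computed on patches quantized against the
dataset-wide HU range; DLac works on the raw Hounsfield scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classical, dlac
from .patches import DEFAULT_LEVELS, HUPatch, global_hu_range, quantize

__all__ = ["patch_features", "extract_features", "feature_columns"]


def patch_features(
    patch: HUPatch,
    hu_range: tuple[float, float],
    L: int = DEFAULT_LEVELS,
    dlac_cfg: dlac.DlacConfig | None = None,
    feature_set: str = "set2",
) -> dict[str, float]:
    """Named texture features of one patch.

    ``hu_range`` is the dataset-wide (min, max) used for quantization so
    gray levels are comparable across patches.
    """
    if feature_set not in ("set1", "set2"):
        raise ValueError("feature_set must be 'set1' or 'set2'")
    q = quantize(patch, hu_range[0], hu_range[1], L)
    feats: dict[str, float] = {}

    fo = classical.first_order_features(classical.histogram(q))
    feats.update({f"fo.{k}": v for k, v in fo.items()})

    for theta, offset in classical.DIRECTIONS.items():
        cm = classical.cooccurrence_matrix(q, offset, symmetric=True)
        for k, v in classical.haralick_features(cm).items():
            feats[f"sgldm.d1.a{theta}.{k}"] = v

    for theta in classical.DIRECTIONS:
        rlm = classical.run_length_matrix(q, theta)
        for k, v in classical.run_length_features(rlm).items():
            feats[f"glrlm.a{theta}.{k}"] = v

    if feature_set == "set2":
        curve = dlac.dlac_curve(patch, dlac_cfg or dlac.DlacConfig())
        feats.update(dlac.dlac_features(curve))
    return feats


def extract_features(
    patches: list[HUPatch],
    L: int = DEFAULT_LEVELS,
    dlac_cfg: dlac.DlacConfig | None = None,
    feature_set: str = "set2",
    hu_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Feature table for a list of patches.

    Returns a DataFrame indexed by ``patch_id`` with ``label`` and
    ``fh_id`` metadata columns followed by the feature columns.
    """
    if not patches:
        raise ValueError("no patches to extract features from")
    if hu_range is None:
        hu_range = global_hu_range(patches)
    rows = []
    for p in patches:
        row: dict[str, object] = {
            "patch_id": p.patch_id,
            "fh_id": p.fh_id,
            "label": p.label,
        }
        row.update(patch_features(p, hu_range, L=L, dlac_cfg=dlac_cfg, feature_set=feature_set))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patch_id")
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature column names of a table (everything but the metadata)."""
    return [c for c in df.columns if c not in ("fh_id", "label")]


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(X, labels, group ids, feature names) views of a feature table."""
    cols = feature_columns(df)
    return (
        df[cols].to_numpy(dtype=float),
        df["label"].to_numpy(),
        df["fh_id"].to_numpy(),
        cols,
    )
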