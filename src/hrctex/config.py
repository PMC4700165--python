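"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .dlac import DlacConfig
from .svm_cad import HyperGrid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings for a full experiment run.

    All randomness flows from ``seed``: each iteration derives its own
    sub-seeds for holdout and fold shuffling through a seed-sequence
    spawn, so a run is a pure function of (config, input data).
    """

    feature_set: str = "set2"  # set1 = FO+SGLDM+GLRLM, set2 adds DLac
    levels: int = 32  # gray levels for the classical methods
    dlac_r: int = 4
    dlac_w_min: int = 5
    dlac_w_max: int = 35
    hu_min: float = -1000.0
    hu_max: float = 1000.0
    p_enter: float = 0.01
    p_remove: float = 0.02
    grid: str = "reduced"  # reduced | coarse
    k: int = 10
    train_fraction: float = 2.0 / 3.0
    iterations: int = 50
    scenario: str = "multiclass"  # multiclass | binary
    seed: int = 0
    # synthetic-dataset shape (used when input is simulated)
    n_groups_per_class: int = 20
    patches_per_group: int = 5
    extra: dict = field(default_factory=dict)

    def dlac_config(self) -> DlacConfig:
        return DlacConfig(
            r=self.dlac_r,
            w_range=tuple(range(self.dlac_w_min, self.dlac_w_max + 1)),
            hu_min=self.hu_min,
            hu_max=self.hu_max,
        )

    def hyper_grid(self) -> HyperGrid:
        if self.grid == "coarse":
            return HyperGrid.coarse()
        if self.grid == "reduced":
            return HyperGrid.reduced()
        raise ValueError(f"unknown grid {self.grid!r}")

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)
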