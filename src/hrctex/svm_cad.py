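"""SVM-RBF classification pipeline with in-fold feature selection.

The classifier is a soft-margin SVM with the Gaussian RBF kernel
K(x, y) = exp(-||x - y||^2 / (2 sigma^2)); multiclass problems use the
one-vs-one construction, training n(n-1)/2 pairwise binary machines and
predicting by winner-takes-all voting (ties resolved by summed decision
values toward each tied class, then class order).

Model selection follows the protocol: the dataset is split 2/3-1/3 by a
group-aware stratified holdout (patches from one freehand region never
straddle the split); (C, sigma) is chosen on the training side by a grid
search over powers of two where every grid point is scored by stratified
10-fold cross-validation with stepwise feature selection re-run inside
each fold on the nine training folds only; the best point is refined on a
+-0.5 exponent neighbourhood at step 0.25; the final machine is retrained
on the whole training side with features selected on it.  The experiment
repeats holdout -> search -> test evaluation over many iterations and
reports mean +- SD of the contingency-table metrics.

Features are z-scored (statistics from the training folds only) before
the SVM so a single shared sigma is meaningful across mixed-scale
features; the stepwise F-test itself is scale-invariant and runs on raw
features.  The binary scenario opposes the normal class to all
pathological classes pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import contingency, metrics
from .features import feature_matrix
from .selection import P_ENTER_DEFAULT, P_REMOVE_DEFAULT, select_features

__all__ = [
    "rbf_kernel",
    "HyperGrid",
    "Split",
    "group_stratified_holdout",
    "OneVsOneSVM",
    "TrainedModel",
    "grid_search_cv",
    "train_model",
    "run_experiment",
]

BINARY_POSITIVE = "PATH"  # pooled pathological label in the binary scenario


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian RBF similarity exp(-||x - y||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal dimension")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma**2)))


@dataclass(frozen=True)
class HyperGrid:
    """Powers-of-two search grid for (C, sigma).

    Exponents are base-2; the coarse grid spans C = 2^-5..2^15 and
    sigma = 2^-2..2^7 at step 0.5 (41 x 19 = 779 points).  The reduced
    grid is the narrowed search space found adequate for this problem
    (C = 2^3..2^13, sigma = 2^-2..2^1).  Refinement around the best point
    uses ``fine_step``.
    """

    C_exponents: tuple[float, ...]
    sigma_exponents: tuple[float, ...]
    fine_step: float = 0.25

    def __post_init__(self) -> None:
        for name, exps in (("C", self.C_exponents), ("sigma", self.sigma_exponents)):
            if len(exps) == 0 or np.any(np.diff(exps) <= 0):
                raise ValueError(f"{name} exponents must be non-empty and increasing")

    @classmethod
    def coarse(cls) -> "HyperGrid":
        return cls(
            C_exponents=tuple(np.arange(-5.0, 15.0 + 1e-9, 0.5)),
            sigma_exponents=tuple(np.arange(-2.0, 7.0 + 1e-9, 0.5)),
        )

    @classmethod
    def reduced(cls) -> "HyperGrid":
        return cls(
            C_exponents=tuple(np.arange(3.0, 13.0 + 1e-9, 0.5)),
            sigma_exponents=tuple(np.arange(-2.0, 1.0 + 1e-9, 0.5)),
        )

    def points(self) -> list[tuple[float, float]]:
        return [(c, s) for c in self.C_exponents for s in self.sigma_exponents]


@dataclass(frozen=True)
class Split:
    """Group-aware holdout split: row indices into the feature table."""

    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test rows overlap")


def group_stratified_holdout(
    labels: np.ndarray,
    groups: np.ndarray,
    train_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> Split:
    """Stratified holdout that assigns whole freehand-ROI groups.

    Groups of each class are shuffled and moved to the training side
    until it holds about ``train_fraction`` of the class's patches; the
    remaining groups form the test side.  A class present in a single
    group cannot be split and is forced to training with a warning.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    train_rows: list[np.ndarray] = []
    test_rows: list[np.ndarray] = []
    for cls in sorted(np.unique(labels).tolist()):
        cls_rows = np.flatnonzero(labels == cls)
        cls_groups = np.unique(groups[cls_rows])
        if cls_groups.size < 2:
            warnings.warn(
                f"class {cls!r} has a single freehand group; forced to training"
            )
            train_rows.append(cls_rows)
            continue
        order = rng.permutation(cls_groups)
        target = train_fraction * cls_rows.size
        taken = 0
        for k, g in enumerate(order):
            g_rows = cls_rows[groups[cls_rows] == g]
            # keep at least one group on each side
            if taken >= target and k < cls_groups.size:
                test_rows.append(g_rows)
            else:
                train_rows.append(g_rows)
                taken += g_rows.size
        if taken == cls_rows.size:  # nothing left for test: move the last group
            moved = train_rows.pop()
            test_rows.append(moved)
    return Split(
        train_idx=np.sort(np.concatenate(train_rows)),
        test_idx=np.sort(np.concatenate(test_rows)) if test_rows else np.array([], dtype=int),
    )


class OneVsOneSVM:
    """One-vs-one multiclass SVM-RBF with winner-takes-all voting.

    One binary soft-margin machine per class pair; prediction tallies the
    pairwise wins and breaks vote ties by the summed decision values in
    favour of each tied class, then by class order.
    """

    def __init__(self, C: float, sigma: float):
        if C <= 0 or sigma <= 0:
            raise ValueError("C and sigma must be positive")
        self.C = C
        self.sigma = sigma
        self.gamma = 1.0 / (2.0 * sigma**2)
        self.classes_: list = []
        self.pair_models_: dict[tuple, SVC] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = sorted(np.unique(y).tolist())
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.pair_models_ = {}
        for a_idx in range(len(self.classes_)):
            for b_idx in range(a_idx + 1, len(self.classes_)):
                a, b = self.classes_[a_idx], self.classes_[b_idx]
                rows = np.flatnonzero((y == a) | (y == b))
                svc = SVC(C=self.C, kernel="rbf", gamma=self.gamma)
                svc.fit(X[rows], np.where(y[rows] == b, 1, -1))  # +1 = class b
                self.pair_models_[(a, b)] = svc
        return self

    @property
    def n_pairs(self) -> int:
        return len(self.pair_models_)

    def decision_table(self, X: np.ndarray) -> dict[tuple, np.ndarray]:
        """Signed decision value per pair model (positive favours the pair's
        second class)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return {pair: svc.decision_function(X) for pair, svc in self.pair_models_.items()}

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        n_cls = len(self.classes_)
        votes = np.zeros((n, n_cls), dtype=int)
        scores = np.zeros((n, n_cls), dtype=float)  # summed decision toward class
        cls_index = {c: k for k, c in enumerate(self.classes_)}
        for (a, b), dec in self.decision_table(X).items():
            ia, ib = cls_index[a], cls_index[b]
            b_wins = dec > 0
            votes[:, ib] += b_wins
            votes[:, ia] += ~b_wins
            scores[:, ib] += dec
            scores[:, ia] -= dec
        out = []
        for i in range(n):
            best_votes = votes[i].max()
            tied = np.flatnonzero(votes[i] == best_votes)
            if tied.size > 1:
                best_score = scores[i, tied].max()
                tied = tied[scores[i, tied] == best_score]
            out.append(self.classes_[int(tied[0])])
        return np.asarray(out)


@dataclass
class TrainedModel:
    """Final classifier: selected features, training z-score statistics,
    the pairwise SVM bank and its hyperparameters."""

    feature_names: list[str]
    selected: tuple[int, ...]
    mu: np.ndarray
    sd: np.ndarray
    ovo: OneVsOneSVM
    C: float
    sigma: float

    @property
    def selected_names(self) -> list[str]:
        return [self.feature_names[j] for j in self.selected]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return (X[:, self.selected] - self.mu) / self.sd

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature table is missing columns: {missing[:5]}")
            X = X[self.feature_names].to_numpy(dtype=float)
        return self.ovo.predict(self.transform(X))


def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


@dataclass
class GridSearchResult:
    best_C_exp: float
    best_sigma_exp: float
    cv_accuracy: float
    surface: dict[tuple[float, float], float] = field(repr=False, default_factory=dict)
    fold_selections: list[tuple[int, ...]] = field(repr=False, default_factory=list)

    @property
    def best_C(self) -> float:
        return float(2.0**self.best_C_exp)

    @property
    def best_sigma(self) -> float:
        return float(2.0**self.best_sigma_exp)


def _prepare_folds(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int,
    p_enter: float,
    p_remove: float,
    max_redraws: int = 5,
) -> list[dict]:
    """Stratified folds with per-fold stepwise selection and z-scoring.

    Selection and scaling use the k-1 training folds only, so the held
    fold never leaks into the fold's model.  Selection does not depend on
    (C, sigma) and is therefore computed once per fold and shared by all
    grid points.
    """
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} instances per class in the training set; "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    folds = []
    for redraw in range(max_redraws):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + redraw) % 2**31)
        candidate = list(skf.split(X, y))
        if all(np.unique(y[tr]).size == classes.size for tr, _ in candidate):
            break
    else:  # pragma: no cover - unreachable given the class-count precondition
        raise RuntimeError("could not draw folds covering every class")
    for tr, va in candidate:
        sel = select_features(X[tr], y[tr], p_enter=p_enter, p_remove=p_remove)
        if not sel:  # degenerate: keep the single best column to stay trainable
            sel = (0,)
        mu, sd = _zscore_stats(X[np.ix_(tr, sel)])
        folds.append(
            {
                "train": tr,
                "val": va,
                "sel": sel,
                "Xtr": (X[np.ix_(tr, sel)] - mu) / sd,
                "ytr": y[tr],
                "Xva": (X[np.ix_(va, sel)] - mu) / sd,
                "yva": y[va],
            }
        )
    return folds


def _cv_accuracy(folds: list[dict], C: float, sigma: float) -> float:
    accs = []
    for f in folds:
        model = OneVsOneSVM(C=C, sigma=sigma).fit(f["Xtr"], f["ytr"])
        accs.append(float(np.mean(model.predict(f["Xva"]) == f["yva"])))
    return float(np.mean(accs))


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid | None = None,
    k: int = 10,
    seed: int = 0,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> GridSearchResult:
    """Choose (C, sigma) by stratified k-fold CV with in-fold selection.

    Every coarse grid point is scored by the mean held-fold accuracy;
    ties prefer the smallest C then the smallest sigma (smoother
    machines).  The winner's exponent neighbourhood (+-0.5 at step 0.25)
    is then scored the same way and the overall best point returned.
    """
    grid = grid or HyperGrid.reduced()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _prepare_folds(X, y, k=k, seed=seed, p_enter=p_enter, p_remove=p_remove)

    surface: dict[tuple[float, float], float] = {}

    def score(ce: float, se: float) -> float:
        key = (round(ce, 4), round(se, 4))
        if key not in surface:
            surface[key] = _cv_accuracy(folds, C=2.0**ce, sigma=2.0**se)
        return surface[key]

    def best_of(points: list[tuple[float, float]]) -> tuple[float, float]:
        # max accuracy; ties -> smallest C exponent, then smallest sigma
        return min(points, key=lambda p: (-score(p[0], p[1]), p[0], p[1]))

    coarse_best = best_of(grid.points())
    step = grid.fine_step
    offsets = np.arange(-0.5, 0.5 + 1e-9, step)
    fine_points = [
        (round(coarse_best[0] + dc, 4), round(coarse_best[1] + ds, 4))
        for dc in offsets
        for ds in offsets
    ]
    overall_best = best_of(list(dict.fromkeys(fine_points + [coarse_best])))
    return GridSearchResult(
        best_C_exp=overall_best[0],
        best_sigma_exp=overall_best[1],
        cv_accuracy=score(*overall_best),
        surface=surface,
        fold_selections=[f["sel"] for f in folds],
    )


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    C: float,
    sigma: float,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> TrainedModel:
    """Retrain on the full training side: select features on it, z-score
    it, fit the pairwise machines at the chosen (C, sigma)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sel = select_features(X, y, p_enter=p_enter, p_remove=p_remove)
    if not sel:
        sel = (0,)
    mu, sd = _zscore_stats(X[:, sel])
    ovo = OneVsOneSVM(C=C, sigma=sigma).fit((X[:, sel] - mu) / sd, y)
    return TrainedModel(
        feature_names=list(feature_names),
        selected=sel,
        mu=mu,
        sd=sd,
        ovo=ovo,
        C=C,
        sigma=sigma,
    )


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    """Pool the pathological patterns against the normal class."""
    return np.where(np.asarray(labels) == "NOR", "NOR", BINARY_POSITIVE)


def run_experiment(
    table: pd.DataFrame,
    scenario: str = "multiclass",
    grid: HyperGrid | None = None,
    k: int = 10,
    train_fraction: float = 2.0 / 3.0,
    iterations: int = 50,
    seed: int = 0,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> dict:
    """Repeated holdout -> grid-search CV -> test evaluation.

    ``table`` is a feature table from :func:`hrctex.features.extract_features`.
    Each iteration redraws the group-stratified holdout from a fresh
    sub-seed, selects (C, sigma) and features on the training side only,
    and scores the final machine on the untouched test side.  Returns the
    per-iteration records plus mean and SD of every metric.
    """
    if scenario not in ("multiclass", "binary"):
        raise ValueError("scenario must be 'multiclass' or 'binary'")
    X, labels, groups, names = feature_matrix(table)
    if scenario == "binary":
        labels = _binary_labels(labels)
    classes = sorted(np.unique(labels).tolist())

    root = np.random.SeedSequence(seed)
    records: list[dict] = []
    for it, seq in enumerate(root.spawn(iterations)):
        sub = seq.generate_state(2)
        split = group_stratified_holdout(
            labels, groups, train_fraction=train_fraction,
            seed=np.random.default_rng(sub[0]),
        )
        tr, te = split.train_idx, split.test_idx
        search = grid_search_cv(
            X[tr], labels[tr], grid=grid, k=k, seed=int(sub[1] % 2**31),
            p_enter=p_enter, p_remove=p_remove,
        )
        model = train_model(
            X[tr], labels[tr], names, C=search.best_C, sigma=search.best_sigma,
            p_enter=p_enter, p_remove=p_remove,
        )
        y_pred = model.ovo.predict(model.transform(X[te]))
        table_counts = contingency(labels[te], y_pred, classes)
        m = metrics(table_counts)
        records.append(
            {
                "iteration": it,
                "C_exp": search.best_C_exp,
                "sigma_exp": search.best_sigma_exp,
                "cv_accuracy": search.cv_accuracy,
                "n_selected": len(model.selected),
                "selected_names": model.selected_names,
                "contingency": table_counts.A.tolist(),
                "metrics": m,
            }
        )

    def collect(path) -> np.ndarray:
        return np.array([path(r["metrics"]) for r in records], dtype=float)

    summary: dict[str, dict[str, float]] = {}
    acc = collect(lambda m: m["overall_accuracy"])
    summary["overall_accuracy"] = {"mean": float(np.nanmean(acc)), "sd": float(np.nanstd(acc))}
    for c in classes:
        for met in ("sensitivity", "precision", "specificity"):
            vals = collect(lambda m, c=c, met=met: m["per_class"][c][met])
            summary[f"{c}.{met}"] = {
                "mean": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals)),
            }
    return {"scenario": scenario, "classes": classes, "iterations": records, "summary": summary}
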