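"""RBF kernel, group-stratified holdout, one-vs-one SVM and grid-search CV."""

import numpy as np
import pytest

from hrctex.svm_cad import (
    HyperGrid,
    OneVsOneSVM,
    grid_search_cv,
    group_stratified_holdout,
    rbf_kernel,
    train_model,
)


class TestRbfKernel:
    def test_identical_points(self, rng):
        x = rng.standard_normal(8)
        assert rbf_kernel(x, x, sigma=1.3) == pytest.approx(1.0)

    def test_characteristic_distance(self):
        sigma = 2.0
        x = np.zeros(1)
        y = np.array([np.sqrt(2.0) * sigma])  # ||x-y||^2 = 2 sigma^2
        assert rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1.0))

    def test_matches_direct_arithmetic(self, rng):
        x, y = rng.standard_normal((2, 12))
        sigma = 0.7
        expected = np.exp(-np.sum((x - y) ** 2) / (2 * sigma**2))
        assert rbf_kernel(x, y, sigma) == pytest.approx(expected)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(2), sigma=0.0)


class TestHyperGrid:
    def test_coarse_grid_point_count(self):
        grid = HyperGrid.coarse()
        assert len(grid.C_exponents) == 41
        assert len(grid.sigma_exponents) == 19
        assert len(grid.points()) == 779
        assert grid.C_exponents[0] == -5.0 and grid.C_exponents[-1] == 15.0
        assert grid.sigma_exponents[0] == -2.0 and grid.sigma_exponents[-1] == 7.0

    def test_reduced_grid_span(self):
        grid = HyperGrid.reduced()
        assert grid.C_exponents[0] == 3.0 and grid.C_exponents[-1] == 13.0
        assert grid.sigma_exponents[-1] == 1.0


def _grouped_labels(n_groups, per_group, classes, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups * len(classes)), per_group)
    labels = np.repeat(np.repeat(classes, n_groups), per_group)
    return labels, groups, rng


class TestGroupStratifiedHoldout:
    def test_groups_never_straddle(self):
        labels, groups, rng = _grouped_labels(6, 5, ["a", "b"])
        split = group_stratified_holdout(labels, groups, seed=rng)
        assert not set(groups[split.train_idx]) & set(groups[split.test_idx])
        assert len(split.train_idx) + len(split.test_idx) == len(labels)

    def test_balanced_six_groups_split_four_two(self):
        labels, groups, rng = _grouped_labels(6, 5, ["a", "b"])
        split = group_stratified_holdout(labels, groups, seed=rng)
        for c in ("a", "b"):
            tr = (labels[split.train_idx] == c).sum()
            te = (labels[split.test_idx] == c).sum()
            assert (tr, te) == (20, 10)  # 4 groups train, 2 test per class

    def test_class_proportions_stable_over_seeds(self):
        labels, groups, _ = _grouped_labels(12, 5, ["a", "b", "c"])
        overall = 1 / 3
        ok = 0
        for seed in range(40):
            split = group_stratified_holdout(labels, groups, seed=seed)
            dev = max(
                abs((labels[idx] == c).mean() - overall)
                for idx in (split.train_idx, split.test_idx)
                for c in ("a", "b", "c")
            )
            ok += dev <= 0.05
        assert ok >= 38

    def test_single_group_class_forced_to_training(self):
        labels = np.array(["a"] * 10 + ["b"] * 4)
        groups = np.array([0] * 5 + [1] * 5 + [2] * 4)
        with pytest.warns(UserWarning):
            split = group_stratified_holdout(labels, groups, seed=1)
        assert set(labels[split.train_idx]) >= {"b"}
        assert "b" not in labels[split.test_idx]


def _blobs(rng, n_per_class, centers, spread=0.3):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(loc=c, scale=spread, size=(n_per_class, len(c))))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestOneVsOneSVM:
    def test_pairwise_model_count(self, rng):
        X, y = _blobs(rng, 12, {"a": (0, 0), "b": (4, 0), "c": (0, 4), "d": (4, 4)})
        model = OneVsOneSVM(C=10, sigma=1.0).fit(X, y)
        assert model.n_pairs == 4 * 3 // 2

    def test_separable_training_accuracy(self, rng):
        X, y = _blobs(rng, 20, {"a": (0, 0), "b": (5, 0), "c": (0, 5)})
        model = OneVsOneSVM(C=10, sigma=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_far_positive_point(self, rng):
        X, y = _blobs(rng, 20, {"lo": (0, 0), "hi": (6, 6)})
        model = OneVsOneSVM(C=10, sigma=1.0).fit(X, y)
        assert model.predict(np.array([[6.2, 5.9]]))[0] == "hi"

    def test_tie_broken_by_decision_then_order(self, rng):
        # craft a 4-class vote tie by querying the centroid of a symmetric
        # layout: every class wins its "far" duel, votes can tie 2-2-1-1
        X, y = _blobs(rng, 25, {"a": (0, 0), "b": (4, 0), "c": (0, 4), "d": (4, 4)})
        model = OneVsOneSVM(C=10, sigma=1.0).fit(X, y)
        query = np.array([[2.0, 2.0]])
        pred = model.predict(query)[0]
        votes = {c: 0 for c in model.classes_}
        scores = {c: 0.0 for c in model.classes_}
        for (p, q), dec in model.decision_table(query).items():
            winner = q if dec[0] > 0 else p
            votes[winner] += 1
            scores[q] += dec[0]
            scores[p] -= dec[0]
        best = max(votes.values())
        tied = [c for c in model.classes_ if votes[c] == best]
        expect = max(tied, key=lambda c: (scores[c], -model.classes_.index(c)))
        assert pred == expect


class TestGridSearchCV:
    def test_separable_blobs_reach_perfect_cv(self, rng):
        X, y = _blobs(rng, 20, {"a": (0, 0), "b": (6, 6)})
        grid = HyperGrid(C_exponents=(0.0, 2.0), sigma_exponents=(-1.0, 0.0, 1.0))
        res = grid_search_cv(X, y, grid=grid, k=4, seed=5)
        assert max(res.surface.values()) == 1.0
        assert res.cv_accuracy == 1.0

    def test_deterministic_per_seed(self, rng):
        X, y = _blobs(rng, 15, {"a": (0, 0), "b": (2.0, 0), "c": (0, 2.0)}, spread=0.8)
        grid = HyperGrid(C_exponents=(0.0, 3.0), sigma_exponents=(0.0, 1.0))
        r1 = grid_search_cv(X, y, grid=grid, k=3, seed=42)
        r2 = grid_search_cv(X, y, grid=grid, k=3, seed=42)
        assert (r1.best_C_exp, r1.best_sigma_exp) == (r2.best_C_exp, r2.best_sigma_exp)
        assert r1.surface == r2.surface

    def test_refined_best_not_worse_than_coarse(self, rng):
        X, y = _blobs(rng, 15, {"a": (0, 0), "b": (1.5, 0)}, spread=0.9)
        grid = HyperGrid(C_exponents=(0.0, 2.0, 4.0), sigma_exponents=(-1.0, 1.0))
        res = grid_search_cv(X, y, grid=grid, k=3, seed=7)
        coarse_best = max(
            res.surface[(c, s)] for c in grid.C_exponents for s in grid.sigma_exponents
        )
        assert res.cv_accuracy >= coarse_best

    def test_too_few_per_class_rejected(self, rng):
        X, y = _blobs(rng, 3, {"a": (0, 0), "b": (3, 3)})
        with pytest.raises(ValueError):
            grid_search_cv(X, y, k=10, seed=0)


class TestTrainedModel:
    def test_predict_requires_schema(self, rng):
        import pandas as pd

        X, y = _blobs(rng, 20, {"a": (0, 0), "b": (4, 4)})
        model = train_model(X, y, ["f0", "f1"], C=10, sigma=1.0)
        df_ok = pd.DataFrame(X, columns=["f0", "f1"])
        assert set(model.predict(df_ok)) <= {"a", "b"}
        with pytest.raises(ValueError):
            model.predict(pd.DataFrame(X[:, :1], columns=["f0"]))

    def test_selected_names_resolve(self, rng):
        X, y = _blobs(rng, 25, {"a": (0, 0), "b": (4, 4)})
        noise = rng.standard_normal((X.shape[0], 3))
        Xn = np.hstack([noise[:, :1], X, noise[:, 1:]])
        names = ["n0", "f0", "f1", "n1", "n2"]
        model = train_model(Xn, y, names, C=10, sigma=1.0)
        assert set(model.selected_names) <= set(names)
        assert {"f0", "f1"} & set(model.selected_names)
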