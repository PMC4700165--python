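"""First-order, co-occurrence and run-length texture features, checked
against brute-force enumerations and hand-evaluated cases."""

import numpy as np
import pytest

from hrctex.classical import (
    DIRECTIONS,
    CooccurrenceMatrix,
    cooccurrence_matrix,
    first_order_features,
    haralick_features,
    histogram,
    run_length_features,
    run_length_matrix,
)
from hrctex.patches import QuantizedPatch


def qp(levels, L=None):
    levels = np.asarray(levels, dtype=np.int64)
    return QuantizedPatch(levels=levels, L=L or int(levels.max()) + 1)


# ---------------------------------------------------------------- oracles

def brute_glcm(levels, L, offset, symmetric):
    """Count pixel pairs with an explicit double loop."""
    rows, cols = levels.shape
    counts = np.zeros((L, L))
    offsets = [offset, (-offset[0], -offset[1])] if symmetric else [offset]
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[levels[r, c], levels[r2, c2]] += 1
    return counts / counts.sum()


def brute_rlm(levels, L, theta):
    """Scan every line pixel by pixel, counting maximal runs."""
    rows, cols = levels.shape
    dr, dc = DIRECTIONS[theta]
    # starting points: cells with no predecessor along (dr, dc)
    starts = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if not (0 <= r - dr < rows and 0 <= c - dc < cols)
    ]
    runs = []
    for r, c in starts:
        line = []
        while 0 <= r < rows and 0 <= c < cols:
            line.append(levels[r, c])
            r, c = r + dr, c + dc
        k = 0
        while k < len(line):
            j = k
            while j < len(line) and line[j] == line[k]:
                j += 1
            runs.append((line[k], j - k))
            k = j
    n_max = max(length for _, length in runs)
    R = np.zeros((L, n_max), dtype=np.int64)
    for a, length in runs:
        R[a, length - 1] += 1
    return R


def brute_haralick(P):
    """Second, independent evaluation of the six co-occurrence sums."""
    L = P.shape[0]
    out = {"asm": 0.0, "entropy": 0.0, "idm": 0.0, "contrast": 0.0}
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    cross = 0.0
    var = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            out["asm"] += p * p
            if p > 0:
                out["entropy"] -= p * np.log2(p)
            out["idm"] += p / (1 + (i - j) ** 2)
            out["contrast"] += (i - j) ** 2 * p
            cross += i * j * p
            var += (i - mu_x) ** 2 * p
    out["correlation"] = (cross - mu_x * mu_y) / (sx * sy) if sx * sy > 0 else 0.0
    out["variance"] = var
    return out


# ------------------------------------------------------------ first order

class TestFirstOrder:
    def test_constant_patch(self):
        f = first_order_features(histogram(qp(np.full((8, 8), 3), L=8)))
        assert f["variance"] == 0 and f["energy"] == 1 and f["entropy"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["mean"] == 3

    def test_two_equal_levels(self):
        lv = np.zeros((4, 4), dtype=int)
        lv[:, 2:] = 5
        f = first_order_features(histogram(qp(lv, L=8)))
        assert f["entropy"] == pytest.approx(1.0)
        assert f["mean"] == pytest.approx(2.5)

    def test_matches_direct_formula(self, rng):
        lv = rng.integers(0, 32, size=(40, 40))
        h = np.bincount(lv.ravel(), minlength=32) / 1600
        f = first_order_features(histogram(qp(lv, L=32)))
        z = np.arange(32)
        mean = (z * h).sum()
        var = ((z - mean) ** 2 * h).sum()
        assert f["mean"] == pytest.approx(mean)
        assert f["variance"] == pytest.approx(var)
        assert f["skewness"] == pytest.approx(((z - mean) ** 3 * h).sum() / var**1.5)
        assert f["kurtosis"] == pytest.approx(((z - mean) ** 4 * h).sum() / var**2)
        assert f["energy"] == pytest.approx((h**2).sum())
        nz = h[h > 0]
        assert f["entropy"] == pytest.approx(-(nz * np.log2(nz)).sum())


# ----------------------------------------------------------- co-occurrence

class TestCooccurrence:
    def test_constant_patch_point_mass(self):
        cm = cooccurrence_matrix(qp(np.full((5, 5), 2), L=4), (0, 1))
        assert cm.P[2, 2] == 1.0
        assert cm.P.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_case(self):
        cm = cooccurrence_matrix(qp([[0, 1], [0, 1]]), (0, 1), symmetric=True)
        assert cm.P[0, 1] == pytest.approx(0.5)
        assert cm.P[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("theta", sorted(DIRECTIONS))
    def test_matches_brute_force(self, theta, rng):
        lv = rng.integers(0, 6, size=(12, 12))
        q = qp(lv, L=6)
        cm = cooccurrence_matrix(q, DIRECTIONS[theta], symmetric=True)
        np.testing.assert_allclose(
            cm.P, brute_glcm(lv, 6, DIRECTIONS[theta], True), atol=1e-12
        )

    def test_symmetric_matrix_equals_transpose(self, rng):
        q = qp(rng.integers(0, 8, size=(15, 15)), L=8)
        cm = cooccurrence_matrix(q, (-1, 1), symmetric=True)
        np.testing.assert_array_equal(cm.P, cm.P.T)

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_matrix(qp(np.zeros((4, 4), dtype=int), L=2), (0, 4))

    def test_translation_invariance(self, rng):
        lv = rng.integers(0, 5, size=(20, 20))
        a = cooccurrence_matrix(qp(lv[:10, :10], L=5), (0, 1))
        b = cooccurrence_matrix(qp(lv[5:15, 3:13], L=5), (0, 1))
        # same content at a different location gives the same matrix
        c = cooccurrence_matrix(qp(lv[:10, :10].copy(), L=5), (0, 1))
        np.testing.assert_array_equal(a.P, c.P)
        assert a.P.shape == b.P.shape


class TestHaralick:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = haralick_features(CooccurrenceMatrix(P=P, offset=(0, 1), symmetric=True))
        assert f == {
            "asm": 1.0, "entropy": 0.0, "idm": 1.0,
            "correlation": 0.0, "contrast": 0.0, "variance": 0.0,
        }

    def test_checkerboard_hand_values(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(CooccurrenceMatrix(P=P, offset=(0, 1), symmetric=True))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["idm"] == pytest.approx(0.5)
        assert f["asm"] == pytest.approx(0.5)

    def test_matches_independent_evaluation(self, rng):
        counts = rng.integers(0, 20, size=(6, 6)).astype(float)
        counts = counts + counts.T  # valid symmetric matrix
        P = counts / counts.sum()
        f = haralick_features(CooccurrenceMatrix(P=P, offset=(0, 1), symmetric=True))
        expected = brute_haralick(P)
        for k, v in expected.items():
            assert f[k] == pytest.approx(v), k


# -------------------------------------------------------------- run length

class TestRunLength:
    def test_single_full_run(self):
        q = qp(np.full((1, 8), 3), L=6)
        rlm = run_length_matrix(q, 0)
        assert rlm.R[3, 7] == 1
        assert rlm.R.sum() == 1

    def test_alternating_line(self):
        q = qp(np.array([[0, 1, 0, 1, 0, 1, 0, 1]]), L=2)
        rlm = run_length_matrix(q, 0)
        assert rlm.R[0, 0] == 4 and rlm.R[1, 0] == 4

    def test_unsupported_direction(self):
        with pytest.raises(ValueError):
            run_length_matrix(qp(np.zeros((4, 4), dtype=int), L=2), 30)

    @pytest.mark.parametrize("theta", sorted(DIRECTIONS))
    def test_matches_brute_force(self, theta, rng):
        lv = rng.integers(0, 4, size=(12, 12))
        got = run_length_matrix(qp(lv, L=4), theta).R
        exp = brute_rlm(lv, 4, theta)
        # matrices may differ in trailing all-zero columns
        n = max(got.shape[1], exp.shape[1])
        np.testing.assert_array_equal(
            np.pad(got, ((0, 0), (0, n - got.shape[1]))),
            np.pad(exp, ((0, 0), (0, n - exp.shape[1]))),
        )

    @pytest.mark.parametrize("theta", sorted(DIRECTIONS))
    def test_pixel_conservation(self, theta, rng):
        lv = rng.integers(0, 5, size=(17, 17))
        rlm = run_length_matrix(qp(lv, L=5), theta)
        r = np.arange(1, rlm.R.shape[1] + 1)
        assert (rlm.R * r).sum() == lv.size


class TestRunLengthFeatures:
    def test_single_run_closed_forms(self):
        q = qp(np.full((1, 40), 2), L=6)
        f = run_length_features(run_length_matrix(q, 0))
        assert f["sre"] == pytest.approx(1 / 1600)
        assert f["lre"] == pytest.approx(1600)
        assert f["rp"] == pytest.approx(1 / 40)
        assert f["lgre"] == pytest.approx(1 / 9)  # gray level 2 -> 1-based 3
        assert f["hgre"] == pytest.approx(9)

    def test_all_unit_runs(self):
        q = qp(np.array([[0, 1, 0, 1, 0, 1, 0, 1]]), L=2)
        f = run_length_features(run_length_matrix(q, 0))
        assert f["rp"] == 1 and f["sre"] == 1 and f["lre"] == 1

    def test_matches_formula_on_brute_matrix(self, rng):
        lv = rng.integers(0, 4, size=(12, 12))
        R = brute_rlm(lv, 4, 45).astype(float)
        f = run_length_features(run_length_matrix(qp(lv, L=4), 45))
        n_runs = R.sum()
        a = np.arange(1, R.shape[0] + 1)[:, None]
        r = np.arange(1, R.shape[1] + 1)[None, :]
        assert f["sre"] == pytest.approx((R / r**2).sum() / n_runs)
        assert f["gln"] == pytest.approx((R.sum(axis=1) ** 2).sum() / n_runs)
        assert f["rln"] == pytest.approx((R.sum(axis=0) ** 2).sum() / n_runs)
        assert f["lrhge"] == pytest.approx((R * a**2 * r**2).sum() / n_runs)

    def test_empty_matrix_rejected(self):
        from hrctex.classical import RunLengthMatrix

        with pytest.raises(ValueError):
            run_length_features(RunLengthMatrix(R=np.zeros((2, 2), dtype=np.int64), theta=0, n_pixels=4))
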