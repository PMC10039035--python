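"""PCA, OLS, two-block PLS, covariance-ratio modularity, rank-sum."""

import numpy as np
import pytest

from otolith import (
    modularity_cr,
    ols_regress,
    regression_battery,
    shape_pca,
    two_block_pls,
    wilcoxon_rank_sum,
    gpa,
)
from otolith.pipeline import default_pc1_battery, default_size_battery

from conftest import random_rotation


class TestShapePca:
    def test_single_direction_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        scores = rng.normal(size=10)
        X = np.outer(scores, direction)
        res = shape_pca(X)
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 24))
        res = shape_pca(X)
        direct = np.sum((X - X.mean(axis=0)) ** 2) / (12 - 1)
        assert res.eigenvalues.sum() == pytest.approx(direct, abs=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 15))
        res = shape_pca(X)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.abs(res.eigenvalues - eig[: len(res.eigenvalues)]).max() < 1e-9

    def test_loadings_orthonormal_and_sign_stable(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 12))
        res = shape_pca(X)
        G = res.loadings @ res.loadings.T
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-10
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_regress(x, 2 * x)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.p_value < 1e-12

    def test_hand_computed_four_points(self):
        # normal equations by hand: x=1..4, y=2,4,5,9
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 9])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        sse = np.sum((y - intercept - slope * x) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        fit = ols_regress(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_type_one_error_nominal(self):
        rng = np.random.default_rng(4)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(size=12), rng.normal(size=12)
            rej += ols_regress(x, y).p_value < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_regress(np.ones(5), np.arange(5.0))


class TestTwoBlockPls:
    def test_identical_blocks_fully_integrated(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 8))
        res = two_block_pls(X, X.copy(), n_perm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-10)

    def test_type_one_error_nominal(self):
        rej = 0
        reps = 400
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            A, B = rng.normal(size=(12, 6)), rng.normal(size=(12, 6))
            rej += two_block_pls(A, B, n_perm=199, seed=s).p_value < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_first_pair_matches_grid_search(self):
        # brute-force maximization of score covariance over dense unit vectors
        rng = np.random.default_rng(6)
        A, B = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        res = two_block_pls(A, B, n_perm=99, seed=0)
        Ac, Bc = A - A.mean(0), B - B.mean(0)
        best = (-np.inf, None, None)
        ts = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        for ta in ts[::5]:
            u = np.array([np.cos(ta), np.sin(ta)])
            sa = Ac @ u
            # optimal v given u is the normalized cross-covariance response
            v = Bc.T @ sa
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            v /= nv
            cov = np.abs(np.dot(sa, Bc @ v))
            if cov > best[0]:
                best = (cov, u, v)
        _, u_grid, v_grid = best
        ang_u = np.arccos(np.clip(abs(np.dot(u_grid, res.left_vector)), 0, 1))
        ang_v = np.arccos(np.clip(abs(np.dot(v_grid, res.right_vector)), 0, 1))
        assert ang_u < 1e-2 and ang_v < 1e-2

    def test_effect_size_zero_for_permuted_observed(self):
        # using a permuted dataset as "observed" should give z near 0
        rng = np.random.default_rng(7)
        A, B = rng.normal(size=(12, 5)), rng.normal(size=(12, 5))
        zs = [
            two_block_pls(A, B[np.random.default_rng(s).permutation(12)],
                          n_perm=199, seed=s).effect_size_z
            for s in range(40)
        ]
        assert abs(np.mean(zs)) < 0.5

    def test_pvalue_floor_and_determinism(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=12)
        A = np.outer(f, rng.normal(size=5)) + 0.01 * rng.normal(size=(12, 5))
        B = np.outer(f, rng.normal(size=5)) + 0.01 * rng.normal(size=(12, 5))
        r1 = two_block_pls(A, B, n_perm=199, seed=3)
        r2 = two_block_pls(A, B, n_perm=199, seed=3)
        assert r1.p_value == r2.p_value and r1.r_pls == r2.r_pls
        assert r1.p_value >= 1.0 / 200.0

    def test_zero_variance_block_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            two_block_pls(np.zeros((6, 4)), np.random.default_rng(0).normal(size=(6, 4)))


class TestModularityCr:
    def test_zero_cross_covariance_gives_zero(self):
        # two landmarks per module moving in exactly orthogonal coordinate
        # subspaces with independent scores
        rng = np.random.default_rng(9)
        n = 40
        A = np.zeros((n, 2, 3))
        B = np.zeros((n, 2, 3))
        A[:, 0, 0] = rng.normal(size=n)
        A[:, 1, 1] = A[:, 0, 0]
        B[:, 0, 2] = rng.normal(size=n)
        B[:, 1, 0] = B[:, 0, 2]
        # remove empirical cross-covariance exactly by symmetrizing the draws
        A = np.concatenate([A, A], axis=0)
        B = np.concatenate([B, -B], axis=0)
        res = modularity_cr(A, B, n_perm=99, seed=0)
        assert res.cr == pytest.approx(0.0, abs=1e-10)

    def test_single_common_factor_mostly_non_significant(self):
        # factor-model simulation: one shared factor, iid landmark loadings
        hits = 0
        reps = 30
        for s in range(reps):
            rng = np.random.default_rng(100 + s)
            f = rng.normal(size=12)
            Pa, Pb = rng.normal(size=(20, 3)), rng.normal(size=(24, 3))
            A = 0.1 * f[:, None, None] * Pa[None] + 0.005 * rng.normal(size=(12, 20, 3))
            B = 0.1 * f[:, None, None] * Pb[None] + 0.005 * rng.normal(size=(12, 24, 3))
            res = modularity_cr(A, B, n_perm=199, seed=s)
            hits += res.p_value >= 0.05
            assert 0.8 < res.cr < 1.2
        assert hits >= int(0.85 * reps)

    def test_two_factor_modular_simulation_detected(self):
        hits = 0
        reps = 30
        for s in range(reps):
            rng = np.random.default_rng(200 + s)
            fa, fb = rng.normal(size=12), rng.normal(size=12)
            Pa, Pb = rng.normal(size=(20, 3)), rng.normal(size=(24, 3))
            A = 0.1 * fa[:, None, None] * Pa[None] + 0.005 * rng.normal(size=(12, 20, 3))
            B = 0.1 * fb[:, None, None] * Pb[None] + 0.005 * rng.normal(size=(12, 24, 3))
            res = modularity_cr(A, B, n_perm=199, seed=s)
            hits += (res.cr < 1.0) and (res.p_value < 0.05)
        assert hits >= int(0.9 * reps)

    def test_invariant_to_rotation_and_scale(self):
        rng = np.random.default_rng(10)
        A, B = rng.normal(size=(10, 5, 3)), rng.normal(size=(10, 6, 3))
        base = modularity_cr(A, B, n_perm=99, seed=1).cr
        R = random_rotation(rng)
        rot = modularity_cr(A @ R, B @ R, n_perm=99, seed=1).cr
        scl = modularity_cr(3.7 * A, 3.7 * B, n_perm=99, seed=1).cr
        assert rot == pytest.approx(base, rel=1e-9)
        assert scl == pytest.approx(base, rel=1e-9)

    def test_small_module_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="at least 2"):
            modularity_cr(rng.normal(size=(8, 1, 3)), rng.normal(size=(8, 5, 3)))


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        # all C(6,3)=20 assignments of {1..6}: the observed split {1,2,3} vs
        # {4,5,6} is one of the two most extreme -> two-sided p = 2/20
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_large_sample_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=30)
        b = rng.normal(size=35) + 0.4
        stat, p = wilcoxon_rank_sum(a, b)
        # independent permutation p-value on the rank-sum statistic
        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        obs = ranks[: a.size].sum()
        mu = a.size * (len(pooled) + 1) / 2
        count = 0
        n_perm = 10_000
        for s in range(n_perm):
            perm = np.random.default_rng(s).permutation(len(pooled))
            count += abs(ranks[perm[: a.size]].sum() - mu) >= abs(obs - mu) - 1e-9
        p_perm = (1 + count) / (n_perm + 1)
        assert abs(p - p_perm) < 0.01


class TestRegressionBattery:
    def test_full_battery_shape(self, landmark_population):
        specimens, _ = landmark_population
        aligned = gpa([s.config for s in specimens])
        pc1 = regression_battery(aligned, default_pc1_battery())
        size = regression_battery(aligned, default_size_battery())
        assert len(pc1) == 11 and len(size) == 15
        assert (pc1["error"] == "").all() and (size["error"] == "").all()
        assert pc1["r_squared"].between(0, 1).all()

    def test_self_regression_of_size_is_perfect(self, landmark_population):
        specimens, _ = landmark_population
        aligned = gpa([s.config for s in specimens])
        labels = [f"LM{i}" for i in range(1, 7)]
        table = regression_battery(
            aligned, [("self", labels, labels, "log_centroid_size")]
        )
        assert table["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_empty_subset_recorded_not_raised(self, landmark_population):
        specimens, _ = landmark_population
        aligned = gpa([s.config for s in specimens])
        table = regression_battery(
            aligned,
            [("bad", [], ["LM1"], "pc1"), ("ok", ["LM1", "LM2", "LM3"], ["LM4", "LM5", "LM6"], "pc1")],
        )
        assert table["error"].iloc[0] != ""
        assert table["error"].iloc[1] == ""
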