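"""Centroid size, ordinary/generalized Procrustes, block subsetting."""

import numpy as np
import pytest

from otolith import centroid_size, gpa, landmark_set, opa_align, subset_blocks
from otolith.landmarks import InvalidConfigurationError, full_scheme_template

from conftest import make_config, random_rotation


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        cfg = make_config([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)])
        assert centroid_size(cfg) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        assert centroid_size(make_config(3 * pts)) == pytest.approx(
            3 * centroid_size(make_config(pts)), rel=1e-14
        )

    def test_pairwise_distance_identity(self):
        # CS^2 = (1/k) sum_{i<j} ||x_i - x_j||^2, an independent formula
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        k = 10
        pair = sum(
            np.sum((pts[i] - pts[j]) ** 2) for i in range(k) for j in range(i + 1, k)
        )
        assert centroid_size(make_config(pts)) ** 2 == pytest.approx(pair / k, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        R = random_rotation(rng)
        moved = pts @ R + rng.normal(size=3)
        assert centroid_size(make_config(moved)) == pytest.approx(
            centroid_size(make_config(pts)), rel=1e-12
        )

    def test_rejects_degenerate_input(self):
        with pytest.raises(InvalidConfigurationError):
            centroid_size(np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(InvalidConfigurationError):
            make_config([(0, 0, 0), (1, 0, np.nan), (0, 1, 0)])


class TestOpaAlign:
    def test_similarity_copy_has_zero_distance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        R = random_rotation(rng)
        moved = 2.3 * (pts @ R) + np.array([1.0, -2.0, 0.5])
        aligned, dist = opa_align(make_config(moved), make_config(pts))
        assert dist <= 1e-10
        assert np.abs(aligned.points - pts).max() < 1e-9

    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        aligned, dist = opa_align(make_config(pts), make_config(pts))
        assert dist <= 1e-12
        assert np.abs(aligned.points - pts).max() < 1e-12

    def test_distance_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        _, d_ab = opa_align(make_config(a), make_config(b))
        _, d_ba = opa_align(make_config(b), make_config(a))
        assert d_ab == pytest.approx(d_ba, abs=1e-12)

    def test_rejects_collinear(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        rng = np.random.default_rng(6)
        with pytest.raises(InvalidConfigurationError):
            opa_align(make_config(line), make_config(rng.normal(size=(5, 3))))


def _brute_force_opa_residual(moving, fixed, coarse=24, refine=3):
    """Best unit-size residual over a dense axis-angle rotation grid, refined."""
    M = moving - moving.mean(axis=0)
    F = fixed - fixed.mean(axis=0)
    M /= np.sqrt((M**2).sum())
    F /= np.sqrt((F**2).sum())

    def rot(axis, angle):
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)

    # coarse grid over axis directions (Fibonacci sphere) and angles
    i = np.arange(coarse * 4)
    ga = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - 2 * (i + 0.5) / (coarse * 4)
    r = np.sqrt(1 - z**2)
    axes = np.column_stack([r * np.cos(ga), r * np.sin(ga), z])
    angles = np.linspace(0, np.pi, coarse, endpoint=True)
    best = (np.inf, None, None)
    for ax in axes:
        for an in angles:
            resid = np.linalg.norm(M @ rot(ax, an).T - F)
            if resid < best[0]:
                best = (resid, ax, an)
    # local refinement around the best cell
    _, ax0, an0 = best
    for _ in range(refine):
        span_ax, span_an = 0.4, 0.3
        for ax in [ax0 + span_ax * d for d in
                   np.vstack([np.zeros(3), np.eye(3), -np.eye(3),
                              np.random.default_rng(0).normal(size=(10, 3)) * 0.5])]:
            if np.linalg.norm(ax) < 1e-9:
                continue
            for an in np.linspace(an0 - span_an, an0 + span_an, 13):
                resid = np.linalg.norm(M @ rot(ax, an).T - F)
                if resid < best[0]:
                    best = (resid, ax, an)
        _, ax0, an0 = best
        span_ax *= 0.5
        span_an *= 0.5
    return best[0]


def test_opa_matches_brute_force_rotation_search():
    """Closed-form OPA equals a dense rotation-grid search on random pairs."""
    rng = np.random.default_rng(42)
    for _ in range(5):  # a larger batch runs in the acceptance suite
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        _, d_closed = opa_align(make_config(a), make_config(b))
        d_grid = _brute_force_opa_residual(a, b)
        assert d_closed <= d_grid + 1e-9  # closed form is optimal
        assert abs(d_closed - d_grid) < 5e-3  # grid approaches it


class TestGpa:
    def test_transformed_copies_align_exactly(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        configs = []
        for i in range(3):
            R = random_rotation(rng)
            configs.append(
                make_config(1.7 * (pts @ R) + rng.normal(size=3), specimen_id=f"s{i}")
            )
        res = gpa(configs)
        assert np.sum((res.coords - res.consensus) ** 2) < 1e-20
        assert res.converged

    def test_consensus_is_pointwise_mean(self):
        rng = np.random.default_rng(8)
        configs = [make_config(rng.normal(size=(6, 3)), specimen_id=f"s{i}") for i in range(4)]
        res = gpa(configs)
        assert np.allclose(res.consensus, res.coords.mean(axis=0))

    def test_two_specimens_match_pairwise_opa(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        res = gpa([make_config(a, "a"), make_config(b, "b")])
        _, d_pair = opa_align(make_config(a), make_config(b))
        d_gpa = np.linalg.norm(res.coords[0] - res.coords[1])
        # for two shapes the GPA residual reproduces the pairwise distance
        assert d_gpa == pytest.approx(d_pair, rel=1e-4)

    def test_mean_distance_grows_with_noise(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(8, 3)) * 2.0
        means = []
        for sigma in (0.01, 0.05, 0.1):
            local = np.random.default_rng(123)
            configs = [
                make_config(base + local.normal(scale=sigma, size=base.shape), f"s{i}")
                for i in range(12)
            ]
            res = gpa(configs)
            means.append(np.mean(np.linalg.norm(res.coords - res.consensus, axis=2)))
        assert means[0] < means[1] < means[2]

    def test_invariant_to_input_similarity_transforms(self):
        rng = np.random.default_rng(11)
        configs = [make_config(rng.normal(size=(7, 3)), f"s{i}") for i in range(5)]
        res1 = gpa(configs)
        moved = []
        for c in configs:
            R = random_rotation(rng)
            moved.append(c.with_points(0.5 * (c.points @ R) + rng.normal(size=3)))
        res2 = gpa(moved)
        # shapes agree after aligning the two consensuses
        a, _ = opa_align(
            make_config(res2.consensus, "c2"), make_config(res1.consensus, "c1")
        )
        assert np.abs(a.points - res1.consensus).max() < 1e-8

    def test_sum_of_squares_trace_non_increasing(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(10, 3))
        configs = [
            make_config(base + rng.normal(scale=0.3, size=base.shape), f"s{i}")
            for i in range(8)
        ]
        res = gpa(configs)
        trace = np.asarray(res.ss_trace)
        assert np.all(np.diff(trace) <= 1e-10)


class TestLandmarkSets:
    def test_full_scheme_has_108_points(self):
        labels, roles, curves, blocks = full_scheme_template()
        assert len(labels) == 108
        assert roles.count("single") == 22
        assert roles.count("semilandmark") == 86

    def test_set_definitions_follow_scheme(self):
        s1, s2, s3 = landmark_set(1), landmark_set(2), landmark_set(3)
        assert set(s1.included_curves) - set(s2.included_curves) == {"SemiLM2"}
        assert s3.included_curves == []
        assert "LM5" not in landmark_set(4).included_singles
        s5 = landmark_set(5)
        assert "LM5" not in s5.included_singles and "LM7" not in s5.included_singles
        s6 = landmark_set(6)
        mods = set(s6.modules.values())
        assert mods == {"greater_utricle", "greater_saccule"}

    def test_block_split_and_roundtrip(self, landmark_population):
        specimens, _ = landmark_population
        res = gpa([s.config for s in specimens])
        views = subset_blocks(res, landmark_set(1))
        assert set(views) == {"bony", "membranous"}
        bony, memb = views["bony"], views["membranous"]
        # bony view: LM1-10 + SemiLM1-2 points
        assert bony.k == 10 + 20 + 18
        assert memb.k == 12 + 16 + 16 + 16
        # recombine reproduces the original coordinates bitwise
        order = bony.labels + memb.labels
        recombined = np.concatenate([bony.coords, memb.coords], axis=1)
        idx = [order.index(l) for l in res.labels]
        assert np.array_equal(recombined[:, idx, :], res.coords)

    def test_views_are_not_independently_superimposed(self, landmark_population):
        specimens, _ = landmark_population
        res = gpa([s.config for s in specimens])
        bony = subset_blocks(res, landmark_set(1))["bony"]
        rerun = gpa([bony.configuration(i) for i in range(bony.n)])
        assert not np.allclose(rerun.coords, bony.coords, atol=1e-6)

    def test_missing_label_reported(self, landmark_population):
        specimens, _ = landmark_population
        res = gpa([s.config for s in specimens])
        sub = res.take(np.arange(20))  # drops most labels
        with pytest.raises(KeyError, match="missing"):
            subset_blocks(sub, landmark_set(1))
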