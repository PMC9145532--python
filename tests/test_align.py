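"""Generalized-mean loss, deformation field, descent and greedy assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wormalign as wa
from wormalign.align import DeformationParams, init_deformation
from wormalign.io import ValidationError


def brute_gm_loss(r1, r2, c1=None, c2=None, gamma=-6.0, eps=1e-3):
    """Scalar double-loop reference implementation of the GM loss."""
    total = 0.0
    for j in range(len(r2)):
        ds = []
        for i in range(len(r1)):
            if c1 is None or c1[i] == c2[j]:
                ds.append(max(np.linalg.norm(r1[i] - r2[j]), eps) ** gamma)
        total += (sum(ds) / len(ds)) ** (1.0 / gamma)
    return total


class TestGMLoss:
    def test_single_pair_is_distance(self):
        r1 = np.array([[0.0, 0.0, 0.0]])
        r2 = np.array([[3.0, 4.0, 0.0]])
        assert wa.gm_loss(r1, r2) == pytest.approx(5.0)

    def test_two_distance_closed_form(self):
        r1 = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        r2 = np.array([[0.0, 0, 0]])
        expected = ((1.0 ** -6 + 2.0 ** -6) / 2.0) ** (-1.0 / 6.0)
        assert wa.gm_loss(r1, r2, gamma=-6.0) == pytest.approx(expected, rel=1e-12)

    def test_strongly_negative_gamma_approaches_min(self, rng):
        """As γ → −∞ the loss approaches the sum of per-point nearest
        distances.  For finite γ the normalized power mean overshoots the
        minimum by at most the factor n^(−1/γ) (n = 20 labeled points), so at
        γ = −50 the loss is sandwiched in [min_sum, min_sum·20^(1/50)], and
        at γ = −400 it is within 1%."""
        from scipy.spatial import distance

        r1 = rng.uniform(0, 100, (20, 3))
        r2 = rng.uniform(0, 100, (20, 3))
        min_sum = distance.cdist(r2, r1).min(axis=1).sum()
        loss50 = wa.gm_loss(r1, r2, gamma=-50.0)
        assert min_sum <= loss50 <= min_sum * 20 ** (1 / 50) * (1 + 1e-9)
        loss400 = wa.gm_loss(r1, r2, gamma=-400.0)
        assert abs(loss400 - min_sum) / min_sum < 0.01
        # convergence is monotone in |γ|
        assert loss400 <= loss50

    def test_brute_force_oracle_100_instances(self, rng):
        """Vectorized loss equals the scalar double loop to 1e-9 relative."""
        for _ in range(100):
            n1, n2 = rng.integers(2, 12, 2)
            r1 = rng.uniform(0, 60, (n1, 3))
            r2 = rng.uniform(0, 60, (n2, 3))
            colored = rng.random() < 0.5
            c1 = rng.integers(0, 2, n1) if colored else None
            c2 = rng.integers(0, 2, n2) if colored else None
            if colored and not set(np.unique(c2)) <= set(np.unique(c1)):
                continue
            got = wa.gm_loss(r1, r2, c1, c2)
            ref = brute_gm_loss(r1, r2, c1, c2)
            assert got == pytest.approx(ref, rel=1e-9)

    def test_missing_color_class_errors(self):
        r = np.zeros((2, 3))
        with pytest.raises(ValidationError, match="colors"):
            wa.gm_loss(r, r, np.array([0, 0]), np.array([0, 1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 3.0))
    def test_positive_homogeneity(self, seed, lam):
        """Scaling all positions about a point by λ scales the loss by λ."""
        rng = np.random.default_rng(seed)
        r1 = rng.uniform(5, 50, (6, 3))
        r2 = rng.uniform(5, 50, (4, 3))
        base = wa.gm_loss(r1, r2, epsilon=1e-9)
        scaled = wa.gm_loss(r1 * lam, r2 * lam, epsilon=1e-9)
        assert scaled == pytest.approx(lam * base, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        r1 = rng.uniform(0, 50, (7, 3))
        r2 = rng.uniform(0, 50, (5, 3))
        base = wa.gm_loss(r1, r2)
        p1, p2 = rng.permutation(7), rng.permutation(5)
        assert wa.gm_loss(r1[p1], r2[p2]) == pytest.approx(base, rel=1e-12)

    def test_gamma2_matches_gaussian_mixture_expression(self):
        """With γ=2 the per-point term is the root-mean-square distance, the
        quantity whose square is (up to constants) minus twice a Gaussian
        log-likelihood; check the analytic expression on a 2-point instance."""
        r1 = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        r2 = np.array([[1.0, 0, 0]])
        loss = wa.gm_loss(r1, r2, gamma=2.0)
        assert loss == pytest.approx(np.sqrt((1.0 + 9.0) / 2.0), rel=1e-12)


class TestDeformationField:
    def test_zero_displacements_identity(self, rng):
        pos = rng.uniform(0, 100, (10, 3))
        p = DeformationParams(np.zeros((5, 3)), rng.uniform(0, 100, (5, 3)), 20.0)
        np.testing.assert_array_equal(wa.deformation_apply(p, pos), pos)

    def test_center_coincident_full_displacement(self):
        p = DeformationParams(np.array([[1.0, -2.0, 3.0]]), np.array([[5.0, 5.0, 5.0]]), 10.0)
        out = wa.deformation_apply(p, np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out[0], [6.0, 3.0, 8.0])

    def test_half_width_point(self):
        """At distance σ√(2 ln 2) the Gaussian kernel is exactly ½."""
        sigma = 12.0
        d = sigma * np.sqrt(2 * np.log(2))
        p = DeformationParams(np.array([[2.0, 0, 0]]), np.array([[0.0, 0, 0]]), sigma)
        out = wa.deformation_apply(p, np.array([[d, 0.0, 0.0]]))
        np.testing.assert_allclose(out[0], [d + 1.0, 0, 0], rtol=1e-12)

    def test_parameter_vector_round_trip(self, rng):
        p = DeformationParams(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)),
                              7.5, rng.normal(size=3))
        q = DeformationParams.from_vector(p.to_vector(), 4)
        np.testing.assert_allclose(q.displacements, p.displacements)
        np.testing.assert_allclose(q.centers, p.centers)
        assert q.sigma == pytest.approx(p.sigma)
        np.testing.assert_allclose(q.global_shift, p.global_shift)


class TestAlignGM:
    def test_recovers_rigid_shift(self, rng):
        atlas = rng.uniform([0, -40, -20], [400, 40, 20], (50, 3))
        moving = atlas + np.array([4.0, 3.0, 2.0])
        out, trace = wa.align_gm(moving, atlas, wa.GMConfig(seed=0))
        err = np.linalg.norm(out - atlas, axis=1)
        assert err.mean() < 0.5
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_identical_clouds_fixed_point(self, rng):
        atlas = rng.uniform(0, 200, (30, 3))
        cfg = wa.GMConfig(epsilon=1e-3)
        out, trace = wa.align_gm(atlas.copy(), atlas, cfg)
        # the loss is floored: each point's nearest distance sits at ε, so the
        # loss is n·ε up to the power-mean normalization factor n^(1/6)
        assert 30 * cfg.epsilon <= trace[0] <= 30 * cfg.epsilon * 30 ** (1 / 6) * 1.01
        assert np.linalg.norm(out - atlas, axis=1).max() < cfg.epsilon

    def test_max_iters_zero_forbidden(self):
        with pytest.raises(ValidationError):
            wa.GMConfig(max_iters=0)


class TestAlignGMRealistic:
    def test_single_gaussian_field_recovery(self, rng):
        """A known smooth deformation is undone to <1 μm at every neuron,
        with 100% downstream ID accuracy."""
        atlas = rng.uniform([0, -40, -20], [400, 40, 20], (60, 3))
        true = DeformationParams(
            np.array([[3.0, -3.0, 2.0]]), np.array([[200.0, 0.0, 0.0]]), 30.0
        )
        moving = wa.deformation_apply(true, atlas)
        out, params, _ = wa.align_gm_realistic(
            moving, atlas, wa.GMConfig(max_iters=6000, convergence_tol=1e-8),
            n_centers=125,
        )
        err = np.linalg.norm(out - atlas, axis=1)
        assert err.max() < 1.0
        a = wa.assign_ids(out, atlas)
        assert all(a.pairs[i][0] == str(i) for i in range(60))

    def test_zero_noise_keeps_displacements_small(self, rng):
        atlas = rng.uniform(0, 300, (40, 3))
        cfg = wa.GMConfig()
        out, params, _ = wa.align_gm_realistic(atlas.copy(), atlas, cfg, n_centers=8)
        assert np.linalg.norm(params.displacements, axis=1).max() < cfg.epsilon

    def test_rigid_translation_recovery(self, rng):
        atlas = rng.uniform([0, -40, -20], [400, 40, 20], (60, 3))
        moving = atlas + np.array([5.0, 5.0, 5.0])
        out, params, _ = wa.align_gm_realistic(
            moving, atlas, wa.GMConfig(max_iters=3000), n_centers=27
        )
        err = np.linalg.norm(out - atlas, axis=1)
        assert err.mean() < 0.5

    def test_nan_divergence_reported(self, rng):
        # an absurd ridge forces a non-finite loss immediately
        atlas = rng.uniform(0, 10, (5, 3))
        with pytest.raises(Exception, match="[Nn]a[Nn]|finite"):
            p = DeformationParams(
                np.full((2, 3), np.nan), np.zeros((2, 3)), 1.0
            )
            wa.align_gm_realistic(atlas + 1, atlas, init=p, n_centers=2)


class TestAssignIds:
    def test_identity_assignment(self, rng):
        atlas = wa.Atlas([f"N{i}" for i in range(10)], rng.uniform(0, 100, (10, 3)))
        a = wa.assign_ids(atlas.positions, atlas)
        assert all(a.pairs[i][0] == f"N{i}" for i in range(10))
        assert not a.unmatched

    def test_printed_3x3_example(self):
        """Greedy on [[1,2,3],[2,1,3],[5,4,0.5]] picks (3,3)=0.5 then (1,1)=1
        then (2,2)=1, as hand-simulated."""
        from wormalign.align import greedy_min_assignment

        D = np.array([[1.0, 2, 3], [2, 1, 3], [5, 4, 0.5]])
        assert greedy_min_assignment(D) == [(2, 2, 0.5), (0, 0, 1.0), (1, 1, 1.0)]

    def test_greedy_matches_exhaustive_rule(self, rng):
        """The row/col-deletion iteration equals a brute-force restatement of
        the same rule (pick the global min among admissible pairs) on random
        matrices."""
        from wormalign.align import greedy_min_assignment

        for _ in range(20):
            D = rng.uniform(0, 10, (4, 5))
            got = greedy_min_assignment(D)
            rows, cols, ref = set(), set(), []
            for _ in range(4):
                cand = [
                    (D[i, j], i, j)
                    for i in range(4) for j in range(5)
                    if i not in rows and j not in cols
                ]
                d, i, j = min(cand)
                ref.append((i, j, d))
                rows.add(i)
                cols.add(j)
            assert got == ref

    def test_color_constraint_beats_proximity(self):
        atlas = wa.Atlas(
            ["A", "B"], np.array([[0.0, 0, 0], [10.0, 0, 0]]),
            colors=np.array([0, 1]),
        )
        # the unlabeled point sits nearer A but carries B's color
        a = wa.assign_ids(np.array([[1.0, 0, 0]]), atlas, colors=np.array([1]))
        assert a.pairs[0][0] == "B"

    def test_agrees_with_hungarian_when_separated(self, rng):
        """On well-separated mutually-nearest pairs, greedy equals the
        Hungarian optimum."""
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial import distance

        for trial in range(10):
            base = rng.uniform(0, 1000, (15, 3))
            jitter = rng.normal(0, 0.5, (15, 3))
            moving = base + jitter
            D = distance.cdist(moving, base)
            rows, cols = linear_sum_assignment(D)
            hung = dict(zip(rows.tolist(), cols.tolist()))
            a = wa.assign_ids(moving, base)
            got = {i: int(name) for i, (name, _) in a.pairs.items()}
            assert got == hung

    def test_surplus_unlabeled_reported_unmatched(self, rng):
        atlas = wa.Atlas(["A"], np.zeros((1, 3)))
        a = wa.assign_ids(rng.uniform(0, 5, (3, 3)), atlas)
        assert len(a.pairs) == 1
        assert len(a.unmatched) == 2


class TestEstimators:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = wa.GMRealisticAligner(gamma=-4.0, n_centers=8, max_iters=50)
        assert clone(est).get_params()["gamma"] == -4.0
        atlas = wa.Atlas([f"N{i}" for i in range(20)], rng.uniform(0, 200, (20, 3)))
        cloud = wa.NeuronPointCloud(atlas.positions + 1.0)
        est.fit(cloud, atlas)
        assert est.transformed_.shape == (20, 3)
        assert hasattr(est, "deformation_params_")
        a = est.predict()
        assert set(a.pairs) == set(range(20))

    def test_registry(self):
        assert set(wa.registered_aligners()) >= {"gm", "gm-realistic"}
        with pytest.raises(KeyError, match="registered"):
            wa.get_aligner("nope")
        wa.register_aligner("gm-alias", wa.GeneralizedMeanAligner)
        assert "gm-alias" in wa.registered_aligners()


def test_end_to_end_rigid_perturbation_identifies_all(rng, substrate302):
    """Rigid jitter within ±5 μm, no other noise: the GM pipeline reaches
    100% ID accuracy on nearly every seed."""
    ok = 0
    n_seeds = 6
    for seed in range(n_seeds):
        jittered, _ = wa.rigid_jitter(substrate302, 5.0, seed=seed)
        est = wa.GMRealisticAligner()
        est.fit(substrate302, jittered)  # align the clean copy to the moved one
        a = wa.assign_ids(est.transformed_, jittered)
        acc = np.mean([
            a.pairs[i][0] == substrate302.names[i] for i in range(len(substrate302))
        ])
        ok += acc == 1.0
    assert ok >= 0.95 * n_seeds
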