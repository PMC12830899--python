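import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecdna3d as e
from ecdna3d.cycles import binmap_from_duplication_regions
from ecdna3d.reconstruct import (
    PoissonModel,
    circular_distance,
    circular_distance_matrix,
    init_redistribute,
    mds_initialize,
    objective,
)
from ecdna3d.simulate import collapse_indicator


class TestCircularDistance:
    def test_adjacency_wraps(self):
        assert circular_distance(0, 99, 100) == 1

    def test_self_zero(self):
        assert circular_distance(17, 17, 100) == 0

    def test_spec_arithmetic(self):
        # 0-based equivalents of the 1-based examples (10,60)->50, (10,70)->40
        assert circular_distance(9, 59, 100) == 50
        assert circular_distance(9, 69, 100) == 40

    def test_matrix_bounded(self):
        G = circular_distance_matrix(31)
        assert G.max() == 15
        assert np.array_equal(G, G.T)


class TestObjective:
    def test_equilateral_triangle_hand_value(self):
        # 3 bins on a unit triangle, alpha=-1, beta=1, C=1 everywhere:
        # each of the 3 unordered pairs contributes 1 - 1*ln(1) = 1
        X = np.array([[0.0, 0.0, 0.0],
                      [1.0, 0.0, 0.0],
                      [0.5, np.sqrt(3) / 2, 0.0]])
        C = np.ones((3, 3)) - np.eye(3)
        bm = binmap_from_duplication_regions(3, ())
        val = objective(X, -1.0, 1.0, C, bm, gamma=0.0)
        assert val == pytest.approx(3.0, abs=1e-12)

    def test_equal_spacing_regularizer_zero(self):
        # equally spaced points on a line: zero variance of spacings
        X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        C = np.ones((5, 5)) - np.eye(5)
        bm = binmap_from_duplication_regions(5, ())
        v0 = objective(X, -1.0, 1.0, C, bm, gamma=0.0)
        v1 = objective(X, -1.0, 1.0, C, bm, gamma=100.0)
        assert v1 == pytest.approx(v0)

    def test_duplicated_lambda_matches_brute_force(self):
        # 3 expanded bins, bins 0 and 2 are copies of collapsed bin 0
        bm = binmap_from_duplication_regions(4, ((0, 1), (2, 1)))
        assert bm.n_collapsed == 3
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        C = np.abs(rng.normal(size=(3, 3))) + 1
        C = (C + C.T) / 2
        alpha, beta = -1.3, 2.0
        val = objective(X, alpha, beta, C, bm, gamma=0.0)
        # brute force: lambda over copy rectangles
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        total = 0.0
        copies = bm.copies
        for i in range(3):
            for j in range(i, 3):
                # Eq. 2: full double sum over copies; for i == j both
                # orderings of a distinct copy pair contribute
                if i != j:
                    pairs = [(a, b) for a in copies[i] for b in copies[j]]
                else:
                    pairs = [(a, b) for a in copies[i] for b in copies[j]
                             if a != b]
                if not pairs:
                    continue
                lam = beta * sum(D[a, b] ** alpha for a, b in pairs)
                total += lam - C[i, j] * np.log(lam)
        assert val == pytest.approx(total, rel=1e-12)

    def test_zero_distance_errors(self):
        X = np.zeros((3, 3))
        C = np.ones((3, 3)) - np.eye(3)
        bm = binmap_from_duplication_regions(3, ())
        with pytest.raises(ValueError, match="zero distance"):
            objective(X, -1.0, 1.0, C, bm)

    def test_rigid_motion_invariance(self, rng):
        bm = binmap_from_duplication_regions(8, ())
        X = rng.normal(size=(8, 3))
        C = np.abs(rng.normal(size=(8, 8))) + 1
        C = (C + C.T) / 2
        v0 = objective(X, -1.5, 2.0, C, bm, gamma=0.7)
        # random rotation + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        v1 = objective(X @ Q + rng.normal(size=3), -1.5, 2.0, C, bm, gamma=0.7)
        assert v1 == pytest.approx(v0, rel=1e-9)


@st.composite
def small_instance(draw):
    ne = draw(st.integers(min_value=5, max_value=9))
    dup = draw(st.booleans())
    seed = draw(st.integers(min_value=0, max_value=2**20))
    return ne, dup, seed


class TestGradients:
    @settings(max_examples=15, deadline=None)
    @given(small_instance())
    def test_analytic_matches_finite_difference(self, inst):
        ne, dup, seed = inst
        regions = ((0, 1), (ne // 2, 1)) if dup else ()
        bm = binmap_from_duplication_regions(ne, regions)
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(ne, 3))
        nc = bm.n_collapsed
        C = np.abs(rng.normal(size=(nc, nc))) + 0.5
        C = (C + C.T) / 2
        model = PoissonModel(C, bm, gamma=0.3)
        alpha, beta = -1.4, 1.7
        gX = model.grad_X(X, alpha, beta)
        gab = model.grad_alpha_beta(X, alpha, beta)
        eps = 1e-6
        # spot-check a few coordinates
        for (i, k) in [(0, 0), (ne - 1, 2), (ne // 2, 1)]:
            Xp, Xm = X.copy(), X.copy()
            Xp[i, k] += eps
            Xm[i, k] -= eps
            fd = (model.objective(Xp, alpha, beta)
                  - model.objective(Xm, alpha, beta)) / (2 * eps)
            assert gX[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        for idx, d in ((0, np.array([eps, 0.0])), (1, np.array([0.0, eps]))):
            fp = model.objective(X, alpha + d[0], beta + d[1])
            fm = model.objective(X, alpha - d[0], beta - d[1])
            assert gab[idx] == pytest.approx((fp - fm) / (2 * eps),
                                             rel=1e-4, abs=1e-6)


class TestInitialization:
    def test_no_duplication_is_identity(self, rng):
        bm = binmap_from_duplication_regions(10, ())
        C = np.abs(rng.normal(size=(10, 10))) + 1
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0)
        E, info = init_redistribute(C, bm)
        assert np.allclose(E, C)

    def test_conservation_with_duplication(self, rng):
        bm = binmap_from_duplication_regions(12, ((1, 2), (7, 2)))
        nc = bm.n_collapsed
        C = np.abs(rng.normal(size=(nc, nc))) + 1
        C = (C + C.T) / 2
        E, _ = init_redistribute(C, bm)
        A = collapse_indicator(bm)
        back = A @ E @ A.T
        # off-diagonal collapsed sums conserved exactly (Eq. 1)
        off = ~np.eye(nc, dtype=bool)
        assert np.allclose(back[off], C[off])

    def test_symmetric_copies_split_evenly(self):
        # copies at 0 and 6 on a 12-circle are equidistant from bin 3
        bm = binmap_from_duplication_regions(12, ((0, 1), (6, 1)))
        nc = bm.n_collapsed
        C = np.ones((nc, nc)) - np.eye(nc)
        E, _ = init_redistribute(C, bm)
        i3 = 3  # expanded index 3 is a unique bin
        assert E[0, i3] == pytest.approx(E[6, i3])
        assert E[0, i3] + E[6, i3] == pytest.approx(C[bm.collapsed_index[0],
                                                      bm.collapsed_index[3]])

    def test_mds_recovers_circle(self):
        # wish distances generated from a known circle -> high distance PCC
        ne = 40
        t = 2 * np.pi * np.arange(ne) / ne
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros(ne)])
        bm = binmap_from_duplication_regions(ne, ())
        D = np.linalg.norm(circle[:, None] - circle[None, :], axis=2)
        beta = 5.0
        C = np.where(np.eye(ne, dtype=bool), 0.0, beta * np.where(D > 0, D, 1) ** -3.0)
        X0 = mds_initialize(C, bm, seed=0)
        assert e.distance_pcc(X0, circle) > 0.95

    def test_deterministic_given_seed(self, small_system):
        X1 = mds_initialize(small_system["normalized"], small_system["binmap"], seed=4)
        X2 = mds_initialize(small_system["normalized"], small_system["binmap"], seed=4)
        assert np.array_equal(X1, X2)


class TestFit:
    def test_trace_non_increasing(self, small_fit):
        objs = [rec[1] for rec in small_fit.trace]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_bounds_and_parameters(self, small_fit):
        assert np.all(np.abs(small_fit.coords) <= 1.0 + 1e-9)
        assert small_fit.alpha < 0
        assert small_fit.beta > 0

    def test_beats_random_structure(self, small_system, small_fit, rng):
        truth = small_system["truth"].coords
        rand = rng.uniform(-1, 1, size=truth.shape)
        rmsd_fit, pcc_fit = e.compare(truth, small_fit.coords)
        rmsd_rand, pcc_rand = e.compare(truth, rand)
        assert rmsd_fit < rmsd_rand
        assert pcc_fit > pcc_rand

    def test_alpha_recovery_small(self, small_system, small_fit):
        true_alpha = small_system["truth"].config.alpha
        assert abs(small_fit.alpha - true_alpha) / abs(true_alpha) < 0.35

    def test_fit_deterministic(self, small_system):
        cfg = e.FitConfig(n_restarts=1, max_rounds=15)
        s1 = e.fit_structure(small_system["normalized"], small_system["binmap"],
                             cfg, seed=7)
        s2 = e.fit_structure(small_system["normalized"], small_system["binmap"],
                             cfg, seed=7)
        assert np.array_equal(s1.coords, s2.coords)
        assert s1.alpha == s2.alpha

    def test_ensemble_returns_all(self, small_system):
        cfg = e.FitConfig(n_restarts=2, max_rounds=5, mode="ensemble")
        out = e.fit_structure(small_system["normalized"], small_system["binmap"],
                              cfg, seed=1)
        assert isinstance(out, list) and len(out) == 2
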