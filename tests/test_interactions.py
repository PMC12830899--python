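import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecdna3d as e
from ecdna3d.cycles import binmap_from_duplication_regions
from ecdna3d.interactions import (
    SIRecord,
    call_si,
    call_spatial_si,
    cluster_si,
    expand_matrix,
    filter_artifact_rows,
    find_crossing,
    group_and_fit,
    iqr_mask,
    reference_distance,
    rescaled_si_experiment,
)
from ecdna3d.simulate import collapse_indicator


class TestIQR:
    def test_spec_example(self):
        # {1,1,1,1,100}: IQR = 0, fences collapse to [1,1], 100 is removed
        v = np.array([1.0, 1, 1, 1, 100])
        mask = iqr_mask(v)
        assert mask.tolist() == [True, True, True, True, False]

    def test_all_equal_kept(self):
        assert iqr_mask(np.full(6, 3.0)).all()


class TestGrouping:
    def test_exact_distance_groups(self):
        vals = np.arange(12.0)
        dists = np.repeat([1, 2, 3], 4)
        groups, gop = group_and_fit(vals, dists, min_group_size=1)
        assert len(groups) == 3
        assert groups[0].n_pairs == 4
        assert (gop == np.repeat([0, 1, 2], 4)).all()

    def test_greedy_merging_respects_min_size(self):
        vals = np.ones(10)
        dists = np.arange(10)
        groups, gop = group_and_fit(vals, dists, min_group_size=4)
        assert all(g.n_pairs >= 4 for g in groups)
        assert sum(g.n_pairs for g in groups) == 10

    def test_trailing_group_merges_backward(self):
        vals = np.ones(9)
        dists = np.array([1] * 4 + [2] * 4 + [3])
        groups, _ = group_and_fit(vals, dists, min_group_size=4)
        assert sum(g.n_pairs for g in groups) == 9
        assert all(g.n_pairs >= 4 for g in groups)

    def test_moments_after_outlier_removal(self):
        vals = np.array([1.0, 1, 1, 1, 100])
        dists = np.ones(5)
        groups, _ = group_and_fit(vals, dists, min_group_size=1)
        assert groups[0].mu == 1.0
        assert groups[0].sigma2 == 0.0
        assert groups[0].n_outliers_removed == 1


class TestReferenceDistance:
    def test_same_chrom(self):
        bm = binmap_from_duplication_regions(10, (), resolution=5000)
        assert reference_distance(0, 3, bm) == 15000

    def test_clamped_at_gmax(self):
        bm = binmap_from_duplication_regions(10, (), resolution=5000)
        assert reference_distance(0, 9, bm, g_max=20000) == 20000

    def test_different_chroms_maximal(self):
        locs = [("chrA", 0), ("chrA", 5000), ("chrB", 0), ("chrB", 5000)]
        from ecdna3d.cycles import BinMap
        bm = BinMap(resolution=5000, locations=locs)
        gmax = bm.n_expanded * bm.resolution
        assert reference_distance(0, 2, bm) == gmax


class TestExpansion:
    def test_no_duplication_preserves_offdiag_up_to_ice(self, small_system,
                                                        small_fit):
        E = expand_matrix(small_system["normalized"], small_fit,
                          small_system["binmap"], run_ice=False)
        off = ~np.eye(E.shape[0], dtype=bool)
        assert np.allclose(E[off], small_system["normalized"][off])

    def test_conservation_with_duplication(self, dup_system, rng):
        bm = dup_system["binmap"]
        nc = bm.n_collapsed
        C = np.abs(rng.normal(size=(nc, nc))) + 1
        C = (C + C.T) / 2
        s = e.Structure3D(coords=rng.uniform(-1, 1, size=(bm.n_expanded, 3)),
                          alpha=-1.3, beta=5.0, gamma=0.0, objective=0.0)
        E = expand_matrix(C, s, bm, run_ice=False)
        A = collapse_indicator(bm)
        back = A @ E @ A.T
        off = ~np.eye(nc, dtype=bool)
        assert np.allclose(back[off], C[off])

    def test_ice_rows_uniform(self, dup_system, small_fit, rng):
        bm = dup_system["binmap"]
        nc = bm.n_collapsed
        C = np.abs(rng.normal(size=(nc, nc))) + 1
        C = (C + C.T) / 2
        s = e.Structure3D(coords=rng.uniform(-1, 1, size=(bm.n_expanded, 3)),
                          alpha=-1.3, beta=5.0, gamma=0.0, objective=0.0)
        E = expand_matrix(C, s, bm, run_ice=True)
        sums = E.sum(axis=1)
        assert np.allclose(sums, sums[0], rtol=1e-3)


class TestArtifactRows:
    def test_sparse_row_flagged(self, rng):
        E = np.abs(rng.normal(size=(30, 30))) + 1
        E = (E + E.T) / 2
        E[7, :] = 0
        E[:, 7] = 0
        E[7, 8] = E[8, 7] = 1  # one lonely contact
        assert 7 in filter_artifact_rows(E)

    def test_user_rows_unioned(self, rng):
        E = np.abs(rng.normal(size=(10, 10)))
        E = (E + E.T) / 2
        rows = filter_artifact_rows(E, extra_rows=(3, 5))
        assert {3, 5} <= set(rows)


def _null_matrix(ne, alpha, beta, seed):
    """Poisson matrix from a perfect circle (pure distance decay, no loops)."""
    t = 2 * np.pi * np.arange(ne) / ne
    X = np.column_stack([np.cos(t), np.sin(t), np.zeros(ne)])
    return e.sample_hic(X, alpha, beta, seed=seed), X


class TestCallSI:
    def test_planted_loop_detected(self):
        ne = 80
        E, X = _null_matrix(ne, -1.2, 8.0, seed=21)
        bm = binmap_from_duplication_regions(ne, ())
        a, b = 10, 50
        E[a, b] = E[b, a] = 20 * max(E[a, b], 1)
        si = call_si(E, bm, model="circ")
        assert any(r.a == a and r.b == b for r in si)

    def test_records_sorted_fields(self):
        ne = 40
        E, _ = _null_matrix(ne, -1.2, 8.0, seed=3)
        bm = binmap_from_duplication_regions(ne, ())
        for r in call_si(E, bm, model="circ", significant_only=False):
            assert r.a < r.b
            assert 0.0 <= r.p <= 1.0
            assert 0.0 <= r.q <= 1.0 + 1e-12

    def test_local_max_filter_subset(self):
        ne = 60
        E, _ = _null_matrix(ne, -1.2, 8.0, seed=9)
        bm = binmap_from_duplication_regions(ne, ())
        E[5, 30] = E[30, 5] = 25 * max(E[5, 30], 1)
        all_si = call_si(E, bm, model="circ")
        lm_si = call_si(E, bm, model="circ", local_max_only=True)
        assert {(r.a, r.b) for r in lm_si} <= {(r.a, r.b) for r in all_si}

    def test_ref_model_runs(self):
        ne = 40
        E, _ = _null_matrix(ne, -1.2, 8.0, seed=5)
        bm = binmap_from_duplication_regions(ne, ())
        recs = call_si(E, bm, model="ref", significant_only=False)
        assert len(recs) == ne * (ne - 1) // 2

    def test_spatial_null_circle_quiet(self):
        # on a perfect circle the genomic/spatial ratio is constant per
        # stratum, so nothing should be called
        ne = 60
        E, X = _null_matrix(ne, -1.2, 8.0, seed=2)
        bm = binmap_from_duplication_regions(ne, ())
        s = e.Structure3D(coords=X, alpha=-1.2, beta=8.0, gamma=0.0,
                          objective=0.0)
        assert call_spatial_si(E, s, bm) == []

    def test_spatial_detects_pinched_pair(self):
        ne = 60
        t = 2 * np.pi * np.arange(ne) / ne
        X = np.column_stack([np.cos(t), np.sin(t), np.zeros(ne)])
        # pinch bins 10 and 40 together spatially
        X[40] = X[10] + np.array([0.0, 0.0, 0.05])
        E = e.sample_hic(X, -1.2, 8.0, seed=4)
        bm = binmap_from_duplication_regions(ne, ())
        s = e.Structure3D(coords=X, alpha=-1.2, beta=8.0, gamma=0.0,
                          objective=0.0)
        si = call_spatial_si(E, s, bm)
        assert any({r.a, r.b} == {10, 40} for r in si)


class TestRescaled:
    def test_small_factor_invalid(self, small_system):
        # a folded structure gives overdispersed counts per stratum at the
        # native scale; scaling down by 100x collapses variance below mean
        E = small_system["raw"]
        bm = small_system["binmap"]
        out = rescaled_si_experiment(E, bm, factors=(0.01, 1.0))
        assert out[0.01]["valid"] is False
        assert out[0.01]["n_si"] is None
        assert out[1.0]["valid"] is True


class TestTopology:
    def test_cluster_partitions_nodes(self):
        si = [SIRecord(0, 1, 1, "circ", 1, 0.01, 0.01),
              SIRecord(1, 2, 1, "circ", 1, 0.01, 0.01),
              SIRecord(10, 11, 1, "circ", 1, 0.01, 0.01)]
        clusters = cluster_si(si, seed=0)
        nodes = sorted(n for c in clusters for n in c)
        assert nodes == [0, 1, 2, 10, 11]
        assert any({10, 11} <= c for c in clusters)

    def test_cluster_empty(self):
        assert cluster_si([], seed=0) == []

    def test_crossing_hand_case(self):
        si = [SIRecord(1, 5, 1, "circ", 4, 0.01, 0.01),
              SIRecord(3, 8, 1, "circ", 5, 0.01, 0.01),
              SIRecord(6, 7, 1, "circ", 1, 0.01, 0.01)]
        crossings = find_crossing(si)
        assert crossings == [((1, 5), (3, 8))]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**20),
           st.integers(min_value=2, max_value=200))
    def test_crossing_matches_brute_force(self, seed, n_si):
        rng = np.random.default_rng(seed)
        pairs = set()
        while len(pairs) < n_si:
            a, b = sorted(rng.integers(0, 60, size=2))
            if a != b:
                pairs.add((int(a), int(b)))
        si = [SIRecord(a, b, 1, "circ", 1, 0.01, 0.01) for a, b in pairs]
        got = set(find_crossing(si))
        spairs = sorted(pairs)
        expected = set()
        for i in range(len(spairs)):
            for j in range(len(spairs)):
                (x, z), (y, w) = spairs[i], spairs[j]
                if x < y < z < w:
                    expected.add(((x, z), (y, w)))
        assert got == expected
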