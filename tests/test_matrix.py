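import numpy as np
import pytest

from ecdna3d.coolio import CoolStore, write_cool
from ecdna3d.cycles import binmap_from_duplication_regions
from ecdna3d.matrix import (
    ContactMatrix,
    DenseGenomeStore,
    assemble_ecdna_matrix,
    collapse_matrix,
    ice_normalize_expanded,
    ice_normalize_generalized,
)


def random_symmetric(n, rng, low=1, high=50):
    M = rng.integers(low, high, size=(n, n)).astype(float)
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return M


class TestContactMatrix:
    def test_rejects_asymmetric(self):
        M = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix(M, kind="collapsed", state="raw", resolution=5000)

    def test_rejects_negative(self):
        M = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="non-negative"):
            ContactMatrix(M, kind="collapsed", state="raw", resolution=5000)

    def test_shape_must_match_binmap(self, rng):
        bm = binmap_from_duplication_regions(10, ((1, 2), (6, 2)))
        with pytest.raises(ValueError, match="does not match"):
            ContactMatrix(random_symmetric(10, rng), kind="collapsed",
                          state="raw", resolution=5000, binmap=bm)


class TestAssembly:
    def test_extract_reorders_minus_segments(self, rng):
        n = 6
        bins = [("chr1", 5000 * i) for i in range(n)]
        V = random_symmetric(n, rng)
        store = DenseGenomeStore(bins=bins, values=V, resolution=5000)
        from ecdna3d.cycles import EcDNACycle, Segment, build_bin_map
        cycle = EcDNACycle(
            segments=(Segment("chr1", 0, 15000, "+"),
                      Segment("chr1", 15000, 30000, "-")),
            resolution=5000)
        bm = build_bin_map(cycle)
        M = assemble_ecdna_matrix(store, bm)
        # expanded order: 0,1,2 then 5,4,3
        perm = [0, 1, 2, 5, 4, 3]
        assert np.array_equal(M.values, V[np.ix_(perm, perm)])

    def test_missing_chrom_errors(self, rng):
        store = DenseGenomeStore(bins=[("chr1", 0)],
                                 values=np.zeros((1, 1)), resolution=5000)
        from ecdna3d.cycles import EcDNACycle, Segment, build_bin_map
        cycle = EcDNACycle(segments=(Segment("chrX", 0, 5000, "+"),),
                           resolution=5000)
        with pytest.raises(KeyError, match="chrX"):
            assemble_ecdna_matrix(store, build_bin_map(cycle))

    def test_resolution_mismatch(self, rng):
        store = DenseGenomeStore(bins=[("chr1", 0)],
                                 values=np.zeros((1, 1)), resolution=10000)
        from ecdna3d.cycles import EcDNACycle, Segment, build_bin_map
        cycle = EcDNACycle(segments=(Segment("chr1", 0, 5000, "+"),),
                           resolution=5000)
        with pytest.raises(ValueError, match="resolution"):
            assemble_ecdna_matrix(store, build_bin_map(cycle))

    def test_collapse_keeps_first_copy(self, rng):
        bm = binmap_from_duplication_regions(8, ((1, 2), (5, 2)))
        V = random_symmetric(8, rng)
        # make duplicated rows identical, as assembly would
        for copies in bm.copies:
            first = copies[0]
            for other in copies[1:]:
                V[other, :] = V[first, :]
                V[:, other] = V[:, first]
        M = ContactMatrix(V, kind="expanded", state="raw",
                          resolution=5000, binmap=bm)
        C = collapse_matrix(M, bm)
        assert C.values.shape == (6, 6)
        keep = [g[0] for g in bm.copies]
        assert np.array_equal(C.values, V[np.ix_(keep, keep)])


class TestGeneralizedICE:
    def test_row_sums_hit_multiplicity_targets(self, rng):
        bm = binmap_from_duplication_regions(30, ((3, 5), (20, 5)))
        C = ContactMatrix(random_symmetric(bm.n_collapsed, rng),
                          kind="collapsed", state="raw",
                          resolution=5000, binmap=bm)
        N, r = ice_normalize_generalized(C, bm)
        targets = np.asarray(bm.multiplicities, dtype=float)
        sums = N.values.sum(axis=1)
        assert np.allclose(sums / r, targets, rtol=1e-4)

    def test_scale_r_is_total_over_nc(self, rng):
        bm = binmap_from_duplication_regions(12, ())
        V = random_symmetric(12, rng)
        C = ContactMatrix(V, kind="collapsed", state="raw",
                          resolution=5000, binmap=bm)
        _, r = ice_normalize_generalized(C, bm)
        assert r == pytest.approx(V.sum() / 12)

    def test_zero_rows_excluded(self, rng):
        bm = binmap_from_duplication_regions(10, ())
        V = random_symmetric(10, rng)
        V[4, :] = 0
        V[:, 4] = 0
        C = ContactMatrix(V, kind="collapsed", state="raw",
                          resolution=5000, binmap=bm)
        N, _ = ice_normalize_generalized(C, bm)
        assert N.meta["zero_rows"] == [4]
        assert np.all(N.values[4] == 0)

    def test_balanced_matrix_is_fixed_point(self):
        bm = binmap_from_duplication_regions(6, ())
        # constant off-diagonal matrix is already balanced
        V = np.ones((6, 6)) - np.eye(6)
        C = ContactMatrix(V, kind="collapsed", state="raw",
                          resolution=5000, binmap=bm)
        N, r = ice_normalize_generalized(C, bm)
        assert np.allclose(N.values, V / V.sum() * 6 * r)
        assert N.meta["ice_iterations"] <= 2

    def test_expanded_ice_uniform_rows(self, rng):
        E = random_symmetric(15, rng)
        out = ice_normalize_expanded(E)
        sums = out.sum(axis=1)
        assert np.allclose(sums, sums[0], rtol=1e-4)


class TestCoolRoundTrip:
    def test_write_then_read(self, rng, tmp_path):
        n = 12
        bins = [("chr1", 5000 * i) for i in range(8)] + \
               [("chr2", 5000 * i) for i in range(4)]
        V = random_symmetric(n, rng)
        path = tmp_path / "toy.cool"
        write_cool(path, bins, V, resolution=5000)
        with CoolStore(path) as store:
            assert store.resolution == 5000
            M = store.matrix_for_locations(bins)
        assert np.array_equal(M, V)

    def test_subset_and_repeats(self, rng, tmp_path):
        bins = [("chr1", 5000 * i) for i in range(6)]
        V = random_symmetric(6, rng)
        path = tmp_path / "toy.cool"
        write_cool(path, bins, V, resolution=5000)
        locs = [("chr1", 5000), ("chr1", 20000), ("chr1", 5000)]
        with CoolStore(path) as store:
            M = store.matrix_for_locations(locs)
        assert M[0, 1] == V[1, 4]
        assert M[0, 2] == V[1, 1]
        assert np.array_equal(M, M.T)

    def test_missing_bin_raises(self, rng, tmp_path):
        bins = [("chr1", 0), ("chr1", 5000)]
        path = tmp_path / "toy.cool"
        write_cool(path, bins, random_symmetric(2, rng), resolution=5000)
        with CoolStore(path) as store:
            with pytest.raises(KeyError):
                store.matrix_for_locations([("chr1", 999999)])
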