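"""Expanded-matrix construction and significant-interaction (SI) calling.

Once a structure is fitted, the observed collapsed counts are redistributed
over copy pairs in proportion to ``d_ab**alpha`` (with the *fitted* spatial
distances and decay), giving an expanded per-copy contact matrix.  Pairs of
bins whose contacts greatly exceed the expectation at their genomic distance
are then called significant under a negative-binomial model fitted per
distance stratum, with three notions of distance:

* ``ref``  — distance on the reference genome (clamped at the ecDNA size):
  captures both structural-variant-driven and conformational proximity.
* ``circ`` — circular distance along the amplicon: breakpoint junctions are
  no longer "distant", so remaining calls reflect conformation.
* ``spatial`` — the ratio of circular genomic distance to spatial distance
  in the fitted structure: calls interactions that are closer in space than
  the consensus structure explains, candidates for trans contacts between
  ecDNA copies or alternative conformations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cycles import BinMap
from .matrix import ice_normalize_expanded
from .reconstruct import Structure3D, circular_distance, circular_distance_matrix
from .simulate import collapse_indicator

log = logging.getLogger(__name__)

#: scale applied to the (continuous) spatial ratio statistic before rounding
#: onto the negative-binomial support
SPATIAL_RATIO_SCALE = 10.0


@dataclass
class SIRecord:
    a: int
    b: int                       # expanded bin indices, a < b
    count: float
    distance_model: str          # 'ref' | 'circ' | 'spatial'
    genomic_distance: float
    p: float
    q: float
    is_local_max: bool = False


@dataclass
class NBGroup:
    distances: tuple
    n_pairs: int
    mu: float
    sigma2: float
    n_outliers_removed: int

    @property
    def overdispersed(self) -> bool:
        return self.sigma2 > self.mu


def iqr_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of inliers under the Tukey fence [Q1-k*IQR, Q3+k*IQR]."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


# ---------------------------------------------------------------------------
# expansion


def expand_matrix(
    C_raw: np.ndarray,
    structure: Structure3D,
    binmap: BinMap,
    run_ice: bool = True,
) -> np.ndarray:
    """Redistribute collapsed counts over copies using fitted distances.

    Off-diagonal collapsed counts are split over their copy rectangles in
    proportion to ``d_ab**alpha`` (conserving the collapsed sums exactly);
    within-bin copy pairs are filled with the average count of unique bin
    pairs at the same circular genomic distance.  The result is then
    ICE-balanced to uniform row sums unless ``run_ice=False``.
    """
    C = np.asarray(C_raw, dtype=float)
    ne = binmap.n_expanded
    ci = np.asarray(binmap.collapsed_index)
    X = structure.coords
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    off_copy = ci[:, None] != ci[None, :]
    if np.any(D[off_copy] == 0) or np.any(
        D[(~off_copy) & ~np.eye(ne, dtype=bool)] == 0
    ):
        raise ValueError("zero distance between distinct bins in fitted structure")
    W = np.zeros_like(D)
    W[off_copy] = D[off_copy] ** structure.alpha
    A = collapse_indicator(binmap)
    denom = A @ W @ A.T
    E = np.zeros((ne, ne))
    with np.errstate(divide="ignore", invalid="ignore"):
        E[off_copy] = (
            W[off_copy]
            / denom[ci[:, None], ci[None, :]][off_copy]
            * C[ci[:, None], ci[None, :]][off_copy]
        )
    # within-bin copy pairs: average of unique pairs at the same circular distance
    G = circular_distance_matrix(ne)
    mult = np.asarray(binmap.multiplicities)
    unique_bins = np.flatnonzero(mult[ci] == 1)
    means: dict[int, float] = {}
    if len(unique_bins) >= 2:
        ug = G[np.ix_(unique_bins, unique_bins)]
        uc = C[np.ix_(ci[unique_bins], ci[unique_bins])]
        iu, ju = np.triu_indices(len(unique_bins), k=1)
        for g in np.unique(ug[iu, ju]):
            means[int(g)] = float(uc[iu, ju][ug[iu, ju] == g].mean())
    avail = np.array(sorted(means)) if means else np.array([])
    for i in range(binmap.n_collapsed):
        copies = binmap.copies[i]
        for x, a in enumerate(copies):
            for b in copies[x + 1:]:
                g = int(circular_distance(a, b, ne))
                if g in means:
                    val = means[g]
                elif len(avail):
                    val = means[int(avail[np.argmin(np.abs(avail - g))])]
                else:
                    val = 0.0
                E[a, b] = E[b, a] = val
    if run_ice:
        E = ice_normalize_expanded(E)
    return E


def reference_distance(
    a: int, b: int, binmap: BinMap, g_max: int | None = None
) -> int:
    """Genomic distance on the reference, clamped at ``g_max``.

    Bins on different chromosomes are maximally distant by definition;
    ``g_max`` defaults to the size of the ecDNA (Ne * resolution), beyond
    which few contacts are expected anyway.
    """
    if g_max is None:
        g_max = binmap.n_expanded * binmap.resolution
    ca, sa = binmap.locations[a]
    cb, sb = binmap.locations[b]
    if ca != cb:
        return int(g_max)
    return int(min(abs(sa - sb), g_max))


def filter_artifact_rows(E: np.ndarray, extra_rows=()) -> list[int]:
    """Rows with IQR-outlier-low numbers of non-zero entries.

    Such rows (mapping/binning artifacts) get their few counts inflated by
    ICE balancing and would otherwise surface as spurious SIs; they are
    excluded from calling.  User-supplied ``extra_rows`` are unioned in.
    """
    nz = (np.asarray(E) != 0).sum(axis=1)
    q1, q3 = np.percentile(nz, [25, 75])
    low = np.flatnonzero(nz < q1 - 1.5 * (q3 - q1))
    return sorted(set(low.tolist()) | set(int(r) for r in extra_rows))


# ---------------------------------------------------------------------------
# distance grouping and NB fitting


def group_and_fit(
    values: np.ndarray, distances: np.ndarray, min_group_size: int
) -> tuple[list[NBGroup], np.ndarray]:
    """Partition pairs into contiguous distance groups and fit moments.

    Pairs are sorted by distance; equal-distance blocks are merged greedily
    until each group holds at least ``min_group_size`` pairs (a trailing
    undersized group merges backward).  Group moments are computed after
    IQR outlier removal.  Returns the groups and, per input pair, the index
    of its group.
    """
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances)
    order = np.argsort(distances, kind="stable")
    sd = distances[order]
    block_starts = np.flatnonzero(np.r_[True, sd[1:] != sd[:-1]])
    block_ends = np.r_[block_starts[1:], len(sd)]
    group_of_pair = np.empty(len(values), dtype=int)
    groups: list[NBGroup] = []
    g_start = 0
    i = 0
    while i < len(block_starts):
        end = block_ends[i]
        while end - g_start < min_group_size and i + 1 < len(block_starts):
            i += 1
            end = block_ends[i]
        if end - g_start < min_group_size and groups:
            # trailing undersized group: merge backward into the last one
            prev = groups.pop()
            g_start = g_start - prev.n_pairs
        idx = order[g_start:end]
        v = values[idx]
        inliers = iqr_mask(v)
        vi = v[inliers] if inliers.any() else v
        groups.append(
            NBGroup(
                distances=tuple(np.unique(distances[idx]).tolist()),
                n_pairs=len(idx),
                mu=float(vi.mean()),
                sigma2=float(vi.var()),
                n_outliers_removed=int((~inliers).sum()),
            )
        )
        group_of_pair[idx] = len(groups) - 1
        g_start = end
        i += 1
    return groups, group_of_pair


def _tail_pvalues(values: np.ndarray, groups: list[NBGroup],
                  group_of_pair: np.ndarray) -> np.ndarray:
    """P(e >= value) under each pair's group distribution.

    Overdispersed groups use a moment-matched negative binomial; groups with
    variance <= mean fall back to Poisson (logged), the NB's limiting case.
    Continuous normalized counts are assessed at their ceiling.
    """
    p = np.empty(len(values))
    kv = np.maximum(np.ceil(values - 1e-9) - 1, -1)
    for gi, grp in enumerate(groups):
        sel = group_of_pair == gi
        if not sel.any():
            continue
        if grp.mu <= 0:
            p[sel] = 1.0
            continue
        if grp.overdispersed:
            r = grp.mu**2 / (grp.sigma2 - grp.mu)
            pr = grp.mu / grp.sigma2
            p[sel] = stats.nbinom.sf(kv[sel], r, pr)
        else:
            log.debug("group %d variance <= mean; Poisson fallback", gi)
            p[sel] = stats.poisson.sf(kv[sel], grp.mu)
    return np.clip(p, 0.0, 1.0)


def _local_max_flags(E: np.ndarray, aa: np.ndarray, bb: np.ndarray) -> np.ndarray:
    """Strictly greater than the top/bottom/left/right matrix neighbors."""
    n = E.shape[0]
    flags = np.ones(len(aa), dtype=bool)
    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        na, nb = aa + da, bb + db
        ok = (na >= 0) & (na < n) & (nb >= 0) & (nb < n)
        neighbor = np.zeros(len(aa))
        neighbor[ok] = E[na[ok], nb[ok]]
        flags &= ~ok | (E[aa, bb] > neighbor)
    return flags


def call_si(
    E: np.ndarray,
    binmap: BinMap,
    model: str = "circ",
    q_threshold: float = 0.05,
    local_max_only: bool = False,
    exclude_rows=(),
    g_max: int | None = None,
    significant_only: bool = True,
) -> list[SIRecord]:
    """Call significant interactions against a genomic-distance null.

    Pairs are stratified by circular (``circ``) or reference (``ref``)
    distance, a negative binomial is moment-fitted per stratum (reference
    strata are merged to hold at least Ne/2 pairs; circular distances all
    hold Ne pairs already), upper-tail p-values are Benjamini-Hochberg
    corrected jointly, and pairs with q below the threshold are reported —
    optionally only those that are 4-neighborhood local maxima.
    """
    E = np.asarray(E, dtype=float)
    ne = binmap.n_expanded
    bad = set(filter_artifact_rows(E, exclude_rows))
    aa, bb = np.triu_indices(ne, k=1)
    keep = np.array([a not in bad and b not in bad for a, b in zip(aa, bb)])
    aa, bb = aa[keep], bb[keep]
    counts = E[aa, bb]
    if model == "circ":
        dist = circular_distance(aa, bb, ne)
        min_group = 1
    elif model == "ref":
        dist = np.array([reference_distance(a, b, binmap, g_max) for a, b in zip(aa, bb)])
        min_group = max(1, ne // 2)
    else:
        raise ValueError("model must be 'circ' or 'ref' (use call_spatial_si for 'spatial')")
    groups, gop = group_and_fit(counts, dist, min_group)
    p = _tail_pvalues(counts, groups, gop)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    lm = _local_max_flags(E, aa, bb)
    records = [
        SIRecord(int(a), int(b), float(c), model, float(g), float(pv), float(qv), bool(f))
        for a, b, c, g, pv, qv, f in zip(aa, bb, counts, dist, p, q, lm)
    ]
    if significant_only:
        records = [r for r in records if r.q < q_threshold]
        if local_max_only:
            records = [r for r in records if r.is_local_max]
    return records


def call_spatial_si(
    E: np.ndarray,
    structure: Structure3D,
    binmap: BinMap,
    q_threshold: float = 0.05,
    exclude_rows=(),
    significant_only: bool = True,
) -> list[SIRecord]:
    """Call pairs spatially closer than their circular distance predicts.

    The statistic is the ratio of circular genomic distance to fitted
    spatial distance, stratified by circular distance.  The continuous ratio
    is scaled by a fixed constant and rounded onto the negative-binomial
    support before the tail probability is evaluated (an explicit modeling
    convention; see docs).  Zero-distance pairs are excluded.
    """
    E = np.asarray(E, dtype=float)
    ne = binmap.n_expanded
    X = structure.coords
    bad = set(filter_artifact_rows(E, exclude_rows))
    aa, bb = np.triu_indices(ne, k=1)
    keep = np.array([a not in bad and b not in bad for a, b in zip(aa, bb)])
    aa, bb = aa[keep], bb[keep]
    d = np.linalg.norm(X[aa] - X[bb], axis=1)
    ok = d > 0
    if not ok.all():
        log.warning("excluding %d zero-spatial-distance pairs", int((~ok).sum()))
    aa, bb, d = aa[ok], bb[ok], d[ok]
    g = circular_distance(aa, bb, ne).astype(float)
    ratio = np.where(g > 0, g / d, 0.0)
    scaled = ratio * SPATIAL_RATIO_SCALE / max(np.median(ratio[g > 0]), 1e-12)
    groups, gop = group_and_fit(scaled, g, min_group_size=1)
    p = _tail_pvalues(scaled, groups, gop)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    records = [
        SIRecord(int(a), int(b), float(E[a, b]), "spatial", float(gd), float(pv), float(qv))
        for a, b, gd, pv, qv in zip(aa, bb, g, p, q)
    ]
    if significant_only:
        records = [r for r in records if r.q < q_threshold]
    return records


def rescaled_si_experiment(
    E: np.ndarray,
    binmap: BinMap,
    model: str = "circ",
    factors=(0.25, 0.5, 1.0, 2.0, 4.0),
    q_threshold: float = 0.05,
) -> dict[float, dict]:
    """SI counts on globally rescaled matrices, with validity flags.

    Rescaling by ``f`` scales group means by ``f`` but variances by ``f**2``,
    so small factors break the negative-binomial overdispersion requirement;
    a factor is flagged valid only if variance exceeds the mean at >= 90% of
    distinct genomic distances, and SIs are counted only for valid factors.
    """
    ne = binmap.n_expanded
    E = np.asarray(E, dtype=float)
    aa, bb = np.triu_indices(ne, k=1)
    if model == "circ":
        dist = circular_distance(aa, bb, ne)
    else:
        dist = np.array([reference_distance(a, b, binmap) for a, b in zip(aa, bb)])
    counts = E[aa, bb]
    out: dict[float, dict] = {}
    for f in factors:
        v = counts * f
        overd = []
        for g in np.unique(dist):
            x = v[dist == g]
            if len(x) < 2:
                continue
            overd.append(x.var() > x.mean())
        valid = bool(np.mean(overd) >= 0.9) if overd else False
        entry = {"valid": valid, "n_si": None}
        if valid:
            entry["n_si"] = len(
                call_si(E * f, binmap, model=model, q_threshold=q_threshold)
            )
        out[float(f)] = entry
    return out


# ---------------------------------------------------------------------------
# downstream topology


def cluster_si(si: list[SIRecord], seed: int = 0) -> list[set[int]]:
    """Louvain communities of the interaction network (bins as nodes)."""
    import networkx as nx

    if not si:
        return []
    G = nx.Graph()
    G.add_edges_from((r.a, r.b) for r in si)
    communities = nx.community.louvain_communities(G, seed=seed)
    return [set(c) for c in communities]


def find_crossing(si: list[SIRecord]) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All interleaved SI pairs (x,z),(y,w) with x < y < z < w.

    Crossing interactions are the signature of a non-planar fold: two
    constriction-like contacts that cannot both be drawn inside a circle
    without intersecting.
    """
    pairs = sorted({(min(r.a, r.b), max(r.a, r.b)) for r in si})
    out = []
    for idx, (x, z) in enumerate(pairs):
        for y, w in pairs[idx + 1:]:
            if x < y < z < w:
                out.append(((x, z), (y, w)))
    return out
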