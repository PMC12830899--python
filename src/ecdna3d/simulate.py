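"""Synthetic ecDNA structures and Hi-C matrices for benchmarking.

Ground-truth structures are closed 3D curves built from a unit circle that is
(i) smoothly deformed by random low-order Fourier modes (so that independent
draws produce genuinely different global shapes), (ii) pinched by *topological
constrictions* — pairs of genomically remote arcs pulled spatially close,
generalizing chromatin loops — and (iii) perturbed by *local folds*, windowed
smooth displacements of short runs of consecutive bins.  Contact matrices are
then sampled entry-wise from a Poisson distribution with mean ``beta *
d**alpha`` (power-law distance decay), and duplications are emulated by
summing the contacts of designated bin ranges into a collapsed matrix.

The construction of the base curve is versioned (:data:`BASE_CURVE_VERSION`);
its two amplitude parameters (Fourier deformation, fold magnitude) are fixed
package constants chosen so that randomly paired structures sharing /not
sharing a base land in a realistic dissimilarity regime (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cycles import BinMap, binmap_from_duplication_regions

BASE_CURVE_VERSION = 1

# Fourier deformation driving the random closed curve that is projected onto
# the unit sphere: flat per-harmonic Gaussian amplitude over h = 1..HARMONICS.
DEFORM_AMPLITUDE = 1.2
DEFORM_HARMONICS = 20
# low-order modulation of the shell radius (0 keeps a pure spherical shell;
# the hook stays so mild departures from a sphere can be studied)
RADIAL_AMPLITUDE = 0.0
RADIAL_HARMONICS = 3

#: default spatial gap (pre-normalization curve units) between constriction arcs
DEFAULT_CONSTRICTION_GAP = 0.12


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated structure/matrix family."""

    ne: int = 250
    k: int = 1                      # number of topological constrictions
    constriction_gap: float = DEFAULT_CONSTRICTION_GAP
    n_local_folds: int | None = None    # default: ne // 5
    fold_magnitude: float = 1.5
    alpha: float = -1.5             # power-law decay exponent, in [-3, -0.75]
    beta: float = 5.0               # contact scale, in [1, 10]
    duplication_regions: tuple[tuple[int, int], ...] = ()
    same_local_substructure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne < 8:
            raise ValueError("ne must be >= 8")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @property
    def folds(self) -> int:
        return self.n_local_folds if self.n_local_folds is not None else max(2, self.ne // 5)


def _fourier_curve(ne_dense: int, rng: np.random.Generator) -> np.ndarray:
    """Random smooth closed curve meandering on a (gently modulated) sphere.

    A circle plus flat-spectrum random Fourier modes is projected radially
    onto the unit sphere, and the shell radius is modulated by a few
    low-order modes.  The shell keeps the mass of the structure away from
    the centroid (ecDNA folds are spheroidal rather than disk-like), and
    the mid-frequency wander decorrelates independent draws.
    """
    t = 2 * np.pi * np.arange(ne_dense) / ne_dense
    curve = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    for axis in range(3):
        for h in range(1, DEFORM_HARMONICS + 1):
            a, b = rng.normal(0.0, DEFORM_AMPLITUDE, size=2)
            curve[:, axis] += a * np.cos(h * t) + b * np.sin(h * t)
    curve /= np.linalg.norm(curve, axis=1, keepdims=True)
    radius = np.ones(ne_dense)
    for h in range(1, RADIAL_HARMONICS + 1):
        a, b = rng.normal(0.0, RADIAL_AMPLITUDE, size=2)
        radius += a * np.cos(h * t) + b * np.sin(h * t)
    return curve * radius[:, None]


def _resample_arclength(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points equally spaced in arc length."""
    closed = np.vstack([curve, curve[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = s[-1] * np.arange(n) / n
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, s, closed[:, axis])
    return out


def _circular_separation(a: int, b: int, n: int) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def _place_constrictions(
    ne: int, k: int, rng: np.random.Generator, max_tries: int = 200
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pick ``k`` pairs of disjoint arcs, each pair genomically remote (>= ne/8)."""
    if k == 0:
        return []
    width = max(4, ne // 20)
    for _ in range(max_tries):
        starts = rng.choice(ne, size=2 * k, replace=False)
        arcs = [np.arange(s, s + width) % ne for s in starts]
        flat = np.concatenate(arcs)
        if len(np.unique(flat)) != len(flat):
            continue
        pairs = [(arcs[2 * c], arcs[2 * c + 1]) for c in range(k)]
        if all(
            _circular_separation(int(p[0][0]), int(p[1][0]), ne) >= ne // 8
            for p in pairs
        ):
            return pairs
    raise ValueError(f"could not place {k} disjoint constrictions on {ne} bins")


def _taper(n: int) -> np.ndarray:
    """Cosine window, 0 at the edges, 1 in the middle."""
    return 0.5 * (1 - np.cos(2 * np.pi * (np.arange(n) + 0.5) / n))


def _pull_arcs_together(
    X: np.ndarray,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    gap: float,
    max_rounds: int = 8,
) -> np.ndarray:
    """Move each constriction arc pair toward its joint centroid until the
    mean inter-arc point distance drops to ``gap``."""
    X = X.copy()
    for arc1, arc2 in pairs:
        w1, w2 = _taper(len(arc1)), _taper(len(arc2))
        for _ in range(max_rounds):
            d = np.linalg.norm(X[arc1][:, None, :] - X[arc2][None, :, :], axis=2)
            mean_d = float(d.mean())
            if mean_d <= gap:
                break
            target = 0.5 * (X[arc1].mean(axis=0) + X[arc2].mean(axis=0))
            pull = min(0.9, 1.0 - gap / mean_d)
            X[arc1] += (w1 * pull)[:, None] * (target - X[arc1])
            X[arc2] += (w2 * pull)[:, None] * (target - X[arc2])
    return X


def _enforce_min_separation(X: np.ndarray, min_frac: float = 0.5,
                            max_rounds: int = 20) -> np.ndarray:
    """Push near-coincident bins apart (excluded volume).

    Chromatin has finite thickness: no two bins can approach much closer
    than the consecutive-bin spacing.  Pairs closer than ``min_frac`` times
    the mean consecutive spacing are symmetrically separated to that floor;
    without this, folded structures develop near-zero distances whose
    power-law contact means dwarf the rest of the matrix.
    """
    X = X.copy()
    n = X.shape[0]
    spacing = float(np.linalg.norm(np.diff(np.vstack([X, X[:1]]), axis=0), axis=1).mean())
    dmin = min_frac * spacing
    rng = np.random.default_rng(0xEC)
    for _ in range(max_rounds):
        D = squareform(pdist(X))
        np.fill_diagonal(D, np.inf)
        ii, jj = np.where(np.triu(D < dmin, k=1))
        if len(ii) == 0:
            break
        for a, b in zip(ii, jj):
            v = X[b] - X[a]
            d = np.linalg.norm(v)
            u = v / d if d > 1e-12 else rng.normal(size=3)
            if d <= 1e-12:
                u /= np.linalg.norm(u)
            shift = 0.5 * (dmin - d) * u
            X[a] -= shift
            X[b] += shift
    return X


def _normalize_bounds(X: np.ndarray) -> np.ndarray:
    """Center and scale into the cube [-1, 1]^3."""
    X = X - X.mean(axis=0)
    m = np.abs(X).max()
    return X / m if m > 0 else X


@dataclass
class GroundTruth:
    """A simulated structure plus the bookkeeping needed to regenerate it."""

    coords: np.ndarray               # (ne, 3), inside [-1, 1]^3
    config: SimConfig
    constrictions: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def ne(self) -> int:
        return self.coords.shape[0]


def simulate_base_structure(config: SimConfig) -> GroundTruth:
    """Build a base structure: deformed circle with ``k`` constrictions.

    Points are approximately equidistant in arc length (exactly so for
    ``k=0``), and constriction arc pairs end up with mean spatial distance
    at most ``constriction_gap`` (pre-normalization) while being at least
    ``ne/8`` bins apart along the circle.
    """
    rng = np.random.default_rng(config.seed)
    dense = _fourier_curve(8 * config.ne, rng)
    X = _resample_arclength(dense, config.ne)
    pairs = _place_constrictions(config.ne, config.k, rng)
    if pairs:
        X = _pull_arcs_together(X, pairs, config.constriction_gap)
        X = _enforce_min_separation(X)
    return GroundTruth(_normalize_bounds(X), config, pairs)


def add_local_folds(truth: GroundTruth, fold_seed: int | None = None) -> GroundTruth:
    """Perturb short windows of consecutive bins by smooth random displacements.

    Each fold displaces a window of 5-15 bins along a random direction with a
    cosine taper, then slides the displaced bins back onto their original
    distance from the centroid, so folds rearrange the structure along its
    spheroidal shell instead of inflating its diameter.  Windows overlapping
    a constriction arc are skipped so every fold variant of a base retains
    the base's constriction contacts; bins outside every window are unchanged
    (unless re-normalization into [-1,1]^3 is required).  Folds applied
    inside duplicated regions are mirrored between the copies when
    ``same_local_substructure`` is set.
    """
    cfg = truth.config
    seed = cfg.seed if fold_seed is None else fold_seed
    rng = np.random.default_rng((seed, 0x0F01D))
    X = truth.coords.copy()
    ne = cfg.ne
    protected = np.zeros(ne, dtype=bool)
    for arc1, arc2 in truth.constrictions:
        protected[arc1] = protected[arc2] = True
    if cfg.fold_magnitude > 0:
        center = X.mean(axis=0)
        radii = np.linalg.norm(X - center, axis=1)
        for _ in range(cfg.folds):
            width = int(rng.integers(5, 16))
            start = int(rng.integers(0, ne))
            idx = np.arange(start, start + width) % ne
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mag = cfg.fold_magnitude * rng.uniform(0.4, 1.0)
            if protected[idx].any():
                continue
            X[idx] += (mag * _taper(width))[:, None] * direction
            v = X[idx] - center
            X[idx] = center + v * (radii[idx] / np.linalg.norm(v, axis=1))[:, None]
        if cfg.duplication_regions and cfg.same_local_substructure:
            # copy each region's folded local displacement onto its duplicate
            for (s1, l1), (s2, l2) in zip(
                cfg.duplication_regions[::2], cfg.duplication_regions[1::2]
            ):
                delta = X[s1 : s1 + l1] - truth.coords[s1 : s1 + l1]
                X[s2 : s2 + l2] = truth.coords[s2 : s2 + l2] + delta
        X = _enforce_min_separation(X)
        if np.abs(X).max() > 1.0:
            X = _normalize_bounds(X)
    return GroundTruth(X, cfg, truth.constrictions)


def sample_hic(
    X: np.ndarray, alpha: float, beta: float, seed: int
) -> np.ndarray:
    """Sample a symmetric integer contact matrix with E[c] = beta * d**alpha.

    One Poisson draw per unordered bin pair; the diagonal is zero.  Raises if
    any two modeled points coincide (the power-law mean is undefined there).
    """
    if alpha >= 0 or beta <= 0:
        raise ValueError("need alpha < 0 and beta > 0")
    d = pdist(X)
    if np.any(d == 0):
        raise ValueError("coincident points: Poisson mean undefined at d = 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(beta * d**alpha)
    E = squareform(counts).astype(float)
    return E


def apply_duplication(
    E: np.ndarray,
    regions: Sequence[tuple[int, int]],
    resolution: int = 5000,
) -> tuple[np.ndarray, BinMap]:
    """Collapse an expanded matrix by summing contacts of duplicated bins.

    ``regions`` are ``(start_bin, length)`` pairs taken two at a time
    (original, duplicate).  The returned collapsed matrix satisfies the
    copy-sum identity C_ij = sum over a in R_i, b in R_j of E_ab exactly,
    and the accompanying :class:`BinMap` records the copy sets.
    """
    ne = E.shape[0]
    binmap = binmap_from_duplication_regions(ne, list(regions), resolution=resolution)
    A = collapse_indicator(binmap)
    C = A @ E @ A.T
    return C, binmap


def collapse_indicator(binmap: BinMap) -> np.ndarray:
    """0/1 matrix A (Nc x Ne) with A[i, a] = 1 iff expanded bin a is a copy of i."""
    A = np.zeros((binmap.n_collapsed, binmap.n_expanded))
    A[binmap.collapsed_index, np.arange(binmap.n_expanded)] = 1.0
    return A


# ---------------------------------------------------------------------------
# benchmark suite


def generate_benchmark_suite(
    seed: int,
    scale: float = 1.0,
    n_variants: int = 2,
    matrices_per_structure: int = 5,
) -> dict:
    """Manifest for the simulation benchmark: bases x fold variants x matrices.

    At full scale: 10 base structures for each combination of k in {1,2,3}
    constrictions and Ne in {250,500,750} bins (90 bases), ``n_variants``
    local-fold variants per base, and per structure ``matrices_per_structure``
    expanded (no duplication) plus the same number of collapsed (with
    duplication) matrices, each with alpha ~ U[-3,-0.75] and beta ~ U[1,10].
    Half of the collapsed samples share local substructure between the
    duplicated copies.  ``scale`` < 1 reduces the number of bases per cell
    proportionally (at least one).  Everything is derived deterministically
    from ``seed``; structures and matrices are realized on demand via
    :func:`realize_structure` / :func:`realize_matrices`.
    """
    rng = np.random.default_rng(seed)
    per_cell = max(1, round(10 * scale))
    structures = []
    base_id = 0
    for k in (1, 2, 3):
        for ne in (250, 500, 750):
            for _ in range(per_cell):
                base_seed = int(rng.integers(0, 2**31 - 1))
                dup_len = max(4, ne // 25)
                g1 = int(rng.integers(0, ne // 2 - dup_len))
                g2 = int(rng.integers(ne // 2, ne - dup_len))
                same = bool(base_id % 2 == 0)
                entry = {
                    "base_id": base_id,
                    "k": k,
                    "ne": ne,
                    "base_seed": base_seed,
                    "duplication_regions": [[g1, dup_len], [g2, dup_len]],
                    "same_local_substructure": same,
                    "variants": [
                        {
                            "fold_seed": int(rng.integers(0, 2**31 - 1)),
                            "matrices": [
                                {
                                    "alpha": float(rng.uniform(-3.0, -0.75)),
                                    "beta": float(rng.uniform(1.0, 10.0)),
                                    "hic_seed": int(rng.integers(0, 2**31 - 1)),
                                }
                                for _ in range(matrices_per_structure)
                            ],
                        }
                        for _ in range(n_variants)
                    ],
                }
                structures.append(entry)
                base_id += 1
    n_struct = len(structures)
    return {
        "version": BASE_CURVE_VERSION,
        "seed": seed,
        "scale": scale,
        "n_bases": n_struct,
        "n_structures": n_struct * n_variants,
        "n_matrices": n_struct * n_variants * matrices_per_structure,
        "structures": structures,
    }


def suite_rmsd_baselines(manifest: dict, n_pairs: int = 450, seed: int = 0) -> dict:
    """Random-pair RMSD baselines over a benchmark suite.

    Draws ``n_pairs`` random pairs of distinct structures sharing a base
    (same constrictions, different local folds) and ``n_pairs`` random pairs
    from different bases with matching bin counts, aligns each pair
    (Kabsch-Umeyama: centroids, max-diameter rescale, SVD rotation) and
    returns the two RMSD samples with their medians.
    """
    from .evaluate import align

    entries = manifest["structures"]
    n_variants = len(entries[0]["variants"])
    if n_variants < 2:
        raise ValueError("need at least two fold variants per base for same-base pairs")
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, int], np.ndarray] = {}

    def coords(b: int, v: int) -> np.ndarray:
        if (b, v) not in cache:
            cache[(b, v)] = realize_structure(entries[b], v).coords
        return cache[(b, v)]

    nb = len(entries)
    same = []
    for _ in range(n_pairs):
        b = int(rng.integers(nb))
        v1, v2 = rng.choice(n_variants, size=2, replace=False)
        same.append(align(coords(b, int(v1)), coords(b, int(v2))).rmsd)
    diff = []
    for _ in range(n_pairs):
        while True:
            b1, b2 = rng.integers(nb, size=2)
            if b1 != b2 and entries[b1]["ne"] == entries[b2]["ne"]:
                break
        v1, v2 = rng.integers(n_variants, size=2)
        diff.append(align(coords(int(b1), int(v1)), coords(int(b2), int(v2))).rmsd)
    return {
        "same_base_rmsd": same,
        "different_base_rmsd": diff,
        "median_same_base": float(np.median(same)),
        "median_different_base": float(np.median(diff)),
        "n_pairs": n_pairs,
    }


def _entry_config(entry: dict) -> SimConfig:
    return SimConfig(
        ne=entry["ne"],
        k=entry["k"],
        seed=entry["base_seed"],
        duplication_regions=tuple(tuple(r) for r in entry["duplication_regions"]),
        same_local_substructure=entry["same_local_substructure"],
    )


def realize_structure(entry: dict, variant: int = 0) -> GroundTruth:
    """Build one structure (base + local-fold variant) from a manifest entry."""
    base = simulate_base_structure(_entry_config(entry))
    return add_local_folds(base, fold_seed=entry["variants"][variant]["fold_seed"])


def realize_matrices(
    entry: dict, variant: int = 0, collapsed: bool = False
) -> list[tuple[np.ndarray, dict]]:
    """Sample the Hi-C matrices of one structure variant.

    Returns ``(matrix, params)`` pairs; with ``collapsed=True`` the
    duplication regions of the entry are summed into collapsed matrices.
    """
    truth = realize_structure(entry, variant)
    out = []
    for m in entry["variants"][variant]["matrices"]:
        E = sample_hic(truth.coords, m["alpha"], m["beta"], m["hic_seed"])
        if collapsed:
            C, binmap = apply_duplication(
                E, [tuple(r) for r in entry["duplication_regions"]]
            )
            out.append((C, {**m, "binmap": binmap}))
        else:
            out.append((E, dict(m)))
    return out
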