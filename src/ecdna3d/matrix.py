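"""Contact-matrix assembly, collapsing, and duplication-aware ICE balancing.

The ecDNA Hi-C matrix is carved out of a whole-genome contact store by
looking up, for every ordered pair of cycle bins, the interaction count of
the corresponding genomic bins.  Because a duplicated genomic bin appears in
several cycle positions, the assembled expanded-shape matrix has repeated
rows; dropping every repeat but the first yields the *collapsed* matrix that
sequencing actually observes.  Balancing then generalizes ICE: instead of
equalizing row sums to one, row ``i`` is driven to its copy multiplicity
``|R_i|``, so that a bin occurring twice on the amplicon carries twice the
normalized contact mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .cycles import BinMap

log = logging.getLogger(__name__)


class ContactStore(Protocol):
    """Anything that can serve whole-genome contact counts at fixed resolution."""

    resolution: int

    def matrix_for_locations(self, locations: Sequence[tuple[str, int]]) -> np.ndarray:
        """Dense symmetric counts for all pairs of the given genomic bins."""
        ...


@dataclass
class DenseGenomeStore:
    """In-memory whole-genome contact store over an explicit bin table.

    ``bins`` lists (chrom, bin_start) for every row of ``values``; useful for
    toy genomes in tests and for matrices produced by the simulator.
    """

    bins: list[tuple[str, int]]
    values: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.bins), len(self.bins)):
            raise ValueError("matrix shape does not match bin table")
        self._index = {loc: i for i, loc in enumerate(self.bins)}
        self._chroms = {c for c, _ in self.bins}

    def matrix_for_locations(self, locations: Sequence[tuple[str, int]]) -> np.ndarray:
        idx = []
        for chrom, start in locations:
            if chrom not in self._chroms:
                raise KeyError(f"chromosome {chrom!r} not present in contact store")
            try:
                idx.append(self._index[(chrom, start)])
            except KeyError:
                raise KeyError(f"bin {chrom}:{start} not present in contact store")
        idx = np.asarray(idx)
        return self.values[np.ix_(idx, idx)].astype(float)


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact matrix plus its provenance tags."""

    values: np.ndarray
    kind: str                     # 'expanded' | 'collapsed'
    state: str                    # 'raw' | 'normalized'
    resolution: int
    binmap: BinMap | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("contact matrix must be non-negative")
        self.values = v
        if self.kind not in ("expanded", "collapsed"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.binmap is not None:
            expected = (
                self.binmap.n_expanded if self.kind == "expanded" else self.binmap.n_collapsed
            )
            if v.shape[0] != expected:
                raise ValueError(
                    f"{self.kind} matrix of size {v.shape[0]} does not match binmap ({expected})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]


def assemble_ecdna_matrix(store: ContactStore, binmap: BinMap) -> ContactMatrix:
    """Extract and reassemble the expanded-shape ecDNA matrix from a store.

    Entry (a, b) is the whole-genome count between the genomic bins at cycle
    positions a and b; '-' segments were already reordered by the bin map, so
    their blocks appear with both axes reversed, and duplicated locations
    produce identical repeated rows/columns.
    """
    if store.resolution != binmap.resolution:
        raise ValueError(
            f"store resolution {store.resolution} != cycle resolution {binmap.resolution}"
        )
    values = store.matrix_for_locations(binmap.locations)
    return ContactMatrix(values, kind="expanded", state="raw",
                         resolution=binmap.resolution, binmap=binmap)


def collapse_matrix(assembled: ContactMatrix, binmap: BinMap) -> ContactMatrix:
    """Drop repeated rows/columns, keeping the smallest expanded index per location."""
    if assembled.kind != "expanded":
        raise ValueError("collapse_matrix expects an expanded-shape matrix")
    keep = [g[0] for g in binmap.copies]
    values = assembled.values[np.ix_(keep, keep)]
    return ContactMatrix(values, kind="collapsed", state=assembled.state,
                         resolution=assembled.resolution, binmap=binmap)


def ice_normalize_generalized(
    C: ContactMatrix,
    binmap: BinMap | None = None,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> tuple[ContactMatrix, float]:
    """Balance a collapsed matrix to row sums |R_i|, then restore total scale.

    Multiplicative diagonal balancing (a diagonal similarity D C D) is
    iterated until every active row sum is within ``tol`` of its multiplicity
    target.  All-zero rows are excluded from balancing and logged.  The
    balanced matrix is finally multiplied by ``r = sum(C) / Nc`` so that its
    overall interaction scale matches the raw input; ``r`` is returned
    alongside and also stored in ``meta['scale_r']``.
    """
    if C.kind != "collapsed":
        raise ValueError("generalized ICE operates on the collapsed matrix")
    binmap = binmap or C.binmap
    if binmap is None:
        raise ValueError("a bin map is required for multiplicity targets")
    V = C.values
    n = V.shape[0]
    targets = np.asarray(binmap.multiplicities, dtype=float)
    active = V.sum(axis=1) > 0
    if not active.all():
        log.warning("excluding %d all-zero rows from ICE balancing",
                    int((~active).sum()))
    bias = np.ones(n)
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        N = V / np.outer(bias, bias)
        s = N.sum(axis=1)
        ratio = np.ones(n)
        ratio[active] = s[active] / targets[active]
        residual = float(np.abs(ratio[active] - 1.0).max()) if active.any() else 0.0
        if residual < tol:
            converged = True
            break
        bias *= np.sqrt(ratio)
    if not converged and active.any():
        log.warning("ICE did not converge in %d iterations (residual %.3g)",
                    max_iter, residual)
    N = V / np.outer(bias, bias)
    r = float(V.sum() / n)
    out = ContactMatrix(
        N * r, kind="collapsed", state="normalized",
        resolution=C.resolution, binmap=binmap,
        meta={
            "scale_r": r, "ice_bias": bias, "ice_iterations": it,
            "ice_converged": converged, "ice_residual": residual,
            "zero_rows": np.flatnonzero(~active).tolist(),
        },
    )
    return out, r


def ice_normalize_expanded(
    E: np.ndarray, max_iter: int = 1000, tol: float = 1e-5
) -> np.ndarray:
    """Plain ICE on an expanded matrix: every active row balanced to sum 1,
    then rescaled by total/Ne to keep the original interaction scale."""
    V = np.asarray(E, dtype=float)
    n = V.shape[0]
    active = V.sum(axis=1) > 0
    bias = np.ones(n)
    for _ in range(max_iter):
        N = V / np.outer(bias, bias)
        ratio = np.ones(n)
        ratio[active] = N.sum(axis=1)[active]
        if not active.any() or np.abs(ratio[active] - 1.0).max() < tol:
            break
        bias *= np.sqrt(ratio)
    N = V / np.outer(bias, bias)
    return N * (V.sum() / n)
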