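"""ecDNA cycle parsing and expanded/collapsed bin index machinery.

An ecDNA amplicon is described as an ordered, oriented list of genomic
segments traversed around the circle.  Because segments may occur more than
once, a fixed-resolution binning of the cycle distinguishes *expanded* bins
(one per position along the circle, ``Ne`` in total) from *collapsed* bins
(one per distinct genomic location, ``Nc`` in total).  The :class:`BinMap`
records the correspondence, in particular the copy sets ``R[i]`` — all
expanded indices sharing the genomic location of collapsed bin ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

log = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 5000


class CycleParseError(ValueError):
    """Raised for malformed cycle files (carries the offending line number)."""


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 0-based, inclusive
    end: int    # exclusive (BED half-open)
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass(frozen=True)
class EcDNACycle:
    """Ordered, oriented genomic segments defining a circular amplicon."""

    segments: tuple[Segment, ...]
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("no segments")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.chrom for s in self.segments))


@dataclass
class BinMap:
    """Mapping between expanded bins, genomic locations, and collapsed bins.

    Attributes
    ----------
    locations:
        Per expanded bin ``a`` (0-based), the ``(chrom, bin_start)`` of the
        genomic bin it represents.  Bins inside a '-' segment appear in
        reversed genomic order so that consecutive expanded indices always
        follow the cycle traversal.
    collapsed_index:
        Expanded index ``a`` -> collapsed index ``i``.  Collapsed indices are
        assigned in order of first appearance along the cycle, which matches
        keeping, for each location, the row of the smallest expanded index.
    copies:
        Collapsed index ``i`` -> sorted tuple of expanded indices with the
        same genomic location (the copy set ``R_i``).
    """

    resolution: int
    locations: list[tuple[str, int]]
    collapsed_index: list[int] = field(default_factory=list)
    copies: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.collapsed_index:
            self._index()

    def _index(self) -> None:
        seen: dict[tuple[str, int], int] = {}
        groups: list[list[int]] = []
        self.collapsed_index = []
        for a, loc in enumerate(self.locations):
            i = seen.get(loc)
            if i is None:
                i = len(groups)
                seen[loc] = i
                groups.append([])
            groups[i].append(a)
            self.collapsed_index.append(i)
        self.copies = [tuple(g) for g in groups]

    @property
    def n_expanded(self) -> int:
        return len(self.locations)

    @property
    def n_collapsed(self) -> int:
        return len(self.copies)

    def multiplicity(self, i: int) -> int:
        return len(self.copies[i])

    @property
    def multiplicities(self) -> list[int]:
        return [len(g) for g in self.copies]

    @property
    def has_duplication(self) -> bool:
        return self.n_collapsed < self.n_expanded

    def collapsed_locations(self) -> list[tuple[str, int]]:
        return [self.locations[g[0]] for g in self.copies]

    def to_frame(self):
        """Serialize as a table (expanded_index, chrom, bin_start, collapsed_index, multiplicity)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "expanded_index": range(self.n_expanded),
                "chrom": [c for c, _ in self.locations],
                "bin_start": [s for _, s in self.locations],
                "collapsed_index": self.collapsed_index,
                "multiplicity": [
                    len(self.copies[i]) for i in self.collapsed_index
                ],
            }
        )


def parse_cycle(path: str | Path, resolution: int = DEFAULT_RESOLUTION) -> EcDNACycle:
    """Parse a BED-like cycle file into an :class:`EcDNACycle`.

    Expects >= 4 tab- or whitespace-separated columns per line:
    chrom, start, end, orientation.  Coordinates are 0-based half-open.
    Lines starting with '#' are ignored.
    """
    segments: list[Segment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise CycleParseError(
                    f"{path}, line {lineno}: expected >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, orient = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CycleParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            if orient not in ("+", "-"):
                raise CycleParseError(
                    f"{path}, line {lineno}: orientation must be '+' or '-', got {orient!r}"
                )
            if start >= end:
                raise CycleParseError(
                    f"{path}, line {lineno}: start ({start}) must be < end ({end})"
                )
            segments.append(Segment(chrom, start, end, orient))
    if not segments:
        raise CycleParseError(f"{path}: no segments")
    return EcDNACycle(tuple(segments), resolution=resolution)


def segment_bin_starts(seg: Segment, resolution: int) -> list[int]:
    """Bin starts tiled across a segment, in traversal order.

    Segment boundaries are snapped outward to the resolution grid (start
    floored, end ceiled); a '-' orientation reverses the genomic order of
    the bins.  A segment that snaps to zero bins is an error.
    """
    lo = (seg.start // resolution) * resolution
    hi = -(-seg.end // resolution) * resolution
    if (lo, hi) != (seg.start, seg.end):
        log.info(
            "segment %s:%d-%d snapped to %d-%d at %d bp resolution",
            seg.chrom, seg.start, seg.end, lo, hi, resolution,
        )
    starts = list(range(lo, hi, resolution))
    if not starts:
        raise ValueError(f"segment {seg.chrom}:{seg.start}-{seg.end} shorter than one bin")
    if seg.orientation == "-":
        starts.reverse()
    return starts


def build_bin_map(cycle: EcDNACycle) -> BinMap:
    """Tile every segment into bins (cycle traversal order) and index copies.

    Duplicated genomic locations — exact (chrom, bin_start) matches after
    snapping — collapse onto one collapsed bin; overlapping-but-offset
    segments remain distinct bins.
    """
    locations: list[tuple[str, int]] = []
    for seg in cycle.segments:
        locations.extend((seg.chrom, s) for s in segment_bin_starts(seg, cycle.resolution))
    return BinMap(resolution=cycle.resolution, locations=locations)


def duplicate_head_for_hsr(binmap: BinMap, n_bins: int = 3) -> BinMap:
    """Append copies of the first ``n_bins`` genomic locations to the map.

    Homogeneously staining regions (HSRs) formed by head-to-tail tandem
    arrays of an ecDNA unit interact across the junction; duplicating the
    first few bins of the unit lets the circular model absorb those
    junction-spanning contacts.  The collapsed dimension is unchanged.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if n_bins >= binmap.n_expanded:
        raise ValueError("n_bins must be smaller than the number of expanded bins")
    locations = list(binmap.locations) + list(binmap.locations[:n_bins])
    return BinMap(resolution=binmap.resolution, locations=locations)


def binmap_from_duplication_regions(
    n_expanded: int,
    regions: Sequence[tuple[int, int]],
    resolution: int = DEFAULT_RESOLUTION,
    chrom: str = "sim",
) -> BinMap:
    """Bin map for a simulated circle where ``regions`` come in duplicate pairs.

    ``regions`` lists ``(start_bin, length)`` pairs in expanded coordinates;
    they are taken two at a time, each consecutive pair sharing one set of
    genomic locations (second member duplicates the first).  Regions must
    not overlap.
    """
    if len(regions) % 2 != 0:
        raise ValueError("regions must come in pairs (original, duplicate)")
    spans = sorted((s, s + l) for s, l in regions)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError("duplication regions overlap")
    for s, l in regions:
        if l < 1 or s < 0 or s + l > n_expanded:
            raise ValueError(f"region ({s},{l}) out of range for Ne={n_expanded}")
    locations = [(chrom, a * resolution) for a in range(n_expanded)]
    for (s1, l1), (s2, l2) in zip(regions[::2], regions[1::2]):
        if l1 != l2:
            raise ValueError("paired duplication regions must have equal length")
        for off in range(l1):
            locations[s2 + off] = locations[s1 + off]
    return BinMap(resolution=resolution, locations=locations)
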