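"""Minimal reader/writer for the .cool/.mcool contact-matrix format.

Implements just the subset of the cooler HDF5 schema this package needs:
the ``chroms``, ``bins`` and ``pixels`` tables plus the ``bin1_offset``
index, at a single fixed resolution (multi-resolution .mcool files are
handled by descending into ``resolutions/<res>``).  Raw counts only; stored
balancing weights are ignored because normalization here is duplication-
aware and performed downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np


class CoolStore:
    """Whole-genome contact store backed by a .cool or .mcool file."""

    def __init__(self, path: str | Path, resolution: int | None = None):
        self.path = Path(path)
        self._f = h5py.File(self.path, "r")
        root = self._f
        if "resolutions" in root:
            avail = sorted(int(k) for k in root["resolutions"])
            if resolution is None:
                if len(avail) > 1:
                    raise ValueError(
                        f"{path} is multi-resolution ({avail}); pass resolution="
                    )
                resolution = avail[0]
            if str(resolution) not in root["resolutions"]:
                raise ValueError(f"resolution {resolution} not in {path} ({avail})")
            root = root[f"resolutions/{resolution}"]
        self._g = root
        chrom_names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in root["chroms/name"][:]
        ]
        bin_chrom = root["bins/chrom"][:]
        bin_start = root["bins/start"][:].astype(np.int64)
        stored_res = root.attrs.get("bin-size")
        if stored_res is None:
            diffs = np.diff(bin_start)
            stored_res = int(diffs[diffs > 0].min()) if len(diffs) else 1
        stored_res = int(stored_res)
        if resolution is not None and resolution != stored_res:
            raise ValueError(
                f"requested resolution {resolution} but file is binned at {stored_res}"
            )
        self.resolution = stored_res
        self.chroms = chrom_names
        self._bin_id = {
            (chrom_names[c], int(s)): i
            for i, (c, s) in enumerate(zip(bin_chrom, bin_start))
        }
        self._bin1_offset = root["indexes/bin1_offset"][:].astype(np.int64)
        self._bin2 = root["pixels/bin2_id"]
        self._count = root["pixels/count"]
        self.n_bins = len(bin_start)

    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "CoolStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def matrix_for_locations(self, locations: Sequence[tuple[str, int]]) -> np.ndarray:
        ids = []
        for chrom, start in locations:
            if chrom not in self.chroms:
                raise KeyError(f"chromosome {chrom!r} not present in {self.path}")
            key = (chrom, int(start))
            if key not in self._bin_id:
                raise KeyError(f"bin {chrom}:{start} not present in {self.path}")
            ids.append(self._bin_id[key])
        ids = np.asarray(ids, dtype=np.int64)
        pos_of_id: dict[int, list[int]] = {}
        for pos, b in enumerate(ids):
            pos_of_id.setdefault(int(b), []).append(pos)
        n = len(ids)
        out = np.zeros((n, n))
        for b1, rows in pos_of_id.items():
            lo, hi = self._bin1_offset[b1], self._bin1_offset[b1 + 1]
            if hi <= lo:
                continue
            b2 = self._bin2[lo:hi]
            cnt = self._count[lo:hi]
            mask = np.isin(b2, ids)
            for b2v, c in zip(b2[mask], cnt[mask]):
                for p1 in rows:
                    for p2 in pos_of_id[int(b2v)]:
                        out[p1, p2] = c
                        out[p2, p1] = c
        return out


def write_cool(
    path: str | Path,
    bins: Sequence[tuple[str, int]],
    values: np.ndarray,
    resolution: int,
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write a dense symmetric matrix over an explicit bin table as a .cool file.

    Pixels store the upper triangle (bin1_id <= bin2_id) of the non-zero
    entries, as the cooler schema prescribes.
    """
    values = np.asarray(values)
    n = len(bins)
    if values.shape != (n, n):
        raise ValueError("matrix shape does not match bin table")
    chrom_names = list(dict.fromkeys(c for c, _ in bins))
    if chrom_sizes is None:
        chrom_sizes = {
            c: max(s for cc, s in bins if cc == c) + resolution for c in chrom_names
        }
    chrom_code = {c: k for k, c in enumerate(chrom_names)}
    i1, i2 = np.triu_indices(n)
    nz = values[i1, i2] != 0
    i1, i2 = i1[nz], i2[nz]
    counts = values[i1, i2]
    order = np.lexsort((i2, i1))
    i1, i2, counts = i1[order], i2[order], counts[order]
    offsets = np.searchsorted(i1, np.arange(n + 1))
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-size"] = resolution
        f.attrs["bin-type"] = "fixed"
        f.attrs["nbins"] = n
        f.attrs["nchroms"] = len(chrom_names)
        f.attrs["nnz"] = len(counts)
        f.create_dataset("chroms/name", data=np.array(chrom_names, dtype="S32"))
        f.create_dataset(
            "chroms/length", data=np.array([chrom_sizes[c] for c in chrom_names])
        )
        f.create_dataset(
            "bins/chrom", data=np.array([chrom_code[c] for c, _ in bins], dtype=np.int32)
        )
        f.create_dataset("bins/start", data=np.array([s for _, s in bins]))
        f.create_dataset(
            "bins/end", data=np.array([s + resolution for _, s in bins])
        )
        f.create_dataset("pixels/bin1_id", data=i1.astype(np.int64))
        f.create_dataset("pixels/bin2_id", data=i2.astype(np.int64))
        f.create_dataset("pixels/count", data=counts)
        f.create_dataset("indexes/bin1_offset", data=offsets.astype(np.int64))
        chrom_ids = np.array([chrom_code[c] for c, _ in bins])
        chrom_offsets = np.searchsorted(chrom_ids, np.arange(len(chrom_names) + 1))
        f.create_dataset("indexes/chrom_offset", data=chrom_offsets.astype(np.int64))
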