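"""Text artifact readers/writers.

Every file written by the tool starts with ``#``-prefixed header lines
recording the tool version, the run seed, and a hash of the effective
configuration, so any output can be traced back to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cycles import BinMap


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def header_lines(seed: int | None = None, config: dict | None = None,
                 **extra) -> list[str]:
    lines = [f"# ecdna3d version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    for k, v in extra.items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_with_header(path: str | Path, body: str, headers: list[str]) -> None:
    Path(path).write_text("\n".join(headers) + "\n" + body)


def write_binmap(path: str | Path, binmap: BinMap, headers: list[str] = ()) -> None:
    df = binmap.to_frame()
    _write_with_header(path, df.to_csv(sep="\t", index=False), list(headers))


def read_binmap(path: str | Path) -> BinMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    resolution = int(df["bin_start"].sort_values().diff().dropna().pipe(
        lambda s: s[s > 0].min()) or 1)
    # resolution is also recoverable from the header; fall back to spacing
    for line in Path(path).read_text().splitlines():
        if line.startswith("# resolution:"):
            resolution = int(line.split(":", 1)[1])
    locations = list(zip(df["chrom"], df["bin_start"].astype(int)))
    return BinMap(resolution=resolution, locations=locations)


def write_matrix(path: str | Path, values: np.ndarray, headers: list[str] = ()) -> None:
    body = "\n".join(
        "\t".join(format(v, ".10g") for v in row) for row in np.asarray(values)
    )
    _write_with_header(path, body + "\n", list(headers))


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, comments="#")


def write_triplets(path: str | Path, values: np.ndarray, headers: list[str] = ()) -> None:
    """Non-zero upper triangle as a .cool-compatible (bin1, bin2, count) list."""
    v = np.asarray(values)
    i1, i2 = np.triu_indices(v.shape[0])
    nz = v[i1, i2] != 0
    rows = [f"{a}\t{b}\t{v[a, b]:.10g}" for a, b in zip(i1[nz], i2[nz])]
    _write_with_header(path, "bin1\tbin2\tcount\n" + "\n".join(rows) + "\n",
                       list(headers))


def write_structure(path: str | Path, structure, binmap: BinMap | None = None,
                    headers: list[str] = ()) -> None:
    """Coordinates as TSV plus a JSON sidecar with the fitted parameters."""
    path = Path(path)
    rows = []
    for i, (x, y, z) in enumerate(structure.coords):
        chrom, start = binmap.locations[i] if binmap is not None else ("", i)
        rows.append(f"{i}\t{chrom}\t{start}\t{x:.8f}\t{y:.8f}\t{z:.8f}")
    body = "bin\tchrom\tbin_start\tx\ty\tz\n" + "\n".join(rows) + "\n"
    _write_with_header(path, body, list(headers))
    sidecar = {
        "alpha": structure.alpha,
        "beta": structure.beta,
        "gamma": structure.gamma,
        "objective": structure.objective,
        "seed": structure.seed,
        "converged": structure.converged,
        "n_rounds": len(structure.trace),
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n")


def read_structure(path: str | Path) -> np.ndarray:
    """Coordinates (Ne, 3) from a structure TSV (plain xyz files also accepted)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if {"x", "y", "z"} <= set(df.columns):
        return df[["x", "y", "z"]].to_numpy(float)
    arr = df.to_numpy(float)
    return arr[:, -3:]


def write_si(path: str | Path, records, binmap: BinMap,
             clusters: list[set[int]] | None = None,
             headers: list[str] = ()) -> None:
    """BEDPE-like SI table; optional Louvain cluster id as a final column."""
    res = binmap.resolution
    member = {}
    if clusters is not None:
        for ci, c in enumerate(clusters):
            for b in c:
                member[b] = ci
    cols = ("chromA\tstartA\tendA\tchromB\tstartB\tendB\t"
            "binA\tbinB\tcount\tg\tp\tq\tmodel\tlocal_max")
    if clusters is not None:
        cols += "\tcluster"
    rows = []
    for r in records:
        ca, sa = binmap.locations[r.a]
        cb, sb = binmap.locations[r.b]
        row = (f"{ca}\t{sa}\t{sa + res}\t{cb}\t{sb}\t{sb + res}\t"
               f"{r.a}\t{r.b}\t{r.count:.6g}\t{r.genomic_distance:.6g}\t"
               f"{r.p:.4g}\t{r.q:.4g}\t{r.distance_model}\t{int(r.is_local_max)}")
        if clusters is not None:
            row += f"\t{member.get(r.a, member.get(r.b, -1))}"
        rows.append(row)
    _write_with_header(path, cols + "\n" + "\n".join(rows) + ("\n" if rows else ""),
                       list(headers))
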