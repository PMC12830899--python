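"""End-to-end orchestration: extract -> normalize -> reconstruct -> expand ->
call-si -> cluster, persisting every artifact as soon as it exists."""

from __future__ import annotations

import logging
from pathlib import Path

from .config import RunConfig
from .coolio import CoolStore
from .cycles import build_bin_map, parse_cycle
from .interactions import call_si, call_spatial_si, cluster_si, expand_matrix
from .io import header_lines, write_binmap, write_matrix, write_si, \
    write_structure, write_triplets
from .matrix import assemble_ecdna_matrix, collapse_matrix, \
    ice_normalize_generalized

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; earlier artifacts are already on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, cycle_file: str | Path,
                 matrix_file: str | Path) -> dict:
    """Run the full workflow and return the artifact paths and key objects."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = lambda **kw: header_lines(seed=config.seed,
                                    config=config.hashable_dict(), **kw)
    bundle: dict = {}

    stage = "extract"
    try:
        cycle = parse_cycle(cycle_file, resolution=config.resolution)
        binmap = build_bin_map(cycle)
        with CoolStore(matrix_file, resolution=config.resolution) as store:
            expanded = assemble_ecdna_matrix(store, binmap)
        collapsed = collapse_matrix(expanded, binmap)
        write_binmap(out / "binmap.tsv", binmap,
                     hdr(resolution=config.resolution))
        write_matrix(out / "collapsed_raw.tsv", collapsed.values, hdr())
        write_triplets(out / "collapsed_raw.triplets.tsv", collapsed.values, hdr())
        bundle.update(binmap=binmap, collapsed_raw=collapsed,
                      paths={"binmap": out / "binmap.tsv"})
        log.info("extract: Ne=%d Nc=%d", binmap.n_expanded, binmap.n_collapsed)

        stage = "normalize"
        normalized, r = ice_normalize_generalized(collapsed, binmap)
        write_matrix(out / "collapsed_normalized.tsv", normalized.values,
                     hdr(scale_r=f"{r:.6g}"))
        bundle.update(normalized=normalized, scale_r=r)

        stage = "reconstruct"
        from .reconstruct import fit_structure
        structure = fit_structure(normalized.values, binmap,
                                  config.fit_config(), seed=config.seed)
        if config.mode == "ensemble":
            for i, s in enumerate(structure):
                write_structure(out / f"structure_{i}.tsv", s, binmap, hdr())
            best = min(structure, key=lambda s: s.objective)
        else:
            best = structure
        for rec in best.trace:
            log.info("round %d: objective=%.6g alpha=%.4f beta=%.4g", *rec)
        write_structure(out / "structure.tsv", best, binmap, hdr())
        bundle.update(structure=best)
        log.info("reconstruct: alpha=%.3f beta=%.3g objective=%.6g converged=%s",
                 best.alpha, best.beta, best.objective, best.converged)

        stage = "expand"
        E = expand_matrix(normalized.values, best, binmap)
        write_matrix(out / "expanded_normalized.tsv", E, hdr())
        bundle.update(expanded=E)

        stage = "call-si"
        if config.distance_model == "spatial":
            si = call_spatial_si(E, best, binmap, q_threshold=config.q_threshold)
        else:
            si = call_si(E, binmap, model=config.distance_model,
                         q_threshold=config.q_threshold)
        bundle.update(si=si)
        log.info("call-si (%s): %d significant pairs", config.distance_model, len(si))

        stage = "cluster"
        clusters = cluster_si(si, seed=config.seed)
        write_si(out / "si.tsv", si, binmap, clusters=clusters, headers=hdr())
        bundle.update(clusters=clusters)
    except Exception as exc:          # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc
    return bundle
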