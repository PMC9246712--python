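"""End-to-end orchestration: one call from assembly (or simulation) to report.

Every stage result is kept on a single :class:`PipelineResult` stamped with
the run id (a hash of config + seed), which the report builder checks, so a
report can never silently mix outputs from different runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import arrays as arrays_mod
from . import joins as joins_mod
from . import matching, report, skew, synthetic
from .classify import ContigClass, TerminalRepeat, classify as _classify
from .classify import detect_circularity, detect_tir
from .core_io import Contig, RunConfig, log_run_header, run_id as _run_id


@dataclass
class PipelineResult:
    run_id: str
    config: RunConfig
    contigs: list[Contig]
    depths: dict[str, float] | None
    arrays: dict[str, list[arrays_mod.CrisprArray]]
    spacers: list[arrays_mod.Spacer]
    hits: list[matching.SpacerHit]
    linkage: pd.DataFrame
    repeats: dict[str, list[TerminalRepeat]]
    classifications: list[ContigClass]
    ratios: dict[str, float]
    skew_profile: skew.SkewProfile | None
    origin: int | None
    joins: list[joins_mod.JoinProposal]
    report: report.LinkageReport
    truth: synthetic.TruthSet | None = None


def run_pipeline(
    config: RunConfig | None = None,
    contigs: Sequence[Contig] | None = None,
    depths: Mapping[str, float] | None = None,
    annotations: Mapping[str, Sequence[str]] | None = None,
) -> PipelineResult:
    """Run every stage.  Without explicit contigs, a synthetic assembly is
    generated from ``config.sim`` and ``config.seed`` (with its depth table),
    and the planted truth is attached to the result."""
    cfg = config or RunConfig()
    log_run_header(cfg)
    rid = _run_id(cfg)

    truth = None
    if contigs is None:
        contigs, truth, gen_depths = synthetic.generate_assembly(cfg.sim, cfg.seed)
        if depths is None:
            depths = gen_depths
    contigs = list(contigs)
    depths = dict(depths) if depths is not None else None

    arrays = {c.id: arrays_mod.detect_arrays(c, cfg) for c in contigs}
    arrays = {cid: arrs for cid, arrs in arrays.items() if arrs}
    spacers = [sp for arrs in arrays.values() for a in arrs for sp in a.spacers]

    hits: list[matching.SpacerHit] = []
    if spacers:
        hits = matching.find_hits(
            spacers,
            contigs,
            max_mismatches=cfg.max_mismatches,
            exclude_arrays=cfg.exclude_arrays,
            arrays=arrays,
        )
    linkage = matching.summarize_linkage(hits)

    repeats: dict[str, list[TerminalRepeat]] = {}
    for c in contigs:
        found = []
        direct = detect_circularity(
            c, cfg.min_circular_overlap, cfg.circular_max_mismatch
        )
        if direct:
            found.append(direct)
        tir = detect_tir(
            c, cfg.tir_min_len, cfg.tir_min_identity, cfg.tir_max_scan
        )
        if tir:
            found.append(tir)
        if found:
            repeats[c.id] = found

    classifications = _classify(
        contigs, arrays, hits, repeats, depths, cfg, annotations
    )
    chrom_id = next(c.contig_id for c in classifications if c.label == "chromosome")

    ratios: dict[str, float] = {}
    if depths and chrom_id in depths and depths[chrom_id] > 0:
        for c in contigs:
            if c.id in depths:
                ratios[c.id] = depths[c.id] / depths[chrom_id]

    chromosome = next(c for c in contigs if c.id == chrom_id)
    profile = None
    origin = None
    if chromosome.length >= 3 * cfg.skew_window:
        profile = skew.windowed_skews(chromosome, cfg.skew_window, cfg.skew_step)
        origin = skew.find_origin(profile)

    join_props = joins_mod.propose_joins(
        contigs,
        arrays,
        min_k=cfg.min_shared_spacers,
        edge_window=cfg.edge_window,
        partial_spacer_fraction=cfg.partial_spacer_fraction,
    )

    rep = report.build_report(
        classifications,
        linkage,
        repeats,
        ratios,
        join_props,
        lengths={c.id: c.length for c in contigs},
        run_ids=[rid],
    )

    return PipelineResult(
        run_id=rid,
        config=cfg,
        contigs=contigs,
        depths=depths,
        arrays=arrays,
        spacers=spacers,
        hits=hits,
        linkage=linkage,
        repeats=repeats,
        classifications=classifications,
        ratios=ratios,
        skew_profile=profile,
        origin=origin,
        joins=join_props,
        report=rep,
        truth=truth,
    )
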