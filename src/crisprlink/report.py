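"""Host-mobilome linkage report.

Aggregates every stage output into a single machine-readable (JSON) and
human-readable (TSV) summary: one row per element with its class label,
spacer-linkage counts, terminal-repeat signature, coverage ratio, and join
or circularization flags, plus a minimal-information block per viral
element in the spirit of community uncultivated-virus reporting standards
(out-of-scope fields are emitted as ``not_computed`` rather than guessed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import ContigClass, TerminalRepeat
from .joins import JoinProposal


class RunMismatchError(ValueError):
    """Stage outputs come from different runs (run ids disagree)."""


@dataclass
class ElementRow:
    element_id: str
    label: str
    length: int
    n_exact_spacers: int
    n_one_mm_spacers: int
    terminal_repeat_kind: str  # "direct" | "inverted" | "none"
    terminal_repeat_length: int
    coverage_ratio: float | None
    join_flag: bool
    circularization_flag: bool


@dataclass
class LinkageReport:
    run_id: str
    host_contig_id: str
    rows: list[ElementRow]
    totals: dict
    miuvig: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "run_id": self.run_id,
            "host_contig_id": self.host_contig_id,
            "elements": [vars(r) for r in self.rows],
            "totals": self.totals,
            "miuvig": self.miuvig,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        df = pd.DataFrame([vars(r) for r in self.rows])
        lines = [f"# run_id: {self.run_id}", f"# host: {self.host_contig_id}"]
        lines.append(df.to_csv(sep="\t", index=False).rstrip("\n"))
        lines.append(
            "# totals\t"
            + "\t".join(f"{k}={v}" for k, v in sorted(self.totals.items()))
        )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _miuvig_block(row: ElementRow) -> dict:
    topology = {
        "circular_mobile": "circular",
        "linear_tir_mobile": "linear",
    }.get(row.label, "not_computed")
    return {
        "virus_id": row.element_id,
        "source": "metagenome-assembled",
        "assembly_software": "not_computed",
        "detection_evidence": "CRISPR spacer linkage; terminal repeat signature",
        "genome_topology": topology,
        "genome_length_nt": row.length,
        "taxonomy": "not_computed",
        "host_prediction_method": "not_computed",
        "host_evidence": f"{row.n_exact_spacers} exact + {row.n_one_mm_spacers} one-mismatch CRISPR spacer matches",
        "completeness_evidence": (
            "terminal direct repeat" if row.terminal_repeat_kind == "direct"
            else "terminal inverted repeats" if row.terminal_repeat_kind == "inverted"
            else "not_computed"
        ),
    }


def build_report(
    classifications: Sequence[ContigClass],
    linkage: pd.DataFrame,
    repeats: Mapping[str, Sequence[TerminalRepeat]],
    ratios: Mapping[str, float],
    joins: Sequence[JoinProposal],
    lengths: Mapping[str, int],
    run_ids: Sequence[str],
) -> LinkageReport:
    """Assemble the linkage report; all inputs must share one run id."""
    ids = {r for r in run_ids if r is not None}
    if len(ids) != 1:
        raise RunMismatchError(f"stage outputs from different runs: {sorted(ids)}")
    rid = ids.pop()

    host = next((c.contig_id for c in classifications if c.label == "chromosome"), None)
    if host is None:
        raise ValueError("no chromosome in classifications")

    link = {row.target_contig_id: row for row in linkage.itertuples(index=False)} if len(linkage) else {}
    joined = {p.contig_a for p in joins} | {p.contig_b for p in joins}
    circ = {p.contig_a for p in joins if p.circularization}

    rows = []
    for c in sorted(classifications, key=lambda c: c.contig_id):
        lk = link.get(c.contig_id)
        reps = list(repeats.get(c.contig_id, ()))
        rows.append(
            ElementRow(
                element_id=c.contig_id,
                label=c.label,
                length=lengths[c.contig_id],
                n_exact_spacers=int(lk.n_exact_spacers) if lk else 0,
                n_one_mm_spacers=int(lk.n_one_mm_spacers) if lk else 0,
                terminal_repeat_kind=reps[0].kind if reps else "none",
                terminal_repeat_length=reps[0].length if reps else 0,
                coverage_ratio=round(ratios[c.contig_id], 4) if c.contig_id in ratios else None,
                join_flag=c.contig_id in joined,
                circularization_flag=c.contig_id in circ,
            )
        )

    totals = {
        "n_contigs": len(rows),
        "n_mobile_elements": sum(
            r.label in ("circular_mobile", "linear_tir_mobile", "mobile_other") for r in rows
        ),
        "n_exact_spacers": sum(r.n_exact_spacers for r in rows),
        "n_one_mm_spacers": sum(r.n_one_mm_spacers for r in rows),
        "n_targeted_contigs": sum(r.n_exact_spacers + r.n_one_mm_spacers > 0 for r in rows),
        "n_join_proposals": len(joins),
    }
    miuvig = [
        _miuvig_block(r) for r in rows if r.label in ("circular_mobile", "linear_tir_mobile")
    ]
    return LinkageReport(run_id=rid, host_contig_id=host, rows=rows, totals=totals, miuvig=miuvig)


def adjacency_list(hits) -> pd.DataFrame:
    """(element, hit position) pairs for external plotting."""
    return pd.DataFrame(
        [{"element": h.target_contig_id, "position": h.start, "spacer": h.spacer_id,
          "mismatches": h.mismatches} for h in hits],
        columns=["element", "position", "spacer", "mismatches"],
    )
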