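"""Spacer-to-protospacer matching under full-query-coverage semantics.

Matches are ungapped: a spacer hits a target wherever the Hamming distance
to the equal-length window is within the mismatch budget, on either strand.
This operationalizes short-query nucleotide searches read at 100% query
coverage; indel-containing alignments are out of contract.  ``N`` in either
sequence always counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import CrisprArray, Spacer
from .core_io import Contig, revcomp

MIN_SPACER_QUERY = 15  # shorter queries are uninformative

# Encodings chosen so that equality holds only for a genuine base match:
# target N -> 4, query N -> 5, so N never equals anything (including N).
_TARGET_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _TARGET_LUT[ord(_b)] = _i
_TARGET_LUT[ord("N")] = 4
_QUERY_LUT = _TARGET_LUT.copy()
_QUERY_LUT[ord("N")] = 5


def _encode(seq: str, lut: np.ndarray) -> np.ndarray:
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SpacerHit:
    """One spacer-protospacer match: the host-virus linkage atom."""

    spacer_id: str
    target_contig_id: str
    start: int  # 0-based half-open on the forward strand of the target
    end: int
    strand: str  # "+" or "-"
    mismatches: int
    full_coverage: bool = True


def _sliding_mismatches(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of the query against every window of the target."""
    m = len(target) - len(query) + 1
    if m <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(m, dtype=np.int32)
    for j, c in enumerate(query):
        mm += target[j : j + m] != c
    return mm


def find_hits(
    spacers: Sequence[Spacer],
    targets: Sequence[Contig],
    max_mismatches: int = 1,
    exclude_arrays: bool = True,
    arrays: Mapping[str, Sequence[CrisprArray]] | None = None,
) -> list[SpacerHit]:
    """All bounded-mismatch, full-coverage hits of every spacer on every target.

    ``arrays`` maps target contig id to its detected CRISPR arrays; when
    ``exclude_arrays`` is true, hits overlapping an array span padded by one
    repeat length are removed (a spacer trivially matches its own array).
    Output is sorted by (target, position, strand, spacer).
    """
    if not spacers or not targets:
        raise ValueError("spacers and targets must be non-empty")
    for sp in spacers:
        if len(sp.seq) < MIN_SPACER_QUERY:
            raise ValueError(
                f"spacer {sp.id!r} is {len(sp.seq)} nt (< {MIN_SPACER_QUERY}): "
                "uninformative query"
            )

    hits: list[SpacerHit] = []
    for t in targets:
        n = t.length
        fwd = _encode(t.seq, _TARGET_LUT)
        rev = _encode(revcomp(t.seq), _TARGET_LUT)
        excluded: list[tuple[int, int]] = []
        if exclude_arrays and arrays:
            for arr in arrays.get(t.id, ()):
                pad = len(arr.repeat_consensus)
                excluded.append((arr.span[0] - pad, arr.span[1] + pad))
        for sp in spacers:
            q = _encode(sp.seq, _QUERY_LUT)
            L = len(q)
            for strand, enc in (("+", fwd), ("-", rev)):
                mm = _sliding_mismatches(enc, q)
                for i in np.nonzero(mm <= max_mismatches)[0]:
                    if strand == "+":
                        s, e = int(i), int(i) + L
                    else:
                        s, e = n - int(i) - L, n - int(i)
                    if any(s < xe and e > xs for xs, xe in excluded):
                        continue
                    hits.append(
                        SpacerHit(
                            spacer_id=sp.id,
                            target_contig_id=t.id,
                            start=s,
                            end=e,
                            strand=strand,
                            mismatches=int(mm[i]),
                        )
                    )
    hits.sort(key=lambda h: (h.target_contig_id, h.start, h.strand, h.spacer_id))
    return hits


def summarize_linkage(
    hits: Iterable[SpacerHit], spacers: Sequence[Spacer] | None = None
) -> pd.DataFrame:
    """Per-target linkage table.

    ``n_exact_spacers`` counts distinct spacers with at least one 0-mismatch
    hit on the target; ``n_one_mm_spacers`` counts the additional distinct
    spacers whose best hit there has exactly one mismatch.  A spacer hitting
    two targets counts toward both (the per-target columns do not
    deduplicate across targets; ``n_distinct_spacers`` of the union is what
    deduplicated totals should be computed from).
    """
    rows: dict[str, dict] = {}
    best: dict[tuple[str, str], int] = {}
    counts: dict[str, int] = {}
    for h in hits:
        key = (h.target_contig_id, h.spacer_id)
        best[key] = min(best.get(key, 99), h.mismatches)
        counts[h.target_contig_id] = counts.get(h.target_contig_id, 0) + 1
    for (target, _spacer), mm in best.items():
        row = rows.setdefault(
            target,
            {"target_contig_id": target, "n_exact_spacers": 0,
             "n_one_mm_spacers": 0, "n_hit_positions": 0, "n_distinct_spacers": 0},
        )
        row["n_distinct_spacers"] += 1
        if mm == 0:
            row["n_exact_spacers"] += 1
        elif mm == 1:
            row["n_one_mm_spacers"] += 1
    for target, row in rows.items():
        row["n_hit_positions"] = counts[target]
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["target_contig_id"]),
        columns=["target_contig_id", "n_exact_spacers", "n_one_mm_spacers",
                 "n_hit_positions", "n_distinct_spacers"],
    )
    return df


def hit_features(hits: Iterable[SpacerHit]):
    """GFF3 'protospacer' features for a hit list."""
    from .core_io import GffFeature

    return [
        GffFeature(
            seqid=h.target_contig_id,
            ftype="protospacer",
            start=h.start,
            end=h.end,
            strand=h.strand,
            attributes={"spacer": h.spacer_id, "mismatches": str(h.mismatches)},
        )
        for h in hits
    ]


def hits_to_table(hits: Iterable[SpacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "target_contig_id": h.target_contig_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["spacer_id", "target_contig_id", "start", "end", "strand", "mismatches"],
    )
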