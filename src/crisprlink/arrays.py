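"""CRISPR repeat-spacer array detection and spacer extraction.

A minimal seed-cluster-extend detector: exact k-mer seeds that recur with
near-constant spacing nucleate repeat candidates, which are extended to the
maximal repeat consensus by column majority voting over all occurrences.
Spacers are the inter-repeat gaps.  This deliberately does not reproduce a
full CRISPR scoring model (no leader inference, no orientation calls); the
pipeline only needs array coordinates and ordered spacer sequences.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .core_io import Contig, RunConfig


@dataclass
class Spacer:
    """One inter-repeat spacer, ordered within its array."""

    id: str
    array_id: str
    index_in_array: int
    seq: str
    span: tuple[int, int]  # 0-based half-open on the contig


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus.

    ``repeat_spans`` and spacer spans tile ``span`` without overlap,
    alternating, repeats first and last; ``n_repeats`` counts full repeats
    plus boundary repeats truncated by the contig edge (kept when >= 50% of
    the consensus length).
    """

    id: str
    contig_id: str
    span: tuple[int, int]
    repeat_consensus: str
    repeat_spans: list[tuple[int, int]]
    spacers: list[Spacer]
    orientation: str = "unknown"

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_spans)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _cluster_positions(
    positions: list[int], gap_lo: int, gap_hi: int, spread_max: int
) -> list[list[int]]:
    """Greedy left-to-right clustering of seed occurrences.

    Successive gaps must fall in [gap_lo, gap_hi] and stay near-constant
    (max gap - min gap <= spread_max within a cluster).
    """
    clusters: list[list[int]] = []
    cur = [positions[0]]
    gaps: list[int] = []
    for p in positions[1:]:
        g = p - cur[-1]
        if gap_lo <= g <= gap_hi and (
            not gaps or max(max(gaps), g) - min(min(gaps), g) <= spread_max
        ):
            cur.append(p)
            gaps.append(g)
        else:
            clusters.append(cur)
            cur, gaps = [p], []
    clusters.append(cur)
    return clusters


def _column(seq: str, starts: list[int], off: int) -> list[str]:
    n = len(seq)
    return [seq[p + off] for p in starts if 0 <= p + off < n]


def _column_agrees(seq: str, starts: list[int], off: int, min_agree: float) -> bool:
    # out-of-bounds occurrences (contig-edge truncations) count as
    # disagreeing votes: a column unseen by an occurrence cannot support it
    col = _column(seq, starts, off)
    if len(col) < 2:
        return False
    _, best = Counter(col).most_common(1)[0]
    return best / len(starts) >= min_agree


def _extend_cluster(seq: str, starts: list[int], k: int, cfg: RunConfig):
    """Extend a seed cluster to the maximal repeat consensus; None if invalid."""
    min_gap = min(b - a for a, b in zip(starts, starts[1:]))
    cap = min(cfg.repeat_len_max, min_gap - 1)
    lo, hi = 0, k  # offsets of the repeat relative to each seed position
    while (hi - lo) < cap and _column_agrees(seq, starts, lo - 1, cfg.column_agreement_min):
        lo -= 1
    while (hi - lo) < cap and _column_agrees(seq, starts, hi, cfg.column_agreement_min):
        hi += 1

    # boundary polish: a flanking column can clear the agreement threshold by
    # chance when occurrences are few; trim outer columns whose agreement sits
    # well below the interior consensus level
    def _agreement(off: int) -> float:
        col = _column(seq, starts, off)
        return Counter(col).most_common(1)[0][1] / len(starts) if col else 0.0

    interior = sorted(_agreement(off) for off in range(lo + 2, hi - 2))
    if interior:
        floor = interior[len(interior) // 2] - 0.1
        while hi - lo > cfg.repeat_len_min and _agreement(lo) < floor:
            lo += 1
        while hi - lo > cfg.repeat_len_min and _agreement(hi - 1) < floor:
            hi -= 1

    rep_len = hi - lo
    if rep_len < cfg.repeat_len_min:
        return None

    consensus = "".join(
        Counter(_column(seq, starts, off)).most_common(1)[0][0]
        for off in range(lo, hi)
    )

    n = len(seq)
    spans: list[tuple[int, int]] = []
    for p in starts:
        s, e = max(0, p + lo), min(n, p + hi)
        # boundary repeats truncated by the contig edge count if >= 50% long
        if e - s >= 0.5 * rep_len:
            spans.append((s, e))
    if len(spans) < cfg.min_repeats:
        return None

    # interior (full-length) repeats must stay within the identity budget
    for s, e in spans:
        if e - s == rep_len and _hamming(seq[s:e], consensus) > cfg.repeat_identity_budget * rep_len:
            return None

    spacer_spans = [(spans[i][1], spans[i + 1][0]) for i in range(len(spans) - 1)]
    for s, e in spacer_spans:
        if not (cfg.spacer_len_min <= e - s <= cfg.spacer_len_max):
            return None

    return (spans[0][0], spans[-1][1]), consensus, spans, spacer_spans


def detect_arrays(contig: Contig, cfg: RunConfig | None = None) -> list[CrisprArray]:
    """Detect CRISPR arrays on one contig; empty list when none are found.

    Seeds are exact ``seed_k``-mers occurring at least ``min_repeats`` times;
    occurrence clusters with near-constant spacing in the plausible
    repeat+spacer range are extended by column-majority consensus (stop when
    column agreement drops below ``column_agreement_min``).  Overlapping
    candidates are merged, keeping the one with more repeats.
    """
    cfg = cfg or RunConfig()
    seq = contig.seq
    n = len(seq)
    if n < 3 * cfg.repeat_len_min:
        return []

    k = cfg.seed_k
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        occ[seq[i : i + k]].append(i)

    gap_lo = cfg.repeat_len_min + cfg.spacer_len_min
    gap_hi = cfg.repeat_len_max + cfg.spacer_len_max

    candidates = []
    seen_spans: set[tuple[int, int]] = set()
    for kmer, positions in occ.items():
        if len(positions) < cfg.min_repeats or "N" in kmer:
            continue
        for cluster in _cluster_positions(positions, gap_lo, gap_hi, cfg.gap_spread_max):
            if len(cluster) < cfg.min_repeats:
                continue
            cand = _extend_cluster(seq, cluster, k, cfg)
            if cand is not None and cand[0] not in seen_spans:
                seen_spans.add(cand[0])
                candidates.append(cand)

    # merge overlapping candidates, keeping the one with more repeats
    candidates.sort(key=lambda c: (c[0][0], c[0][1]))
    merged = []
    for cand in candidates:
        if merged and cand[0][0] < merged[-1][0][1]:  # overlaps previous
            prev = merged[-1]
            better = max(
                (prev, cand),
                key=lambda c: (len(c[2]), c[0][1] - c[0][0], -c[0][0]),
            )
            merged[-1] = better
        else:
            merged.append(cand)

    arrays: list[CrisprArray] = []
    for idx, (span, consensus, rep_spans, sp_spans) in enumerate(merged):
        aid = f"{contig.id}:arr{idx + 1}"
        spacers = [
            Spacer(
                id=f"{aid}:sp{j:02d}",
                array_id=aid,
                index_in_array=j,
                seq=seq[s:e],
                span=(s, e),
            )
            for j, (s, e) in enumerate(sp_spans)
        ]
        arrays.append(
            CrisprArray(
                id=aid,
                contig_id=contig.id,
                span=span,
                repeat_consensus=consensus,
                repeat_spans=rep_spans,
                spacers=spacers,
            )
        )
    return arrays


def boundary_arrays(
    contig: Contig, arrays: list[CrisprArray], edge_window: int = 500
) -> list[tuple[CrisprArray, str]]:
    """Arrays whose span reaches within ``edge_window`` of a contig end.

    Returns (array, end) pairs with end in {"left", "right"}; an array close
    to both ends of a short contig is reported twice.
    """
    out = []
    for arr in arrays:
        if arr.span[0] <= edge_window:
            out.append((arr, "left"))
        if contig.length - arr.span[1] <= edge_window:
            out.append((arr, "right"))
    return out


def array_features(arrays: list[CrisprArray]):
    """GFF3 features (repeat_region per array, plus repeat_unit/spacer parts)."""
    from .core_io import GffFeature

    feats = []
    for arr in arrays:
        feats.append(
            GffFeature(
                seqid=arr.contig_id,
                ftype="repeat_region",
                start=arr.span[0],
                end=arr.span[1],
                attributes={"ID": arr.id, "rpt_family": "CRISPR",
                            "rpt_unit_seq": arr.repeat_consensus},
            )
        )
        for sp in arr.spacers:
            feats.append(
                GffFeature(
                    seqid=arr.contig_id,
                    ftype="CRISPR_spacer",
                    start=sp.span[0],
                    end=sp.span[1],
                    attributes={"ID": sp.id, "Parent": arr.id},
                )
            )
    return feats
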