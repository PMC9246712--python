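"""Contig joins evidenced by shared boundary CRISPR-array spacers.

When an assembler breaks a chromosome inside a CRISPR array, the two
resulting contigs end in partial arrays, and a run of consecutive spacers
can appear at both facing boundaries.  Because spacers are unique sequences
(unlike the repeats between them), a run of k identical consecutive spacers
at two contig ends is strong in-silico evidence that the contigs are
adjacent.  Proposals emitted here are explicitly provisional — the evidence
level is recorded as ``in_silico``; closing a genome for real requires
independent confirmation (e.g. long-range PCR across the gap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .arrays import CrisprArray, boundary_arrays
from .core_io import Contig, revcomp


class MergeError(ValueError):
    """The proposed overlap disagrees beyond the repeat-mismatch tolerance."""


@dataclass
class JoinProposal:
    """A proposed junction between two contig ends.

    The merged layout is: contig_a oriented so ``end_a`` faces right, then
    contig_b in ``orientation_b`` (relative to its input strand) so its
    ``end_b`` faces left, with the shared-spacer block collapsed once.
    """

    contig_a: str
    end_a: str  # "left" | "right"
    contig_b: str
    end_b: str
    orientation_b: str  # "forward" | "reverse-complement"
    shared_run: list[tuple[str, str]]  # (spacer id in a, spacer id in b)
    k: int
    overlap_a_start: int  # start of the duplicated block in oriented-A coordinates
    overlap_length: int
    circularization: bool = False  # self-join of one contig's two ends
    evidence_level: str = "in_silico"


def _oriented_edge(
    contig: Contig,
    arr: CrisprArray,
    end: str,
    flip_to: str,
    min_len: float,
):
    """Spacers of a boundary array in merged-layout orientation.

    ``flip_to`` is "right" (array must face the right edge) or "left".  The
    contig is reverse-complemented when the array sits on the other end.
    Returns (flipped, spacer list as (id, seq, oriented span)) with partial
    spacers (shorter than ``min_len``) dropped from the run computation.
    """
    flipped = end != flip_to
    n = contig.length
    spacers = []
    for sp in arr.spacers:
        if len(sp.seq) < min_len:
            continue
        if flipped:
            s, e = n - sp.span[1], n - sp.span[0]
            spacers.append((sp.id, revcomp(sp.seq), (s, e)))
        else:
            spacers.append((sp.id, sp.seq, sp.span))
    spacers.sort(key=lambda t: t[2][0])
    return flipped, spacers


_BOUNDARY_SLOP = 2  # nt of spacer-boundary wobble tolerated between detections


def _spacers_match(x: str, y: str) -> bool:
    """Spacer identity, tolerating detector boundary wobble.

    Exact equality, or one sequence is the other trimmed by at most
    _BOUNDARY_SLOP nt at its ends (repeat-boundary placement can differ by a
    base or two between two independent detections of the same array; for
    random distinct spacers a containment this long cannot occur by chance).
    """
    if x == y:
        return True
    if abs(len(x) - len(y)) > _BOUNDARY_SLOP:
        return False
    short, long_ = (x, y) if len(x) <= len(y) else (y, x)
    return len(long_) - len(short) <= _BOUNDARY_SLOP and short in long_


def _suffix_prefix_run(a: list, b: list) -> int:
    """Longest r with the last r spacer sequences of a matching the first r of b."""
    best = 0
    for r in range(1, min(len(a), len(b)) + 1):
        if all(_spacers_match(a[-r + i][1], b[i][1]) for i in range(r)):
            best = r
    return best


def propose_joins(
    contigs: Sequence[Contig],
    arrays: Mapping[str, Sequence[CrisprArray]],
    min_k: int = 4,
    edge_window: int = 500,
    partial_spacer_fraction: float = 0.8,
) -> list[JoinProposal]:
    """Joins supported by >= ``min_k`` shared consecutive boundary spacers.

    Every pair of boundary arrays on distinct contig ends is tried in both
    orientations of the second contig; the two ends of a single contig are
    also compared (a hit there is circularization evidence).  Spacer
    identity is exact string equality up to 2 nt of repeat-boundary wobble
    (see :func:`_spacers_match`); spacers shorter than
    ``partial_spacer_fraction`` times the median spacer length of the two
    arrays are treated as partial and excluded from run computation.
    Proposals are sorted by descending k.
    """
    by_id = {c.id: c for c in contigs}
    edges: list[tuple[Contig, CrisprArray, str]] = []
    for c in contigs:
        for arr, end in boundary_arrays(c, list(arrays.get(c.id, ())), edge_window):
            edges.append((c, arr, end))

    proposals: list[JoinProposal] = []
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            ca, arr_a, end_a = edges[i]
            cb, arr_b, end_b = edges[j]
            if ca.id == cb.id and end_a == end_b:
                continue
            lengths = [len(sp.seq) for sp in arr_a.spacers] + [
                len(sp.seq) for sp in arr_b.spacers
            ]
            lengths.sort()
            min_len = partial_spacer_fraction * lengths[len(lengths) // 2]
            flip_a, sp_a = _oriented_edge(ca, arr_a, end_a, "right", min_len)
            flip_b, sp_b = _oriented_edge(cb, arr_b, end_b, "left", min_len)
            if not sp_a or not sp_b:
                continue
            r = _suffix_prefix_run(sp_a, sp_b)
            if r < min_k:
                continue
            overlap_start = sp_a[-r][2][0]
            # extend the overlap to the repeat flanking the first shared spacer
            reps_a = arr_a.repeat_spans
            if flip_a:
                n = ca.length
                reps_a = sorted((n - e, n - s) for s, e in reps_a)
            preceding = [sp for sp in reps_a if sp[1] <= overlap_start]
            if preceding and preceding[-1][1] == overlap_start:
                overlap_start = preceding[-1][0]
            proposals.append(
                JoinProposal(
                    contig_a=ca.id,
                    end_a=end_a,
                    contig_b=cb.id,
                    end_b=end_b,
                    orientation_b="forward" if not flip_b else "reverse-complement",
                    shared_run=[(sp_a[-r + t][0], sp_b[t][0]) for t in range(r)],
                    k=r,
                    overlap_a_start=overlap_start,
                    overlap_length=by_id[ca.id].length - overlap_start,
                    circularization=(ca.id == cb.id),
                )
            )
    proposals.sort(key=lambda p: (-p.k, p.contig_a, p.contig_b))
    return proposals


def merge_contigs(
    proposal: JoinProposal,
    contigs: Sequence[Contig],
    tolerance: int = 0,
) -> Contig:
    """Concatenate the two contigs of a proposal, collapsing the duplicated
    shared-spacer block once.

    The duplicated region, as seen from both contigs, must agree within
    ``tolerance`` mismatches (spacers are identical by construction of the
    proposal; disagreement can only come from the flanking repeats), else
    the proposal is rejected with :class:`MergeError`.  The merged record is
    provisional: its description carries ``join_evidence=in_silico``.
    """
    by_id = {c.id: c for c in contigs}
    a, b = by_id[proposal.contig_a], by_id[proposal.contig_b]
    seq_a = a.seq if proposal.end_a == "right" else revcomp(a.seq)
    seq_b = b.seq if proposal.orientation_b == "forward" else revcomp(b.seq)

    nominal = proposal.overlap_length
    if nominal > len(seq_b):
        raise MergeError(
            f"overlap ({nominal} nt) longer than contig {b.id!r}; proposal invalid"
        )
    # the detected spacer spans locate the overlap to within a few bases;
    # the exact duplicated block is fixed by the sequences themselves
    margin = 4 * _BOUNDARY_SLOP
    olen = None
    best_mm = None
    for l in range(min(nominal + margin, len(seq_b)), max(nominal - margin, 1) - 1, -1):
        mm = sum(1 for x, y in zip(seq_a[-l:], seq_b[:l]) if x != y)
        if mm <= tolerance:
            olen = l
            break
        best_mm = mm if best_mm is None else min(best_mm, mm)
    if olen is None:
        raise MergeError(
            f"overlap between {a.id!r} and {b.id!r} disagrees at >= {best_mm} "
            f"positions (tolerance {tolerance}); proposal rejected"
        )
    merged = seq_a + seq_b[olen:]
    return Contig(
        id=f"{a.id}+{b.id}",
        seq=merged,
        description=(
            f"join_evidence={proposal.evidence_level} k={proposal.k} "
            f"circularization={str(proposal.circularization).lower()}"
        ),
        topology="circular" if proposal.circularization else "unknown",
    )
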