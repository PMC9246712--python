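"""Mobile-element signatures and contig triage.

Three signatures separate mobile elements from the host chromosome in an
assembly: a terminal direct repeat (an assembler's linear representation of
a circular molecule duplicates its first bases at the end), terminal
inverted repeats (the hallmark of linear dsDNA virus genomes with
protein-primed replication), and read depth well above the chromosome's
(ongoing viral replication).  Together with spacer hits these drive a fixed
rule cascade assigning one label per contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .arrays import CrisprArray
from .core_io import Contig, RunConfig
from .matching import SpacerHit

#: classification labels, in rule order
LABELS = (
    "chromosome",
    "crispr_fragment",
    "circular_mobile",
    "linear_tir_mobile",
    "mobile_other",
    "unclassified",
)


@dataclass(frozen=True)
class TerminalRepeat:
    """A terminal direct (circularity) or inverted (TIR) repeat."""

    contig_id: str
    kind: str  # "direct" | "inverted"
    length: int
    identity: float
    left_span: tuple[int, int]
    right_span: tuple[int, int]


@dataclass
class Evidence:
    kind: str
    detail: str


@dataclass
class ContigClass:
    contig_id: str
    label: str
    evidence: list[Evidence] = field(default_factory=list)


def detect_circularity(
    contig: Contig, min_overlap: int = 20, max_mismatch: int = 0
) -> TerminalRepeat | None:
    """Longest terminal direct repeat: a prefix equal (within ``max_mismatch``)
    to an equal-length suffix.

    Searched down from half the contig length (a terminal repeat longer than
    half the molecule is not a circularity signature); returns None when no
    overlap of at least ``min_overlap`` exists.
    """
    seq = contig.seq
    n = len(seq)
    if n < 2 * min_overlap:
        return None
    for l in range(n // 2, min_overlap - 1, -1):
        pre, suf = seq[:l], seq[n - l :]
        if max_mismatch == 0:
            if pre != suf:
                continue
            mm = 0
        else:
            mm = sum(1 for a, b in zip(pre, suf) if a != b)
            if mm > max_mismatch:
                continue
        return TerminalRepeat(
            contig_id=contig.id,
            kind="direct",
            length=l,
            identity=(l - mm) / l,
            left_span=(0, l),
            right_span=(n - l, n),
        )
    return None


def trim_circular(contig: Contig, repeat: TerminalRepeat) -> Contig:
    """Drop the duplicated suffix and mark the contig circular."""
    if repeat.kind != "direct" or repeat.contig_id != contig.id:
        raise ValueError("trim_circular needs a direct terminal repeat of this contig")
    return Contig(
        id=contig.id,
        seq=contig.seq[: contig.length - repeat.length],
        description=contig.description,
        mean_depth=contig.mean_depth,
        topology="circular",
    )


_MATCH_SCORE = 1
_MISMATCH_SCORE = -5
_XDROP = 15


def detect_tir(
    contig: Contig,
    min_len: int = 20,
    min_identity: float = 0.85,
    max_scan: int = 500,
) -> TerminalRepeat | None:
    """Terminal inverted repeat by ungapped extension from the contig ends.

    Position i of the left end is compared with the complement of position
    n-1-i; the arm is grown by a scored extension (match +1, mismatch -5,
    stop when the score falls 15 below its running maximum, ties resolved to
    the shortest arm) and trimmed to end on a match, so an exact arm is
    recovered at exactly its length rather than extended through chance
    matches in the flanking sequence.  Reported if the arm is at least
    ``min_len`` long with identity at least ``min_identity``.
    """
    seq = contig.seq
    n = len(seq)
    if n < 2 * min_len:
        return None
    limit = min(max_scan, n // 2)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    match = [seq[i] == comp[seq[n - 1 - i]] for i in range(limit)]

    score = 0
    best_score, best_len = 0, 0
    for i, m in enumerate(match):
        score += _MATCH_SCORE if m else _MISMATCH_SCORE
        if score > best_score:  # strict: ties keep the shorter arm
            best_score, best_len = score, i + 1
        if score <= best_score - _XDROP:
            break

    # the score maximum always follows a match, but guard anyway
    l = best_len
    while l > 0 and not match[l - 1]:
        l -= 1
    for arm in range(l, min_len - 1, -1):
        if not match[arm - 1]:
            continue
        matches = sum(match[:arm])
        if matches / arm >= min_identity:
            return TerminalRepeat(
                contig_id=contig.id,
                kind="inverted",
                length=arm,
                identity=matches / arm,
                left_span=(0, arm),
                right_span=(n - arm, n),
            )
    return None


def coverage_ratio(
    contig: Contig | str, chromosome: Contig | str, depths: Mapping[str, float]
) -> float:
    """Contig depth divided by chromosome depth."""
    cid = contig if isinstance(contig, str) else contig.id
    chrom = chromosome if isinstance(chromosome, str) else chromosome.id
    for name in (cid, chrom):
        if name not in depths:
            raise KeyError(f"no depth recorded for contig {name!r}")
    if depths[chrom] <= 0:
        raise ValueError(f"chromosome {chrom!r} has non-positive depth")
    return depths[cid] / depths[chrom]


def _array_cover(contig: Contig, arrays: Sequence[CrisprArray]) -> float:
    covered = sum(e - s for s, e in (a.span for a in arrays))
    return covered / contig.length if contig.length else 0.0


def classify(
    contigs: Sequence[Contig],
    arrays: Mapping[str, Sequence[CrisprArray]],
    hits: Sequence[SpacerHit],
    repeats: Mapping[str, Sequence[TerminalRepeat]],
    depths: Mapping[str, float] | None,
    cfg: RunConfig | None = None,
    annotations: Mapping[str, Sequence[str]] | None = None,
) -> list[ContigClass]:
    """Assign one label per contig by a fixed rule cascade (first match wins).

    1. the designated (``cfg.chromosome_id``) or longest contig -> chromosome
    2. at least half the contig covered by CRISPR arrays -> crispr_fragment
    3. terminal direct repeat -> circular_mobile
    4. terminal inverted repeat -> linear_tir_mobile
    5. any spacer hit as target, a coverage ratio above threshold, or a
       user-supplied mobile-gene annotation -> mobile_other
    6. otherwise unclassified

    ``annotations`` (optional, from an external annotation table) maps contig
    id to mobile-gene labels such as "integrase"; it only adds rule-5
    evidence, no gene calling happens here.
    """
    cfg = cfg or RunConfig()
    if not contigs:
        raise ValueError("empty assembly")
    chrom_id = cfg.chromosome_id or max(contigs, key=lambda c: c.length).id

    hit_targets: dict[str, int] = {}
    for h in hits:
        hit_targets[h.target_contig_id] = hit_targets.get(h.target_contig_id, 0) + 1

    out: list[ContigClass] = []
    for c in contigs:
        ev: list[Evidence] = []
        if c.id == chrom_id:
            ev.append(Evidence("designation", f"longest/designated contig ({c.length} nt)"))
            out.append(ContigClass(c.id, "chromosome", ev))
            continue
        cover = _array_cover(c, arrays.get(c.id, ()))
        if cover >= cfg.array_cover_fraction:
            ev.append(Evidence("array_content", f"{cover:.0%} of length in CRISPR arrays"))
            out.append(ContigClass(c.id, "crispr_fragment", ev))
            continue
        direct = [r for r in repeats.get(c.id, ()) if r.kind == "direct"]
        if direct:
            r = direct[0]
            ev.append(Evidence("terminal_direct_repeat", f"{r.length} nt, identity {r.identity:.3f}"))
            out.append(ContigClass(c.id, "circular_mobile", ev))
            continue
        inverted = [r for r in repeats.get(c.id, ()) if r.kind == "inverted"]
        if inverted:
            r = inverted[0]
            ev.append(Evidence("terminal_inverted_repeat", f"{r.length} nt, identity {r.identity:.3f}"))
            out.append(ContigClass(c.id, "linear_tir_mobile", ev))
            continue
        if c.id in hit_targets:
            ev.append(Evidence("spacer_hits", f"{hit_targets[c.id]} protospacer hit(s)"))
        if depths is not None and c.id in depths and chrom_id in depths and depths[chrom_id] > 0:
            ratio = depths[c.id] / depths[chrom_id]
            if ratio >= cfg.coverage_ratio_threshold:
                ev.append(Evidence("coverage_ratio", f"{ratio:.2f}x chromosome depth"))
        for gene in (annotations or {}).get(c.id, ()):
            ev.append(Evidence("mobile_gene", gene))
        if ev:
            out.append(ContigClass(c.id, "mobile_other", ev))
        else:
            out.append(ContigClass(c.id, "unclassified", []))
    return out


def repeat_features(repeats: Sequence[TerminalRepeat]):
    """GFF3 features (direct_repeat / inverted_repeat, one per arm)."""
    from .core_io import GffFeature

    feats = []
    for r in repeats:
        ftype = "direct_repeat" if r.kind == "direct" else "inverted_repeat"
        for span, arm in ((r.left_span, "left"), (r.right_span, "right")):
            feats.append(
                GffFeature(
                    seqid=r.contig_id,
                    ftype=ftype,
                    start=span[0],
                    end=span[1],
                    attributes={"arm": arm, "length": str(r.length),
                                "identity": f"{r.identity:.4f}"},
                )
            )
    return feats
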