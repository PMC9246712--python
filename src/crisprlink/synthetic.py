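"""Synthetic assemblies with planted ground truth.

Emulates, at desk scale, the anatomy of a hot-spring archaeal host-virus
system: a circular chromosome whose strand-biased composition gives the
cumulative GC skew a unique V-shaped minimum at a planted replication
origin, carrying two CRISPR arrays that flank a marker locus; a circular
virus represented linearly with its first bases duplicated at its end; a
linear virus flanked by terminal inverted repeats and sequenced at elevated
depth; optional plain mobile contigs; and protospacers copied from planted
spacers at exactly 0 or exactly 1 substitution, on either strand.  A
fragmentation mode breaks the chromosome inside an array so that the two
fragments end in partial arrays sharing k consecutive spacers — the
situation a contig-joining stage must recognise.

Everything returned is a pure function of (parameters, seed); regenerating
with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import Contig, SimParams, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CHROMOSOME_ID = "chromosome"
CIRCULAR_VIRUS_ID = "circular_virus"
TIR_VIRUS_ID = "tir_virus"


@dataclass
class SpacerTruth:
    id: str
    seq: str
    start: int  # on the chromosome, 0-based half-open
    end: int


@dataclass
class ArrayTruth:
    contig_id: str
    start: int
    end: int
    repeat: str
    repeat_spans: list[tuple[int, int]]
    spacers: list[SpacerTruth]


@dataclass
class ProtospacerTruth:
    spacer_id: str
    target_contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int  # planted: exactly 0 or exactly 1


@dataclass
class JoinTruth:
    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    orientation_b: str
    k_shared: int
    overlap_length: int
    shared_spacer_ids: list[str]
    original_id: str
    original_length: int


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic assembly."""

    origin_position: int
    arrays: list[ArrayTruth]
    protospacers: list[ProtospacerTruth]
    tir: dict = field(default_factory=dict)            # per linear virus: length, identity
    circular_overlap: dict = field(default_factory=dict)  # per circular element: nt
    depth_multipliers: dict = field(default_factory=dict)
    join_truth: JoinTruth | None = None
    decoy_spacer_id: str | None = None

    def spacer_by_id(self) -> dict[str, SpacerTruth]:
        return {sp.id: sp for arr in self.arrays for sp in arr.spacers}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["arrays"] = [
            ArrayTruth(
                contig_id=a["contig_id"], start=a["start"], end=a["end"],
                repeat=a["repeat"],
                repeat_spans=[tuple(s) for s in a["repeat_spans"]],
                spacers=[SpacerTruth(**s) for s in a["spacers"]],
            )
            for a in d["arrays"]
        ]
        d["protospacers"] = [ProtospacerTruth(**p) for p in d["protospacers"]]
        if d.get("join_truth"):
            jt = dict(d["join_truth"])
            d["join_truth"] = JoinTruth(**jt)
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _biased_chromosome(rng: np.random.Generator, p: SimParams, origin: int) -> str:
    """Backbone with leading-strand G and A excess downstream of the origin."""
    L = p.chromosome_length
    ta, ga = (1 - p.gc_content) / 2, p.gc_content / 2
    bt, bg = p.at_bias / 2, p.gc_bias / 2
    # base order A, C, G, T
    p_lead = [ta + bt, ga - bg, ga + bg, ta - bt]
    p_lag = [ta - bt, ga + bg, ga - bg, ta + bt]
    lead = rng.choice(_BASES, size=L, p=p_lead)
    lag = rng.choice(_BASES, size=L, p=p_lag)
    leading = ((np.arange(L) - origin) % L) < L // 2
    return np.where(leading, lead, lag).tobytes().decode("ascii")


def _build_array(
    rng: np.random.Generator,
    p: SimParams,
    repeat: str,
    n_spacers: int,
    used: set[str],
    id_prefix: str,
) -> tuple[str, list[tuple[int, int]], list[tuple[str, str, int, int]]]:
    """Array string R s1 R s2 ... R with mutually distinct spacers.

    Returns (sequence, repeat spans, spacer records) with spans local to the
    array string; spacer records are (id, seq, start, end).
    """
    parts = [repeat]
    rep_spans = [(0, len(repeat))]
    spacers = []
    pos = len(repeat)
    for j in range(n_spacers):
        while True:
            sl = int(rng.integers(p.spacer_len_min, p.spacer_len_max + 1))
            s = _random_seq(rng, sl, p.gc_content)
            if s not in used:
                used.add(s)
                break
        spacers.append((f"{id_prefix}_sp{j:02d}", s, pos, pos + sl))
        parts.append(s)
        pos += sl
        parts.append(repeat)
        rep_spans.append((pos, pos + len(repeat)))
        pos += len(repeat)
    return "".join(parts), rep_spans, spacers


def _plant(seq: list[str], start: int, insert: str) -> None:
    seq[start : start + len(insert)] = list(insert)


def _add_tir_virus(rng, p: SimParams, mobile, margins, truth, depths) -> None:
    """Linear virus flanked by (exact or near) terminal inverted repeats."""
    tir = _random_seq(rng, p.tir_length, p.gc_content)
    vcore = list(_random_seq(rng, p.linear_virus_length - 2 * p.tir_length, p.gc_content))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if vcore[0] == comp[vcore[-1]]:
        # break palindromic continuation so the planted arm is maximal
        vcore[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[vcore[0]]
    left_arm = list(tir)
    n_mm = 0
    for _ in range(p.tir_mismatches):
        i = int(rng.integers(1, p.tir_length - 1))
        if left_arm[i] == tir[i]:
            left_arm[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[left_arm[i]]
            n_mm += 1
    mobile[TIR_VIRUS_ID] = list("".join(left_arm) + "".join(vcore) + revcomp(tir))
    margins[TIR_VIRUS_ID] = (p.tir_length + 120, p.linear_virus_length - p.tir_length - 120)
    truth.tir[TIR_VIRUS_ID] = {
        "length": p.tir_length,
        "identity": (p.tir_length - n_mm) / p.tir_length,
        "planted_mismatches": n_mm,
    }
    depths[TIR_VIRUS_ID] = p.chromosome_depth * p.virus_depth_multiplier
    truth.depth_multipliers[TIR_VIRUS_ID] = p.virus_depth_multiplier


def generate_assembly(
    params: SimParams | None = None, seed: int = 0
) -> tuple[list[Contig], TruthSet, dict[str, float]]:
    """Generate (contigs, planted truth, depth table) for one seed.

    The chromosome is the first contig; mobile contigs follow.  Protospacers
    are copied from planted spacers with exactly 0 or exactly 1 substitution
    onto the mobile contigs, never inside an array (unless the adversarial
    ``plant_in_array_decoy`` mode is on, which additionally reuses one
    array-1 spacer as an array-2 spacer so the self-hit filter has a decoy
    to suppress).
    """
    p = params or SimParams()
    if p.chromosome_length < 20_000:
        raise ValueError("chromosome length must be >= 20 kb")
    rng = np.random.default_rng(seed)

    L = p.chromosome_length
    origin = int(p.origin_frac * L)
    backbone = _biased_chromosome(rng, p, origin)

    used: set[str] = set()
    repeat = _random_seq(rng, p.repeat_length, p.gc_content)
    arr1_seq, arr1_reps, arr1_sp = _build_array(rng, p, repeat, p.n_spacers_array1, used, "arr1")
    arr2_seq, arr2_reps, arr2_sp = _build_array(rng, p, repeat, p.n_spacers_array2, used, "arr2")

    decoy_id = None
    if p.plant_in_array_decoy:
        # reuse an array-1 spacer inside array 2: a self-hit the filter must drop
        src_id, src_seq, _, _ = arr1_sp[2]
        tgt = list(arr2_sp[len(arr2_sp) // 2])
        arr2_chars = list(arr2_seq)
        old_start, old_end = tgt[2], tgt[3]
        # splice, keeping coordinates consistent by rebuilding the array string
        arr2_chars[old_start:old_end] = list(src_seq)
        delta = len(src_seq) - (old_end - old_start)
        arr2_seq = "".join(arr2_chars)
        if delta:
            arr2_reps = [(s + delta if s >= old_end else s, e + delta if e > old_end else e)
                         for s, e in arr2_reps]
            arr2_sp = [
                (i, q, s + delta, e + delta) if s >= old_end else (i, q, s, e)
                for i, q, s, e in arr2_sp
            ]
        j = len(arr2_sp) // 2
        arr2_sp[j] = (tgt[0], src_seq, tgt[2], tgt[2] + len(src_seq))
        decoy_id = src_id

    a1 = int(p.array_region_frac * L)
    a2 = a1 + len(arr1_seq) + p.marker_locus_length
    if a2 + len(arr2_seq) >= origin - 2 * p.chromosome_length // 10:
        raise ValueError("arrays would collide with the origin region; enlarge the chromosome")

    chrom = list(backbone)
    _plant(chrom, a1, arr1_seq)
    _plant(chrom, a2, arr2_seq)
    chrom_seq = "".join(chrom)

    def _shift(records, spans, offset):
        recs = [SpacerTruth(id=i, seq=q, start=s + offset, end=e + offset)
                for i, q, s, e in records]
        return recs, [(s + offset, e + offset) for s, e in spans]

    sp1, reps1 = _shift(arr1_sp, arr1_reps, a1)
    sp2, reps2 = _shift(arr2_sp, arr2_reps, a2)
    arrays = [
        ArrayTruth(CHROMOSOME_ID, a1, a1 + len(arr1_seq), repeat, reps1, sp1),
        ArrayTruth(CHROMOSOME_ID, a2, a2 + len(arr2_seq), repeat, reps2, sp2),
    ]

    # ---- mobile contigs -------------------------------------------------
    contigs = [Contig(id=CHROMOSOME_ID, seq=chrom_seq)]
    truth = TruthSet(origin_position=origin, arrays=arrays, protospacers=[],
                     decoy_spacer_id=decoy_id)
    depths: dict[str, float] = {CHROMOSOME_ID: p.chromosome_depth}

    mobile: dict[str, list[str]] = {}
    margins: dict[str, tuple[int, int]] = {}

    if p.circular_virus_length > 0:
        core = _random_seq(rng, p.circular_virus_length, p.gc_content)
        mobile[CIRCULAR_VIRUS_ID] = list(core + core[: p.circular_overlap])
        margins[CIRCULAR_VIRUS_ID] = (100, p.circular_virus_length - p.circular_overlap - 100)
        truth.circular_overlap[CIRCULAR_VIRUS_ID] = p.circular_overlap
        depths[CIRCULAR_VIRUS_ID] = p.chromosome_depth * p.virus_depth_multiplier
        truth.depth_multipliers[CIRCULAR_VIRUS_ID] = p.virus_depth_multiplier

    if p.linear_virus_length > 0:
        _add_tir_virus(rng, p, mobile, margins, truth, depths)

    plain_ids = []
    for m in range(p.n_plain_mobiles):
        mid = f"mobile_{m + 1}"
        plain_ids.append(mid)
        mobile[mid] = list(_random_seq(rng, p.plain_mobile_length, p.gc_content))
        margins[mid] = (100, p.plain_mobile_length - 100)
        depths[mid] = p.chromosome_depth * p.plain_depth_multiplier
        truth.depth_multipliers[mid] = p.plain_depth_multiplier
    # ---- protospacers ---------------------------------------------------
    # default plan mirrors the study conditions: 9 spacers with exact
    # protospacers across 4 mobile contigs, the TIR virus carrying 3 exact
    # plus 3 one-mismatch targets
    plan: list[tuple[str, int, int]] = [(CIRCULAR_VIRUS_ID, 2, 0)]
    plan += [(mid, 2, 0) for mid in plain_ids]
    plan.append((TIR_VIRUS_ID, 3, 3))
    plan = [(t, ne, nm) for t, ne, nm in plan if t in mobile]

    all_spacers = [sp for arr in arrays for sp in arr.spacers
                   if sp.id != decoy_id]
    need = sum(ne + nm for _, ne, nm in plan)
    if need > len(all_spacers):
        raise ValueError(
            f"requested {need} protospacers but only {len(all_spacers)} planted spacers exist"
        )
    order = rng.permutation(len(all_spacers))
    queue = [all_spacers[i] for i in order]

    for target, n_exact, n_one_mm in plan:
        tlist = mobile[target]
        lo, hi = margins[target]
        placed: list[tuple[int, int]] = []
        for mm_target in [0] * n_exact + [1] * n_one_mm:
            sp = queue.pop()
            slen = len(sp.seq)
            for _ in range(1000):
                pos = int(rng.integers(lo, hi - slen))
                if all(pos >= e + 10 or pos + slen <= s - 10 for s, e in placed):
                    break
            else:  # pragma: no cover - margins are generous
                raise RuntimeError("could not place protospacer")
            placed.append((pos, pos + slen))
            proto = list(sp.seq)
            if mm_target == 1:
                i = int(rng.integers(1, slen - 1))
                proto[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto[i]]
            strand = "+" if rng.random() < 0.5 else "-"
            insert = "".join(proto) if strand == "+" else revcomp("".join(proto))
            tlist[pos : pos + slen] = list(insert)
            truth.protospacers.append(
                ProtospacerTruth(
                    spacer_id=sp.id,
                    target_contig_id=target,
                    start=pos,
                    end=pos + slen,
                    strand=strand,
                    mismatches=mm_target,
                )
            )

    for mid, chars in mobile.items():
        contigs.append(Contig(id=mid, seq="".join(chars)))

    return contigs, truth, depths


def fragment_at_array(
    chromosome: Contig,
    truth: TruthSet,
    k_shared: int = 4,
    seed: int = 0,
) -> tuple[Contig, Contig, TruthSet]:
    """Break the chromosome inside its first array so both fragments end in
    partial arrays sharing exactly ``k_shared`` consecutive identical spacers.

    Fragment A keeps the chromosome start and ends just after the repeat
    that follows the last shared spacer; fragment B starts at the repeat
    that precedes the first shared spacer, so the shared block (repeats
    included) is duplicated.  Concatenating A with B minus the duplicated
    overlap reconstructs the chromosome exactly; the correct join is
    recorded in ``join_truth``.
    """
    if k_shared < 1:
        raise ValueError("k_shared must be >= 1")
    arr = next(a for a in truth.arrays if a.contig_id == chromosome.id)
    n_sp = len(arr.spacers)
    if n_sp < k_shared + 2:
        raise ValueError(
            f"array has {n_sp} spacers; need >= {k_shared + 2} for a {k_shared}-spacer overlap"
        )
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, n_sp - k_shared))  # first shared spacer index

    cut_b = arr.repeat_spans[m][0]            # start of repeat before spacer m
    cut_a = arr.repeat_spans[m + k_shared][1]  # end of repeat after last shared spacer

    seq = chromosome.seq
    frag_a = Contig(id=f"{chromosome.id}_frag_a", seq=seq[:cut_a])
    frag_b = Contig(id=f"{chromosome.id}_frag_b", seq=seq[cut_b:])

    shared = [sp.id for sp in arr.spacers[m : m + k_shared]]
    new_truth = dataclasses.replace(
        truth,
        join_truth=JoinTruth(
            contig_a=frag_a.id,
            end_a="right",
            contig_b=frag_b.id,
            end_b="left",
            orientation_b="forward",
            k_shared=k_shared,
            overlap_length=cut_a - cut_b,
            shared_spacer_ids=shared,
            original_id=chromosome.id,
            original_length=chromosome.length,
        ),
    )
    return frag_a, frag_b, new_truth


def recount_mismatches(truth: TruthSet, contigs: list[Contig]) -> list[int]:
    """Direct recount of each planted protospacer's mismatches from the
    emitted sequences (consistency oracle for the generator itself)."""
    by_id = {c.id: c for c in contigs}
    spacers = truth.spacer_by_id()
    out = []
    for ps in truth.protospacers:
        window = by_id[ps.target_contig_id].seq[ps.start : ps.end]
        if ps.strand == "-":
            window = revcomp(window)
        sp = spacers[ps.spacer_id].seq
        out.append(sum(1 for a, b in zip(sp, window) if a != b))
    return out
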