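"""On-disk formats, run configuration and provenance.

Every pipeline stage consumes and produces the types defined here.  Internal
coordinates are 0-based half-open throughout the package; GFF3 output is
1-based inclusive (converted only at serialization time).  Sequences are
upper-cased on read and restricted to the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

logger = logging.getLogger("crisprlink")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed on-disk input (FASTA/GFF3/TSV)."""


@dataclass
class Contig:
    """A DNA sequence record with optional depth and topology metadata.

    The unit every pipeline stage consumes.  ``topology`` records whether the
    molecule is known to be circular (e.g. after terminal-repeat trimming) or
    linear; assemblies normally arrive as ``unknown``.
    """

    id: str
    seq: str
    description: str = ""
    mean_depth: float | None = None
    topology: str = "unknown"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: illegal characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N)"
            )
        if self.mean_depth is not None and self.mean_depth < 0:
            raise ValueError(f"contig {self.id!r}: negative mean depth")
        if self.topology not in ("linear", "circular", "unknown"):
            raise ValueError(f"contig {self.id!r}: bad topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`, order preserved.

    Raises :class:`FormatError` on empty records or duplicate identifiers,
    naming the offending record.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        contigs.append(Contig(id=rec.id, seq=str(rec.seq), description=desc))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description=c.description) for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffFeature:
    """A genomic feature in internal (0-based half-open) coordinates."""

    seqid: str
    ftype: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."
    source: str = "crisprlink"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        # GFF3 mandates 1-based inclusive coordinates.
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.start + 1),
                str(self.end),
                self.score,
                self.strand,
                ".",
                attrs,
            ]
        )

    @classmethod
    def from_line(cls, line: str) -> "GffFeature":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise FormatError(f"bad GFF3 line ({len(parts)} columns): {line!r}")
        attrs = {}
        if parts[8] != ".":
            for item in parts[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
        return cls(
            seqid=parts[0],
            source=parts[1],
            ftype=parts[2],
            start=int(parts[3]) - 1,
            end=int(parts[4]),
            score=parts[5],
            strand=parts[6],
            attributes=attrs,
        )


def write_features_gff3(
    features: Iterable[GffFeature],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write features as GFF3 (1-based inclusive on disk).

    If ``contig_lengths`` is given, features extending past a contig end are a
    hard error and ``##sequence-region`` pragmas are emitted.
    """
    features = list(features)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths is not None:
            for cid in sorted(contig_lengths):
                fh.write(f"##sequence-region {cid} 1 {contig_lengths[cid]}\n")
            for f in features:
                if f.seqid not in contig_lengths:
                    raise FormatError(f"feature on unknown contig {f.seqid!r}")
                if f.end > contig_lengths[f.seqid] or f.start < 0:
                    raise FormatError(
                        f"feature {f.ftype} [{f.start},{f.end}) extends past "
                        f"contig {f.seqid!r} (length {contig_lengths[f.seqid]})"
                    )
        for f in features:
            fh.write(f.to_line() + "\n")


def read_features_gff3(path: str | Path) -> list[GffFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            out.append(GffFeature.from_line(line))
    return out


# ---------------------------------------------------------------------------
# Depth tables


def read_depth_table(path: str | Path) -> dict[str, float]:
    """Read a TSV with header columns ``contig_id`` and ``mean_depth``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"contig_id", "mean_depth"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: depth table must have header columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    depths: dict[str, float] = {}
    for row in df.itertuples(index=False):
        d = float(row.mean_depth)
        if d < 0:
            raise FormatError(f"{path}: negative depth for contig {row.contig_id!r}")
        depths[str(row.contig_id)] = d
    return depths


def write_depth_table(depths: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tmean_depth\n")
        for cid in depths:
            fh.write(f"{cid}\t{depths[cid]:g}\n")


def read_annotation_table(path: str | Path) -> dict[str, list[str]]:
    """Optional gene-annotation TSV: columns ``contig_id`` and ``feature``.

    Feeds mobile-gene evidence (e.g. "integrase", "endonuclease") into the
    classifier; no gene calling happens in this package.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"contig_id", "feature"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation table must have header columns {sorted(required)}"
        )
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.contig_id), []).append(str(row.feature))
    return out


def mean_depth_from_alignment(path: str | Path, stat: str = "mean") -> dict[str, float]:
    """Optional adapter: per-contig depth from a coordinate-sorted SAM/BAM.

    The core pipeline never requires this — depth normally arrives as a TSV —
    but assemblies often come with an alignment instead of a depth table.
    Requires pysam; imported lazily so the pipeline runs without it.
    """
    import numpy as np
    import pysam  # local import: optional dependency path

    depths: dict[str, float] = {}
    with pysam.AlignmentFile(str(path)) as af:
        for ref, length in zip(af.references, af.lengths):
            cov = np.zeros(length, dtype=np.int64)
            for col_a, col_c, col_g, col_t in [af.count_coverage(ref)]:
                cov += np.array(col_a) + np.array(col_c) + np.array(col_g) + np.array(col_t)
            depths[ref] = float(np.median(cov) if stat == "median" else cov.mean())
    return depths


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class SimParams:
    """Parameters of the synthetic assembly generator (see ``synthetic``)."""

    chromosome_length: int = 60_000
    gc_content: float = 0.41
    gc_bias: float = 0.04      # per-base G-C excess on the leading strand
    at_bias: float = 0.06      # per-base A-T excess on the leading strand
    origin_frac: float = 0.7   # planted origin, as a fraction of the chromosome
    repeat_length: int = 30
    n_spacers_array1: int = 20
    n_spacers_array2: int = 10
    spacer_len_min: int = 35
    spacer_len_max: int = 42
    marker_locus_length: int = 1500
    array_region_frac: float = 0.40
    circular_virus_length: int = 8000
    circular_overlap: int = 30
    linear_virus_length: int = 12_700
    tir_length: int = 80
    tir_mismatches: int = 0
    n_plain_mobiles: int = 2
    plain_mobile_length: int = 6000
    chromosome_depth: float = 20.0
    virus_depth_multiplier: float = 3.5
    plain_depth_multiplier: float = 1.0
    plant_in_array_decoy: bool = False


@dataclass
class RunConfig:
    """All pipeline thresholds plus the single seed governing randomness.

    Serializes losslessly to/from YAML; every threshold has a default.
    """

    seed: int = 0
    # CRISPR array detection
    seed_k: int = 13
    min_repeats: int = 3
    repeat_len_min: int = 23
    repeat_len_max: int = 50
    spacer_len_min: int = 20
    spacer_len_max: int = 50
    gap_spread_max: int = 12
    column_agreement_min: float = 0.8
    repeat_identity_budget: float = 0.2
    edge_window: int = 500
    # spacer matching
    max_mismatches: int = 1
    exclude_arrays: bool = True
    # classification
    min_circular_overlap: int = 20
    circular_max_mismatch: int = 0
    tir_min_len: int = 20
    tir_min_identity: float = 0.85
    tir_max_scan: int = 500
    coverage_ratio_threshold: float = 2.0
    array_cover_fraction: float = 0.5
    chromosome_id: str | None = None
    depth_stat: str = "mean"
    # skew / origin
    skew_window: int = 1000
    skew_step: int | None = None  # None -> equal to skew_window
    # contig joining
    min_shared_spacers: int = 4
    merge_mismatch_tolerance: int = 0
    partial_spacer_fraction: float = 0.8
    # synthetic generator
    sim: SimParams = field(default_factory=SimParams)
    # paths (optional; the library API passes objects directly)
    input_fasta: str | None = None
    depth_table: str | None = None
    annotation_table: str | None = None
    output_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(sim, Mapping):
            cfg.sim = SimParams(**dict(sim))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_id(config: RunConfig) -> str:
    """Deterministic 12-hex-digit id of a run: hash of the full config (incl. seed)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_run_header(config: RunConfig) -> None:
    """Echo timestamp, seed and config at startup for reproducibility."""
    logger.info("run %s started %s", run_id(config), time.strftime("%Y-%m-%dT%H:%M:%S"))
    logger.info("seed=%d", config.seed)
    logger.info("config=%s", json.dumps(config.to_dict(), sort_keys=True))
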