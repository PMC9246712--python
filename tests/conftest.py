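"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the dumbest correct
method (naive sliding scans, quadratic searches, direct recounts) and never
call the implementation paths they check.
"""

from __future__ import annotations

import random

import pytest

from crisprlink import RunConfig, generate_assembly, revcomp

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@pytest.fixture(scope="session")
def default_assembly():
    """One default synthetic assembly, shared read-only across tests."""
    contigs, truth, depths = generate_assembly(seed=11)
    return contigs, truth, depths


@pytest.fixture
def cfg():
    return RunConfig(seed=11)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


# ---------------------------------------------------------------------------
# independent oracles


def oracle_spacer_hits(spacers, targets, max_mismatches):
    """Naive slide of every spacer over every target position, both strands,
    counting mismatches character by character (N mismatches everything)."""
    hits = set()
    for t in targets:
        n = len(t.seq)
        for sp in spacers:
            L = len(sp.seq)
            for strand, seq in (("+", t.seq), ("-", revcomp(t.seq))):
                for i in range(n - L + 1):
                    mm = 0
                    for a, b in zip(sp.seq, seq[i : i + L]):
                        if a != b or a == "N" or b == "N":
                            mm += 1
                            if mm > max_mismatches:
                                break
                    else:
                        s, e = (i, i + L) if strand == "+" else (n - i - L, n - i)
                        hits.add((sp.id, t.id, s, e, strand, mm))
    return hits


def oracle_longest_terminal_direct(seq: str, min_overlap: int) -> int:
    """Quadratic scan for the longest equal prefix/suffix (<= half length)."""
    best = 0
    for l in range(min_overlap, len(seq) // 2 + 1):
        if seq[:l] == seq[-l:]:
            best = l
    return best


def oracle_longest_shared_run(spacers_a: list[str], spacers_b: list[str]) -> int:
    """Quadratic scan over all suffix/prefix offsets for the longest run of
    consecutive identical spacers aligned end-to-end."""
    best = 0
    for r in range(1, min(len(spacers_a), len(spacers_b)) + 1):
        if spacers_a[-r:] == spacers_b[:r]:
            best = r
    return best


def oracle_window_skews(seq: str, start: int, end: int):
    """Direct per-window recount of all four skews with a character loop."""
    a = c = g = t = 0
    for ch in seq[start:end]:
        if ch == "A":
            a += 1
        elif ch == "C":
            c += 1
        elif ch == "G":
            g += 1
        elif ch == "T":
            t += 1
    total = a + c + g + t

    def ratio(num, den):
        return num / den if den else 0.0

    return (
        ratio(g - c, g + c),
        ratio(a - t, a + t),
        ratio((a + g) - (c + t), total),
        ratio((a + c) - (g + t), total),
    )


def hit_key(h):
    return (h.spacer_id, h.target_contig_id, h.start, h.end, h.strand, h.mismatches)
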