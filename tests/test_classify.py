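"""Terminal-repeat signatures, coverage ratios and the triage cascade."""

import random

import pytest

from crisprlink import (
    Contig,
    RunConfig,
    SimParams,
    classify,
    coverage_ratio,
    detect_circularity,
    detect_tir,
    generate_assembly,
    revcomp,
    trim_circular,
)
from crisprlink.arrays import detect_arrays
from crisprlink.matching import SpacerHit

from conftest import oracle_longest_terminal_direct, random_dna


class TestDetectCircularity:
    def test_planted_terminal_duplication(self):
        rng = random.Random(1)
        x = random_dna(rng, 5000)
        r = detect_circularity(Contig(id="c", seq=x + x[:30]))
        assert r is not None and (r.kind, r.length, r.identity) == ("direct", 30, 1.0)
        assert r.left_span == (0, 30) and r.right_span == (5000, 5030)

    def test_random_sequence_has_none(self):
        rng = random.Random(2)
        assert detect_circularity(Contig(id="c", seq=random_dna(rng, 5000))) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_oracle(self, seed):
        rng = random.Random(seed)
        x = random_dna(rng, 2000)
        seq = x + x[: rng.randint(0, 60)]
        expected = oracle_longest_terminal_direct(seq, 20)
        r = detect_circularity(Contig(id="c", seq=seq))
        assert (r.length if r else 0) == expected

    def test_trim_marks_circular(self):
        rng = random.Random(3)
        x = random_dna(rng, 3000)
        c = Contig(id="c", seq=x + x[:25])
        r = detect_circularity(c)
        trimmed = trim_circular(c, r)
        assert trimmed.seq == x and trimmed.topology == "circular"

    def test_revcomp_invariance(self):
        rng = random.Random(4)
        x = random_dna(rng, 4000)
        c = Contig(id="c", seq=x + x[:40])
        rc = Contig(id="c", seq=revcomp(c.seq))
        assert detect_circularity(rc).length == detect_circularity(c).length


class TestDetectTir:
    def test_planted_exact_80nt_arms(self):
        rng = random.Random(5)
        t = random_dna(rng, 80)
        core = random_dna(rng, 3000)
        r = detect_tir(Contig(id="c", seq=t + core + revcomp(t)))
        assert (r.kind, r.length, r.identity) == ("inverted", 80, 1.0)

    def test_one_substitution_inside_arm(self):
        rng = random.Random(6)
        t = random_dna(rng, 80)
        mutated = t[:40] + {"A": "C", "C": "G", "G": "T", "T": "A"}[t[40]] + t[41:]
        core = random_dna(rng, 3000)
        r = detect_tir(Contig(id="c", seq=mutated + core + revcomp(t)))
        assert r.length == 80 and r.identity == pytest.approx(79 / 80)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sequences_have_none(self, seed):
        rng = random.Random(1000 + seed)
        assert detect_tir(Contig(id="c", seq=random_dna(rng, 4000))) is None

    def test_revcomp_invariance(self):
        rng = random.Random(7)
        t = random_dna(rng, 80)
        seq = t + random_dna(rng, 2500) + revcomp(t)
        a = detect_tir(Contig(id="c", seq=seq))
        b = detect_tir(Contig(id="c", seq=revcomp(seq)))
        assert (a.kind, a.length) == (b.kind, b.length) == ("inverted", 80)


class TestCoverageRatio:
    def test_arithmetic(self):
        assert coverage_ratio("v1", "chr", {"v1": 70.0, "chr": 20.0}) == pytest.approx(3.5)

    def test_equal_depths(self):
        assert coverage_ratio("a", "chr", {"a": 20.0, "chr": 20.0}) == 1.0

    def test_missing_depth_names_contig(self):
        with pytest.raises(KeyError, match="v9"):
            coverage_ratio("v9", "chr", {"chr": 20.0})

    def test_planted_multiplier_recovered_exactly(self):
        contigs, truth, depths = generate_assembly(seed=8)
        for cid, mult in truth.depth_multipliers.items():
            assert coverage_ratio(cid, "chromosome", depths) == pytest.approx(mult)


class TestClassify:
    def _run(self, contigs, depths=None, hits=(), repeats=None, arrays=None, cfg=None):
        return classify(
            contigs,
            arrays or {},
            list(hits),
            repeats or {},
            depths,
            cfg or RunConfig(),
        )

    def test_synthetic_assembly_fully_labelled(self):
        from crisprlink import run_pipeline

        res = run_pipeline(RunConfig(seed=19))
        labels = {c.contig_id: c.label for c in res.classifications}
        assert labels["chromosome"] == "chromosome"
        assert labels["circular_virus"] == "circular_mobile"
        assert labels["tir_virus"] == "linear_tir_mobile"
        assert labels["mobile_1"] == labels["mobile_2"] == "mobile_other"
        # labels partition the assembly; every non-unclassified has evidence
        assert len(res.classifications) == len(res.contigs)
        assert all(c.evidence for c in res.classifications if c.label != "unclassified")

    def test_array_dominated_contig_is_crispr_fragment(self):
        rng = random.Random(9)
        repeat = random_dna(rng, 30)
        parts = [repeat]
        for _ in range(8):
            parts.extend([random_dna(rng, 37), repeat])
        frag = Contig(id="frag", seq="".join(parts) + random_dna(rng, 100))
        chrom = Contig(id="chr", seq=random_dna(rng, 25_000))
        arrays = {"frag": detect_arrays(frag)}
        out = self._run([chrom, frag], arrays=arrays)
        assert {c.contig_id: c.label for c in out}["frag"] == "crispr_fragment"

    def test_rule_order_direct_repeat_beats_spacer_hit(self):
        rng = random.Random(10)
        x = random_dna(rng, 3000)
        circ = Contig(id="circ", seq=x + x[:30])
        chrom = Contig(id="chr", seq=random_dna(rng, 25_000))
        hit = SpacerHit("s1", "circ", 100, 136, "+", 0)
        repeats = {"circ": [detect_circularity(circ)]}
        out = self._run([chrom, circ], hits=[hit], repeats=repeats)
        assert {c.contig_id: c.label for c in out}["circ"] == "circular_mobile"

    def test_no_signal_is_unclassified(self):
        rng = random.Random(11)
        chrom = Contig(id="chr", seq=random_dna(rng, 25_000))
        boring = Contig(id="x", seq=random_dna(rng, 4000))
        out = self._run([chrom, boring], depths={"chr": 20.0, "x": 21.0})
        by = {c.contig_id: c for c in out}
        assert by["x"].label == "unclassified" and by["x"].evidence == []

    def test_coverage_alone_triggers_mobile_other(self):
        rng = random.Random(12)
        chrom = Contig(id="chr", seq=random_dna(rng, 25_000))
        hot = Contig(id="v", seq=random_dna(rng, 4000))
        out = self._run([chrom, hot], depths={"chr": 20.0, "v": 70.0})
        assert {c.contig_id: c.label for c in out}["v"] == "mobile_other"

    def test_annotation_hook_adds_evidence(self):
        rng = random.Random(13)
        chrom = Contig(id="chr", seq=random_dna(rng, 25_000))
        m = Contig(id="m", seq=random_dna(rng, 4000))
        out = classify([chrom, m], {}, [], {}, None, RunConfig(), {"m": ["integrase"]})
        by = {c.contig_id: c for c in out}
        assert by["m"].label == "mobile_other"
        assert any(e.kind == "mobile_gene" for e in by["m"].evidence)

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            self._run([])

    def test_designated_chromosome_override(self):
        rng = random.Random(14)
        a = Contig(id="a", seq=random_dna(rng, 25_000))
        b = Contig(id="b", seq=random_dna(rng, 30_000))
        cfg = RunConfig(chromosome_id="a")
        out = self._run([a, b], cfg=cfg)
        assert {c.contig_id: c.label for c in out}["a"] == "chromosome"
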