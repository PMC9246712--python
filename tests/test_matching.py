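"""Spacer-protospacer matching: planted hits, N semantics, oracle equality."""

import random

import pytest

from crisprlink import Contig, find_hits, generate_assembly, revcomp, summarize_linkage
from crisprlink.arrays import Spacer, detect_arrays

from conftest import hit_key, oracle_spacer_hits, random_dna


def _spacer(seq, sid="s1"):
    return Spacer(id=sid, array_id="a", index_in_array=0, seq=seq, span=(0, len(seq)))


def _mutate(s, i):
    return s[:i] + {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]] + s[i + 1 :]


class TestFindHits:
    def test_planted_forward_exact(self):
        rng = random.Random(1)
        sp = random_dna(rng, 35)
        target = Contig(id="t", seq=random_dna(rng, 100) + sp + random_dna(rng, 200))
        (h,) = find_hits([_spacer(sp)], [target], max_mismatches=0, exclude_arrays=False)
        assert (h.start, h.end, h.strand, h.mismatches) == (100, 135, "+", 0)
        assert h.full_coverage

    def test_planted_revcomp_one_mismatch(self):
        rng = random.Random(2)
        sp = random_dna(rng, 35)
        planted = revcomp(_mutate(sp, 10))
        target = Contig(id="t", seq=random_dna(rng, 50) + planted + random_dna(rng, 50))
        (h,) = find_hits([_spacer(sp)], [target], max_mismatches=1, exclude_arrays=False)
        assert (h.start, h.end, h.strand, h.mismatches) == (50, 85, "-", 1)

    def test_n_counts_as_mismatch_both_ways(self):
        rng = random.Random(7)
        sp = random_dna(rng, 20)
        # N in the target under the spacer -> 1 mismatch
        t1 = Contig(id="t", seq="TTTT" + sp[:10] + "N" + sp[11:] + "TTTT")
        (h,) = find_hits([_spacer(sp)], [t1], max_mismatches=1, exclude_arrays=False)
        assert h.mismatches == 1
        # N in the spacer never matches, not even N
        spn = sp[:10] + "N" + sp[11:]
        t2 = Contig(id="t", seq="TTTT" + spn + "TTTT")
        hits = find_hits([_spacer(spn)], [t2], max_mismatches=0, exclude_arrays=False)
        assert hits == []

    def test_short_spacer_is_hard_error(self):
        with pytest.raises(ValueError, match="uninformative"):
            find_hits([_spacer("ACGTACGTACGT")], [Contig(id="t", seq="ACGT" * 20)])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            find_hits([], [Contig(id="t", seq="ACGT" * 20)])

    def test_monotone_in_mismatch_budget(self):
        contigs, truth, _ = generate_assembly(seed=21)
        spacers = [
            _spacer(sp.seq, sp.id) for a in truth.arrays for sp in a.spacers
        ]
        h0 = {hit_key(h) for h in find_hits(spacers, contigs, 0, exclude_arrays=False)}
        h1 = {hit_key(h) for h in find_hits(spacers, contigs, 1, exclude_arrays=False)}
        assert h0 <= h1

    def test_strand_symmetry(self):
        """Reverse-complementing a target mirrors hit coordinates."""
        rng = random.Random(3)
        sp = random_dna(rng, 36)
        seq = random_dna(rng, 300) + sp + random_dna(rng, 111)
        fwd = find_hits([_spacer(sp)], [Contig(id="t", seq=seq)], 1, exclude_arrays=False)
        rev = find_hits([_spacer(sp)], [Contig(id="t", seq=revcomp(seq))], 1, exclude_arrays=False)
        assert len(fwd) == len(rev) == 1
        n = len(seq)
        assert rev[0].start == n - fwd[0].end and rev[0].strand != fwd[0].strand

    def test_oracle_equivalence_on_synthetic_assembly(self):
        """Set-identical to the naive slide on one full synthetic assembly."""
        contigs, truth, _ = generate_assembly(seed=13)
        spacers = [
            _spacer(sp.seq, sp.id) for a in truth.arrays for sp in a.spacers
        ]
        for mm in (0, 1):
            impl = {hit_key(h) for h in find_hits(spacers, contigs, mm, exclude_arrays=False)}
            assert impl == oracle_spacer_hits(spacers, contigs, mm)

    def test_self_hits_excluded_with_detected_arrays(self):
        contigs, truth, _ = generate_assembly(seed=13)
        chrom = contigs[0]
        arrays = {chrom.id: detect_arrays(chrom)}
        spacers = [sp for a in arrays[chrom.id] for sp in a.spacers]
        hits = find_hits(spacers, [chrom], 1, exclude_arrays=True, arrays=arrays)
        assert hits == []  # every chromosome hit is a self-hit inside an array

    def test_in_array_decoy_suppressed_only_by_filter(self):
        """Adversarial mode plants a spacer copy inside the other array; the
        self-hit filter must drop it, and only the filter."""
        from crisprlink import SimParams

        contigs, truth, _ = generate_assembly(SimParams(plant_in_array_decoy=True), seed=17)
        chrom = contigs[0]
        arrays = {chrom.id: detect_arrays(chrom)}
        decoy_sp = next(
            sp for a in arrays[chrom.id] for sp in a.spacers
            if sp.seq == truth.spacer_by_id()[truth.decoy_spacer_id].seq
        )
        with_filter = find_hits([decoy_sp], [chrom], 0, exclude_arrays=True, arrays=arrays)
        without = find_hits([decoy_sp], [chrom], 0, exclude_arrays=False)
        assert with_filter == []
        assert len(without) == 2  # its own array position plus the decoy copy


class TestSummarizeLinkage:
    def test_three_exact_plus_three_one_mismatch(self):
        """Three spacers with identical full-coverage matches and three more
        at one mismatch on the same target summarize as (3, 3)."""
        rng = random.Random(4)
        spacers = [_spacer(random_dna(rng, 38), f"s{i}") for i in range(6)]
        inserts = [sp.seq for sp in spacers[:3]] + [_mutate(sp.seq, 5) for sp in spacers[3:]]
        seq = random_dna(rng, 80)
        for ins in inserts:
            seq += ins + random_dna(rng, 40)
        hits = find_hits(spacers, [Contig(id="V", seq=seq)], 1, exclude_arrays=False)
        (row,) = summarize_linkage(hits).itertuples(index=False)
        assert (row.target_contig_id, row.n_exact_spacers, row.n_one_mm_spacers) == ("V", 3, 3)

    def test_no_hits_empty_table(self):
        assert len(summarize_linkage([])) == 0

    def test_distinct_spacer_counting(self):
        """One spacer hitting twice at 0 mm counts once, with 2 positions."""
        rng = random.Random(5)
        sp = _spacer(random_dna(rng, 36), "s1")
        seq = random_dna(rng, 50) + sp.seq + random_dna(rng, 50) + sp.seq + random_dna(rng, 50)
        hits = find_hits([sp], [Contig(id="V", seq=seq)], 1, exclude_arrays=False)
        (row,) = summarize_linkage(hits).itertuples(index=False)
        assert (row.n_exact_spacers, row.n_one_mm_spacers, row.n_hit_positions) == (1, 0, 2)

    def test_spacer_hitting_two_contigs_counts_on_both(self):
        rng = random.Random(6)
        sp = _spacer(random_dna(rng, 36), "s1")
        t1 = Contig(id="A", seq=random_dna(rng, 60) + sp.seq + random_dna(rng, 60))
        t2 = Contig(id="B", seq=random_dna(rng, 60) + sp.seq + random_dna(rng, 60))
        df = summarize_linkage(find_hits([sp], [t1, t2], 0, exclude_arrays=False))
        assert list(df.n_exact_spacers) == [1, 1]
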