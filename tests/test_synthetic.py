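"""Generator self-consistency: planted truth must match the emitted bytes."""

import pytest

from crisprlink import SimParams, fragment_at_array, generate_assembly, revcomp
from crisprlink.synthetic import TruthSet, recount_mismatches


def test_same_seed_is_byte_identical():
    a_contigs, a_truth, a_depths = generate_assembly(seed=1)
    b_contigs, b_truth, b_depths = generate_assembly(seed=1)
    assert [(c.id, c.seq) for c in a_contigs] == [(c.id, c.seq) for c in b_contigs]
    assert a_depths == b_depths
    assert [p.__dict__ for p in a_truth.protospacers] == [
        p.__dict__ for p in b_truth.protospacers
    ]


def test_different_seed_differs():
    a, _, _ = generate_assembly(seed=1)
    b, _, _ = generate_assembly(seed=2)
    assert a[0].seq != b[0].seq


def test_zero_mobile_elements():
    p = SimParams(n_plain_mobiles=0, circular_virus_length=0, linear_virus_length=0)
    contigs, truth, _ = generate_assembly(p, seed=3)
    assert [c.id for c in contigs] == ["chromosome"]
    assert truth.protospacers == []


def test_array_truth_matches_sequence():
    contigs, truth, _ = generate_assembly(seed=5)
    chrom = contigs[0]
    for arr in truth.arrays:
        for s, e in arr.repeat_spans:
            assert chrom.seq[s:e] == arr.repeat
        for sp in arr.spacers:
            assert chrom.seq[sp.start : sp.end] == sp.seq


@pytest.mark.parametrize("seed", range(8))
def test_planted_mismatch_recount(seed):
    """Recounting mismatches from the emitted sequences reproduces the
    recorded 0/1 counts for every planted protospacer."""
    contigs, truth, _ = generate_assembly(seed=seed)
    recounted = recount_mismatches(truth, contigs)
    assert recounted == [ps.mismatches for ps in truth.protospacers]
    assert set(recounted) <= {0, 1}


def test_protospacer_spacer_ids_exist():
    _, truth, _ = generate_assembly(seed=5)
    ids = set(truth.spacer_by_id())
    assert all(ps.spacer_id in ids for ps in truth.protospacers)


def test_protospacers_never_inside_arrays():
    contigs, truth, _ = generate_assembly(seed=5)
    assert all(ps.target_contig_id != "chromosome" for ps in truth.protospacers)


def test_spacers_mutually_distinct():
    _, truth, _ = generate_assembly(seed=5)
    seqs = [sp.seq for arr in truth.arrays for sp in arr.spacers]
    assert len(seqs) == len(set(seqs))


def test_spacer_lengths_in_observed_range():
    _, truth, _ = generate_assembly(seed=5)
    lens = {len(sp.seq) for arr in truth.arrays for sp in arr.spacers}
    assert min(lens) >= 35 and max(lens) <= 42


def test_depth_table_uses_planted_multipliers():
    _, truth, depths = generate_assembly(seed=5)
    assert depths["tir_virus"] == pytest.approx(20.0 * 3.5)
    assert depths["chromosome"] == pytest.approx(20.0)
    assert truth.depth_multipliers["tir_virus"] == 3.5


def test_tir_virus_anatomy():
    contigs, truth, _ = generate_assembly(seed=5)
    v = next(c for c in contigs if c.id == "tir_virus")
    L = truth.tir["tir_virus"]["length"]
    assert v.seq[-L:] == revcomp(v.seq[:L])  # exact planted arms
    # the planted arm is maximal: position L breaks the palindrome
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    assert v.seq[L] != comp[v.seq[v.length - 1 - L]]


def test_circular_virus_anatomy():
    contigs, truth, _ = generate_assembly(seed=5)
    v = next(c for c in contigs if c.id == "circular_virus")
    k = truth.circular_overlap["circular_virus"]
    assert v.seq[:k] == v.seq[-k:]


def test_truth_json_roundtrip(tmp_path):
    _, truth, _ = generate_assembly(seed=5)
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = TruthSet.from_json(p)
    assert back.origin_position == truth.origin_position
    assert [s.__dict__ for a in back.arrays for s in a.spacers] == [
        s.__dict__ for a in truth.arrays for s in a.spacers
    ]


def test_too_many_protospacers_requested():
    p = SimParams(n_spacers_array1=3, n_spacers_array2=3, chromosome_length=30_000)
    with pytest.raises(ValueError, match="protospacers"):
        generate_assembly(p, seed=1)


class TestFragmentAtArray:
    @pytest.mark.parametrize("k", [1, 4])
    def test_shared_run_is_exactly_k(self, k):
        contigs, truth, _ = generate_assembly(seed=4)
        fa, fb, t2 = fragment_at_array(contigs[0], truth, k_shared=k, seed=4)
        jt = t2.join_truth
        assert jt.k_shared == k and len(jt.shared_spacer_ids) == k
        # the duplicated block appears verbatim at both facing ends
        assert fa.seq[-jt.overlap_length :] == fb.seq[: jt.overlap_length]
        # the shared spacers are consecutive in the planted array
        arr = truth.arrays[0]
        ids = [sp.id for sp in arr.spacers]
        first = ids.index(jt.shared_spacer_ids[0])
        assert jt.shared_spacer_ids == ids[first : first + k]

    def test_concatenation_reconstructs_chromosome(self):
        """String-equality oracle: A + B[overlap:] is the original."""
        contigs, truth, _ = generate_assembly(seed=4)
        chrom = contigs[0]
        fa, fb, t2 = fragment_at_array(chrom, truth, k_shared=4, seed=4)
        assert fa.seq + fb.seq[t2.join_truth.overlap_length :] == chrom.seq

    def test_array_too_short_for_overlap(self):
        contigs, truth, _ = generate_assembly(seed=4)
        with pytest.raises(ValueError, match="spacers"):
            fragment_at_array(contigs[0], truth, k_shared=19, seed=4)
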