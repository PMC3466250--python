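from __future__ import annotations

import random

import numpy as np
import pytest

from oligocap import preprocess as pp
from oligocap.records import SeqRecord, reverse_complement

from oracles import best_window_bruteforce, smith_waterman_best


def _read(seq, quals=None, rid="c1_5p"):
    return SeqRecord(id=rid, residues=seq, qualities=quals)


class TestTrimQuality:
    def test_all_high_keeps_everything(self):
        r = _read("A" * 100, [40] * 100)
        assert pp.trim_quality(r) == (0, 100)

    def test_all_low_gives_empty_interval(self):
        r = _read("A" * 50, [10] * 50)
        s, e = pp.trim_quality(r)
        assert e - s == 0

    def test_missing_qualities_raises(self):
        with pytest.raises(ValueError, match="skip"):
            pp.trim_quality(_read("ACGT"))

    def test_matches_exhaustive_window_oracle(self):
        rng = random.Random(1)
        for _ in range(300):
            n = rng.randint(1, 80)
            quals = [rng.randint(0, 45) for _ in range(n)]
            r = _read("A" * n, quals)
            assert pp.trim_quality(r) == best_window_bruteforce(quals)


class TestTrimVector:
    VEC = "GATCCGGTACCTAGCAATTCGGCACTAGCGTTAACGGATTCACA"

    def test_exact_vector_prefix_removed(self):
        insert = "ACGTAGCTAGGTCCATGCAATCGGCGCGCGATATCGCGATT" * 3
        r = _read(self.VEC[:40] + insert)
        interval = pp.trim_vector(r, [self.VEC])
        assert interval[0] == 40 and interval[1] == len(r.residues)

    def test_no_vector_keeps_full_read(self):
        r = _read("ACGTAGCTAGGTCCATGCAATCGGCGCGCGATATCGCGATT")
        assert pp.trim_vector(r, [self.VEC]) == (0, len(r.residues))

    def test_pure_vector_discarded(self):
        r = _read(self.VEC + self.VEC[:20])
        assert pp.trim_vector(r, [self.VEC]) is pp.DiscardReason.ALL_VECTOR


class TestCapTag:
    def test_exact_tag_at_start(self):
        r = _read(pp.CAP_TAG + "ACGT" * 50)
        found, end = pp.detect_cap_tag(r)
        assert found and end == 30

    def test_one_substitution_within_budget(self):
        tag = "C" + pp.CAP_TAG[1:]
        r = _read(tag + "ACGT" * 50)
        found, end = pp.detect_cap_tag(r)
        assert found and end == 30

    def test_absent_tag(self):
        r = _read("ACGTTGCAGGTCCATGCAATCG" * 5)
        found, end = pp.detect_cap_tag(r)
        assert not found and end is None

    def test_sfii_remnant_suffix_accepted(self):
        r = _read("GG" + pp.CAP_TAG_SUFFIX + "ACGTTGCAGGTCCATGCAATCG" * 5)
        found, end = pp.detect_cap_tag(r)
        assert found and end == 2 + len(pp.CAP_TAG_SUFFIX)


class TestPolyA:
    BODY = "ACGTTGCAGGTCCATGCAATCGGTCCTGACGTTGCAGGTCCATGCAATCGGTCCTG"

    def test_sense_read_terminal_tail(self):
        seq = self.BODY + "A" * 20
        r = _read(seq, rid="c1_3p")
        sense, tail, flipped = pp.orient_and_detect_polya(r)
        assert not flipped
        assert tail == len(seq) - 20

    def test_antisense_read_is_flipped_and_tail_found(self):
        sense_seq = self.BODY + "A" * 20
        r = _read(reverse_complement(sense_seq), rid="c1_3p")
        out, tail, flipped = pp.orient_and_detect_polya(r)
        assert flipped
        assert out.residues == sense_seq
        assert tail == len(sense_seq) - 20

    def test_internal_a_run_is_not_a_tail(self):
        seq = self.BODY + "A" * 20 + self.BODY[:50]
        r = _read(seq, rid="c1_3p")
        _, tail, _ = pp.orient_and_detect_polya(r)
        assert tail is None

    def test_primer_head_stripped_before_orientation(self):
        sense_seq = self.BODY * 4 + "A" * 25
        raw = pp.POLYT_PRIMER_HEAD + reverse_complement(sense_seq)
        out, tail, flipped = pp.orient_and_detect_polya(_read(raw, rid="c1_3p"))
        assert flipped and tail is not None
        assert out.residues == sense_seq

    def test_idempotent_on_sense_reads(self):
        seq = self.BODY * 3 + "A" * 22
        r = _read(seq, rid="c1_3p")
        once, tail1, _ = pp.orient_and_detect_polya(r)
        twice, tail2, flipped = pp.orient_and_detect_polya(once)
        assert not flipped
        assert twice.residues == once.residues and tail1 == tail2


@pytest.mark.parametrize("length, keep", [(149, False), (150, True), (151, True)])
def test_length_filter_boundary(length, keep):
    assert pp.filter_length(length) is keep


class TestLowComplexity:
    def test_dinucleotide_repeat_flagged(self):
        assert pp.flag_low_complexity("AT" * 200)

    def test_random_sequence_kept_at_default_threshold(self):
        # default threshold must exceed the 99.9th percentile of the
        # windowed score over random 50% GC sequence
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        worst = []
        for _ in range(1000):
            seq = rng.choice(bases, size=400).tobytes().decode()
            scores = [
                pp.dust_score(seq[s : s + 64]) for s in range(0, 400 - 64 + 1, 32)
            ]
            worst.append(max(scores))
        assert np.quantile(worst, 0.999) < 2.0
        seq = rng.choice(bases, size=400).tobytes().decode()
        assert not pp.flag_low_complexity(seq)

    def test_external_mask_coverage_rule(self):
        seq = "ACGT" * 100
        assert pp.flag_low_complexity(seq, mask_intervals=[(0, 380)])
        assert not pp.flag_low_complexity(
            "ACGTTGCAGGTCCATGCAATCGGTCCTG" * 10, mask_intervals=[(0, 50)]
        )


@pytest.fixture(scope="module")
def mito():
    rng = np.random.default_rng(13)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=3000).tobytes().decode()


class TestMitochondrial:

    def test_exact_substring_flagged(self, mito):
        r = _read(mito[500:700], rid="m1_5p")
        assert pp.flag_mitochondrial(r, mito)

    def test_substring_with_five_pct_subs_flagged(self, mito):
        rng = np.random.default_rng(17)
        seq = list(mito[1000:1200])
        for i in rng.choice(200, size=10, replace=False):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        r = _read("".join(seq), rid="m2_5p")
        assert pp.flag_mitochondrial(r, mito)

    def test_shuffled_bases_kept_and_oracle_agrees(self, mito):
        rng = np.random.default_rng(19)
        shuffled = "".join(rng.permutation(list(mito[500:700])))
        r = _read(shuffled, rid="m3_5p")
        assert not pp.flag_mitochondrial(r, mito)
        # Smith-Waterman oracle: no qualifying (>=100 nt at >=95% identity)
        # local alignment can exist on either strand
        min_score = 100 * 0.95 - 100 * 0.05  # matches minus mismatches
        for strand in (shuffled, reverse_complement(shuffled)):
            assert smith_waterman_best(strand, mito) < min_score


class TestCascade:
    def test_every_read_gets_exactly_one_disposition(self, small_library):
        anns = small_library["anns"]
        assert len(anns) == len(small_library["reads"])
        for ann in anns.values():
            kept = ann.insert is not None
            assert kept == (ann.discard_reason is None)

    def test_clean_library_caps_all_found(self, clean_library):
        for lc in clean_library["clones"]:
            assert clean_library["anns"][lc.read5.id].cap_found

    def test_clean_library_tails_all_found(self, clean_library):
        for lc in clean_library["clones"]:
            assert clean_library["anns"][lc.read3.id].tail_start is not None
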