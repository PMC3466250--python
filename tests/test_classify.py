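from __future__ import annotations

import numpy as np
import pytest

from oligocap import classify
from oligocap.assembly import MergedTranscript
from oligocap.records import Basis, Category, EvidenceHit, LossCat


def _hit(frame=1, e=1e-40, desc="hypothetical protein", subject="P1",
         q=(0, 300), s=(0, 100), subject_len=150, bits=200.0):
    return EvidenceHit(
        query_id="x", subject_id=subject, subject_desc=desc, pct_identity=95.0,
        e_value=e, q_start=q[0], q_end=q[1], s_start=s[0], s_end=s[1],
        frame=frame, bitscore=bits, subject_len=subject_len,
    )


class TestTruncationTriage:
    def test_complete_coverage_with_cap_not_truncated(self):
        hit = _hit(s=(0, 150), subject_len=150)
        assert not classify.flag_truncated_coding("5p", 600, True, None, [hit])

    def test_missing_n_terminus_is_truncated(self):
        hit = _hit(q=(2, 242), s=(80, 160), subject_len=300)
        assert classify.flag_truncated_coding("5p", 600, True, None, [hit])

    def test_missing_cap_with_hit_is_truncated(self):
        hit = _hit(s=(0, 100))
        assert classify.flag_truncated_coding("5p", 600, False, None, [hit])

    def test_no_hit_is_never_flagged(self):
        assert not classify.flag_truncated_coding("5p", 600, False, None, [])

    def test_insignificant_hit_is_not_flagged(self):
        hit = _hit(e=1e-3, s=(80, 160))
        assert not classify.flag_truncated_coding("5p", 600, False, None, [hit])

    def test_3p_missing_tail_is_truncated(self):
        hit = _hit(s=(50, 100), subject_len=300)
        assert classify.flag_truncated_coding("3p", 600, False, None, [hit])

    def test_3p_c_terminus_not_reached_is_truncated(self):
        hit = _hit(q=(300, 600), s=(0, 100), subject_len=300)
        assert classify.flag_truncated_coding("3p", 600, False, 550, [hit])

    def test_3p_reaching_c_terminus_kept(self):
        hit = _hit(q=(0, 300), s=(195, 295), subject_len=300)
        assert not classify.flag_truncated_coding("3p", 600, False, 550, [hit])


def _merged(clone="c1"):
    return MergedTranscript(clone, "ACGT" * 100, 200, 0.99, (f"{clone}_5p", f"{clone}_3p"))


class TestFullLengthClassification:
    def test_sense_hit_is_coding(self):
        rec = classify.classify_full_length(_merged(), [_hit(e=1e-40)])
        assert rec.category is Category.FL_CODING
        assert rec.basis is Basis.BLAST_HIT_SENSE

    def test_antisense_only_is_noncoding(self):
        rec = classify.classify_full_length(_merged(), [_hit(frame=-2, e=1e-30)])
        assert rec.category is Category.FL_NONCODING
        assert rec.basis is Basis.BLAST_HIT_ANTISENSE

    def test_no_hit_is_noncoding(self):
        rec = classify.classify_full_length(_merged(), [])
        assert rec.category is Category.FL_NONCODING
        assert rec.basis is Basis.NO_HIT

    def test_reverse_transcriptase_discarded(self):
        hits = [
            _hit(e=1e-30, desc="pol-like Reverse Transcriptase", subject="RT1"),
            _hit(e=1e-20, subject="P2"),
        ]
        rec = classify.classify_full_length(_merged(), hits)
        assert rec.category is Category.DISCARD_RT

    def test_never_coding_from_antisense_only_random_tables(self):
        rng = np.random.default_rng(51)
        for _ in range(200):
            hits = [
                _hit(
                    frame=-int(rng.integers(1, 4)),
                    e=float(10.0 ** -rng.uniform(1, 60)),
                    subject=f"S{i}",
                )
                for i in range(int(rng.integers(0, 5)))
            ]
            rec = classify.classify_full_length(_merged(), hits)
            assert rec.category is not Category.FL_CODING


class TestWalkingSelection:
    def _clone(self, len5=700, s5=(0, 100), s3=(195, 295), subject="P1",
               subject3=None, slen=300):
        h5 = _hit(s=s5, subject=subject, subject_len=slen)
        h3 = _hit(s=s3, subject=subject3 or subject, subject_len=slen)
        return (len5, [h5], [h3])

    def test_both_termini_covered_qualifies(self):
        got = classify.select_walking_candidates({"c1": self._clone()})
        assert got == ["c1"]

    def test_ends_hitting_different_subjects_do_not_qualify(self):
        got = classify.select_walking_candidates(
            {"c1": self._clone(subject="P1", subject3="P2")}
        )
        assert got == []

    def test_top_n_by_read5_length(self):
        clones = {
            f"c{i}": self._clone(len5=500 + 10 * i) for i in range(10)
        }
        got = classify.select_walking_candidates(clones, n=3)
        assert got == ["c9", "c8", "c7"]


class TestEstRetention:
    @pytest.mark.parametrize(
        "length, end, expected",
        [
            (299, "5p", Category.DISCARD_SHORT_EST),
            (300, "3p", Category.EST3),
            (300, "5p", Category.EST5),
            (1000, "3p", Category.EST3),
        ],
    )
    def test_length_boundary(self, length, end, expected):
        (rec,) = classify.retain_ests([(f"r_{end}", end, length)])
        assert rec.category is expected


class TestGeneLoss:
    def test_tetrapod_only_gene_lost_in_teleosts(self):
        presence = {"A4gnt": {"tetrapods": {"human": True, "mouse": True},
                              "teleosts": {"zebrafish": False, "fugu": False}}}
        (rec,) = classify.categorize_gene_loss(presence)
        assert rec.category is LossCat.LOST_IN_TELEOSTS

    def test_teleost_only_gene_lost_in_tetrapods(self):
        presence = {"ccl_c24j": {"tetrapods": False,
                                 "teleosts": {"zebrafish": True}}}
        (rec,) = classify.categorize_gene_loss(presence)
        assert rec.category is LossCat.LOST_IN_TETRAPODS

    def test_absent_everywhere(self):
        presence = {"mtase": {"tetrapods": False, "teleosts": False}}
        (rec,) = classify.categorize_gene_loss(presence)
        assert rec.category is LossCat.ABSENT_IN_BONY_VERTEBRATES

    def test_shared_gene(self):
        presence = {"actb": {"tetrapods": True, "teleosts": True}}
        (rec,) = classify.categorize_gene_loss(presence)
        assert rec.category is LossCat.SHARED
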