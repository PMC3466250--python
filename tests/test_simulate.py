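from __future__ import annotations

import numpy as np
import pytest

from oligocap import polya, simulate
from oligocap.preprocess import CAP_TAG, preprocess_read


def _run(cfg):
    rng = np.random.default_rng(cfg.seed)
    genes = simulate.make_transcriptome(cfg, rng)
    clones = simulate.simulate_library(genes, cfg, rng)
    return genes, clones


class TestTranscriptome:
    def test_same_seed_is_byte_identical(self):
        cfg = simulate.SynthConfig(n_genes=10, seed=1)
        a = simulate.make_transcriptome(cfg)
        b = simulate.make_transcriptome(cfg)
        assert [g.mrna for g in a] == [g.mrna for g in b]
        assert [g.protein for g in a] == [g.protein for g in b]

    def test_point_mass_signal_distribution(self):
        cfg = simulate.SynthConfig(
            n_genes=30, seed=2, signal_distribution={"AAUAAA": 1.0}
        )
        genes = simulate.make_transcriptome(cfg)
        assert all(g.signal_used == "AAUAAA" for g in genes)

    def test_planted_signal_recovered_by_scanner(self):
        cfg = simulate.SynthConfig(n_genes=150, seed=3)
        genes = simulate.make_transcriptome(cfg)
        for g in genes:
            call = polya.scan_signal(g.mrna, g.tail_start)
            assert call.signal == g.signal_used

    def test_cds_translates_cleanly(self):
        cfg = simulate.SynthConfig(n_genes=40, seed=4, fraction_coding=1.0)
        genes = simulate.make_transcriptome(cfg)
        for g in genes:
            assert g.coding and g.protein is not None
            assert g.protein.startswith("M") and "*" not in g.protein


class TestLibrary:
    def test_no_truncation_means_every_5p_read_capped(self):
        cfg = simulate.SynthConfig(n_genes=60, seed=5, truncation_prob=0.0, error_rate=0.0)
        _genes, clones = _run(cfg)
        for lc in clones:
            assert lc.read5.residues.startswith(CAP_TAG)
            assert lc.truth.full_length

    def test_truncated_fraction_within_binomial_bounds(self):
        cfg = simulate.SynthConfig(
            n_genes=2000, seed=6, truncation_prob=0.3,
            size_window=(1, 10**9),  # disable size selection for the rate check
        )
        _genes, clones = _run(cfg)
        frac = sum(not lc.truth.full_length for lc in clones) / len(clones)
        sigma = (0.3 * 0.7 / len(clones)) ** 0.5
        assert abs(frac - 0.3) < 3 * sigma

    def test_size_selection_drops_out_of_window_inserts(self):
        cfg = simulate.SynthConfig(
            n_genes=80, seed=7, truncation_prob=0.0, size_window=(500, 3500)
        )
        genes, clones = _run(cfg)
        lo, hi = cfg.size_window
        kept_genes = {lc.truth.gene_id for lc in clones}
        rc_len = 25  # poly(T)-primer remnant
        for g in genes:
            insert_len = len(CAP_TAG) + len(g.mrna) + rc_len
            assert (g.gene_id in kept_genes) == (lo <= insert_len <= hi)

    def test_reads_are_deterministic_under_seed(self):
        cfg = simulate.SynthConfig(n_genes=25, seed=8)
        _g1, c1 = _run(cfg)
        _g2, c2 = _run(cfg)
        assert [lc.read5.residues for lc in c1] == [lc.read5.residues for lc in c2]
        assert [lc.read3.qualities for lc in c1] == [lc.read3.qualities for lc in c2]


class TestEvidence:
    def test_noise_free_coding_reads_have_one_true_sense_hit(self, clean_library):
        genes = {g.gene_id: g for g in clean_library["genes"]}
        truths = {lc.clone_id: lc.truth for lc in clean_library["clones"]}
        hits_by_query = {}
        for h in clean_library["hits"]:
            assert h.is_sense
            hits_by_query.setdefault(h.query_id, []).append(h)
        for rec in clean_library["inserts"]:
            clone = rec.clone_id
            gene = genes[truths[clone].gene_id]
            got = hits_by_query.get(rec.id, [])
            if not gene.coding:
                assert got == []
            else:
                assert len(got) <= 1

    def test_emitted_coordinates_satisfy_hit_invariants(self, small_library):
        for h in small_library["hits"]:
            assert 0 <= h.q_start < h.q_end
            assert 0 <= h.s_start < h.s_end
            assert h.frame in (1, 2, 3, -1, -2, -3)
            assert h.subject_len is not None and h.s_end <= h.subject_len + 1

    def test_rt_decoys_discard_everything_downstream(self):
        from oligocap.classify import classify_full_length
        from oligocap.records import Category
        from oligocap.assembly import MergedTranscript

        cfg = simulate.SynthConfig(n_genes=20, seed=9, truncation_prob=0.0,
                                   error_rate=0.0, fraction_coding=1.0)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate.make_transcriptome(cfg, rng)
        clones = simulate.simulate_library(genes, cfg, rng)
        reads = [lc.read5 for lc in clones]
        anns = {r.id: preprocess_read(r) for r in reads}
        inserts = [a.insert for a in anns.values() if a.insert is not None]
        # with noise=1 every sequence gets a decoy; RT decoys have the best
        # e-value, so any transcript whose decoy is RT must be discarded
        hits = simulate.simulate_evidence(
            inserts, genes, {r.id: r.clone_id for r in reads},
            {lc.clone_id: lc.truth for lc in clones}, noise=1.0,
            rng=np.random.default_rng(10),
        )
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        n_rt = 0
        for rec in inserts:
            qh = by_query.get(rec.id, [])
            if any(h.subject_id == "RT_decoy" for h in qh):
                n_rt += 1
                m = MergedTranscript(rec.clone_id, rec.residues, 100, 1.0,
                                     (rec.id, rec.id))
                assert classify_full_length(m, qh).category is Category.DISCARD_RT
        assert n_rt > 0


class TestExpectedCategories:
    def test_oracle_covers_every_clone(self, small_library):
        expected = simulate.expected_clone_categories(
            small_library["clones"], small_library["anns"], small_library["hits"]
        )
        assert set(expected) == {lc.clone_id for lc in small_library["clones"]}
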