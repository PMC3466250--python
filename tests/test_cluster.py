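from __future__ import annotations

import numpy as np
import pytest

from oligocap import cluster
from oligocap.records import SeqRecord

from oracles import greedy_cluster_oracle


def _rand_seq(rng, n):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=n).tobytes().decode()


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _recs(named):
    return [SeqRecord(id=n, residues=s) for n, s in named]


@pytest.fixture(scope="module")
def mixed_input():
    """30 random originals, each with a copy at 0.5% or 4% divergence:
    partitions differ meaningfully across identity thresholds."""
    rng = np.random.default_rng(21)
    named = []
    for i in range(30):
        seq = _rand_seq(rng, int(rng.integers(250, 500)))
        rate = 0.005 if i % 2 == 0 else 0.04
        named.append((f"s{i:03d}a", seq))
        named.append((f"s{i:03d}b", _mutate(rng, seq, rate)))
    return named


class TestGreedyCluster:
    def test_identical_pair_forms_one_cluster(self):
        recs = _recs([("a", "ACGT" * 50), ("b", "ACGT" * 50)])
        clusters = cluster.greedy_cluster(recs, identity=0.99)
        assert len(clusters) == 1 and sorted(clusters[0].member_ids) == ["a", "b"]

    def test_divergent_pair_stays_apart(self):
        rng = np.random.default_rng(2)
        seq = _rand_seq(rng, 300)
        recs = _recs([("a", seq), ("b", _mutate(rng, seq, 0.10))])
        assert len(cluster.greedy_cluster(recs, identity=0.99)) == 2

    def test_mutated_copies_pair_with_originals(self):
        rng = np.random.default_rng(3)
        named = []
        for i in range(50):
            seq = _rand_seq(rng, int(rng.integers(300, 600)))
            named.append((f"o{i:02d}", seq))
            named.append((f"c{i:02d}", _mutate(rng, seq, 0.005)))
        clusters = cluster.greedy_cluster(_recs(named), identity=0.98)
        assert len(clusters) == 50
        for c in clusters:
            stems = {m[1:] for m in c.member_ids}
            assert len(stems) == 1 and len(c.member_ids) == 2

    def test_empty_input_and_bad_thresholds(self):
        assert cluster.greedy_cluster([], 0.99) == []
        with pytest.raises(ValueError):
            cluster.greedy_cluster([], 1.5)
        with pytest.raises(ValueError):
            cluster.greedy_cluster([], 0.9, coverage=0.0)

    @pytest.mark.parametrize("identity", [0.90, 0.98, 0.99])
    def test_agrees_with_all_pairs_oracle(self, mixed_input, identity):
        got = cluster.greedy_cluster(_recs(mixed_input), identity)
        want = greedy_cluster_oracle(mixed_input, identity)
        got_partition = sorted(sorted(c.member_ids) for c in got)
        want_partition = sorted(sorted(members) for _rep, members in want)
        assert got_partition == want_partition

    def test_partition_property_and_input_order_independence(self, mixed_input):
        recs = _recs(mixed_input)
        clusters = cluster.greedy_cluster(recs, 0.98)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(n for n, _ in mixed_input)
        shuffled = list(reversed(recs))
        again = cluster.greedy_cluster(shuffled, 0.98)
        assert sorted(c.rep_id for c in again) == sorted(c.rep_id for c in clusters)

    def test_cluster_count_monotone_in_identity(self, mixed_input):
        recs = _recs(mixed_input)
        counts = [
            len(cluster.greedy_cluster(recs, t))
            for t in (0.80, 0.90, 0.95, 0.98, 0.99, 1.0)
        ]
        assert counts == sorted(counts)

    def test_representative_is_longest_member(self, mixed_input):
        by_id = dict(mixed_input)
        for c in cluster.greedy_cluster(_recs(mixed_input), 0.95):
            assert all(len(by_id[c.rep_id]) >= len(by_id[m]) for m in c.member_ids)


class TestTwoSetClustering:
    def test_utr_fragment_removed(self):
        rng = np.random.default_rng(7)
        coding = _rand_seq(rng, 900)
        utr_fragment = coding[600:880]  # 3'UTR-like substring
        unrelated = _rand_seq(rng, 300)
        retained, clusters = cluster.cluster_two_sets(
            _recs([("frag", utr_fragment), ("novel", unrelated)]),
            _recs([("tx1", coding)]),
        )
        assert retained == ["novel"]
        assert len(clusters) == 1

    def test_planted_fragments_exactly_removed(self):
        rng = np.random.default_rng(8)
        references = [_rand_seq(rng, int(rng.integers(600, 1200))) for _ in range(20)]
        queries, planted = [], set()
        for i, ref in enumerate(references[:10]):
            a = int(rng.integers(0, len(ref) - 300))
            queries.append((f"utr{i:02d}", ref[a : a + 280]))
            planted.add(f"utr{i:02d}")
        for i in range(15):
            queries.append((f"nc{i:02d}", _rand_seq(rng, int(rng.integers(250, 700)))))
        retained, _clusters = cluster.cluster_two_sets(
            _recs(queries), _recs([(f"tx{i}", r) for i, r in enumerate(references)])
        )
        assert set(q for q, _ in queries) - set(retained) == planted
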