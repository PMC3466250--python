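"""Greedy incremental identity clustering (cd-hit style).

Sequences are processed longest-first; each joins the first existing
cluster whose representative it matches at the identity threshold, else it
seeds a new cluster.  Identity between a sequence and a representative is
computed from the minimal glocal edit distance (the shorter sequence
aligned end-to-end inside the longer, end gaps on the longer free):
identity = 1 - d / len(shorter).  Because the shorter sequence is always
aligned over its full length, the alignment-coverage requirement on the
shorter sequence is met by construction.  A shared-k-mer prefilter skips
hopeless comparisons and never changes the outcome at the identity levels
used here.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from oligocap.records import Cluster, SeqRecord

KMER_BY_MODE = {"nucleotide": 8, "protein": 4, "two_set": 8}


def glocal_identity(shorter: str, longer: str, max_dist: int | None = None) -> float:
    """Identity of the best end-to-end placement of ``shorter`` in ``longer``."""
    if not shorter:
        return 0.0
    k = -1 if max_dist is None else max_dist
    res = edlib.align(shorter, longer, mode="HW", task="distance", k=k)
    d = res["editDistance"]
    if d == -1:  # beyond the k bound
        return 0.0
    return 1.0 - d / len(shorter)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    seqs: Sequence[SeqRecord],
    identity: float,
    coverage: float = 0.95,
    mode: str = "nucleotide",
) -> list[Cluster]:
    """Cluster sequences greedily at an identity threshold.

    Input order does not matter: processing is longest-first with a
    lexicographic id tie-break, and each sequence joins the first cluster
    (in creation order) whose representative satisfies the threshold.
    """
    if not (0 < identity <= 1) or not (0 < coverage <= 1):
        raise ValueError("identity and coverage must be in (0, 1]")
    if mode not in KMER_BY_MODE:
        raise ValueError(f"unknown mode {mode!r}")
    k = KMER_BY_MODE[mode]
    ordered = sorted(seqs, key=lambda r: (-len(r.residues), r.id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[set[str]] = []
    for rec in ordered:
        qk = _kmers(rec.residues, k)
        placed = False
        max_dist = int((1 - identity) * len(rec.residues))
        for idx, cl in enumerate(clusters):
            if qk and rep_kmers[idx] and not (qk & rep_kmers[idx]):
                continue
            ident = glocal_identity(rec.residues, rep_seqs[idx], max_dist)
            if ident >= identity:
                cl.member_ids.append(rec.id)
                cl.identity_used[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(rep_id=rec.id, member_ids=[rec.id], identity_used={rec.id: 1.0})
            )
            rep_seqs.append(rec.residues)
            rep_kmers.append(qk)
    return clusters


def cluster_two_sets(
    query_set: Sequence[SeqRecord],
    reference_set: Sequence[SeqRecord],
    identity: float = 0.98,
    coverage: float = 0.95,
) -> tuple[list[str], list[Cluster]]:
    """Drop query sequences redundant with a reference set, then cluster.

    Used to exclude noncoding transcripts that are really UTR fragments of
    protein-coding transcripts: a query matching any reference at the
    thresholds (identity over the shorter of the two) is removed; the
    survivors are clustered among themselves with :func:`greedy_cluster`.
    Returns (retained query ids, clusters of the retained set).
    """
    if not (0 < identity <= 1) or not (0 < coverage <= 1):
        raise ValueError("identity and coverage must be in (0, 1]")
    k = KMER_BY_MODE["two_set"]
    ref = [(r.residues, _kmers(r.residues, k)) for r in reference_set]
    retained: list[SeqRecord] = []
    for rec in query_set:
        qk = _kmers(rec.residues, k)
        redundant = False
        for ref_seq, ref_k in ref:
            if qk and ref_k and not (qk & ref_k):
                continue
            shorter, longer = (
                (rec.residues, ref_seq)
                if len(rec.residues) <= len(ref_seq)
                else (ref_seq, rec.residues)
            )
            max_dist = int((1 - identity) * len(shorter))
            if glocal_identity(shorter, longer, max_dist) >= identity:
                redundant = True
                break
        if not redundant:
            retained.append(rec)
    clusters = greedy_cluster(retained, identity, coverage, mode="nucleotide")
    return [r.id for r in retained], clusters
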