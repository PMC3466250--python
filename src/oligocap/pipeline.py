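"""End-to-end orchestration of the cDNA processing decision tree.

Order of stages (truncation triage deliberately precedes assembly):

1. per-read QC (quality, vector, cap/tail, length, complexity, mito)
2. truncated-coding triage -> EST_TRUNCATED
3. clone pairing and overlap merge -> full-length transcripts
4. full-length classification (coding / noncoding / RT discard) and
   homology-guided ORFs
5. unmerged reads: per-end deduplication, primer-walking candidate
   selection, 5'/3' EST retention
6. non-redundant sets (proteins; noncoding vs coding two-set clustering)
7. polyadenylation-signal calls on full-length transcripts

Every read receives exactly one terminal disposition; the report module
asserts the count conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from oligocap import assembly, classify, cluster, polya
from oligocap.assembly import MergedTranscript
from oligocap.orf import OrfCall, orf_from_evidence
from oligocap.preprocess import DiscardReason, ReadAnnotation, preprocess_read
from oligocap.records import (
    Category,
    ClassificationRecord,
    EvidenceHit,
    NamedSeq,
    SeqRecord,
    SignalCall,
)


@dataclass
class PipelineParams:
    e_max: float = 1e-7
    margin_aa: int = 20
    min_read_len: int = 150
    min_est_len: int = 300
    merge_min_identity: float = 0.95
    merge_min_overlap_frac: float = 0.5
    est_cluster_identity: float = 0.99
    est_cluster_coverage: float = 0.95
    protein_nr_identity: float = 0.98
    protein_nr_coverage: float = 0.90
    noncoding_nr_identity: float = 0.98
    noncoding_nr_coverage: float = 0.95
    walking_n: int = 800


@dataclass
class PipelineResult:
    annotations: dict[str, ReadAnnotation]
    read_category: dict[str, object]  # read_id -> Category | DiscardReason
    merged: list[MergedTranscript]
    clone_class: dict[str, ClassificationRecord]
    orfs: list[OrfCall]
    est5_clusters: list
    est3_clusters: list
    protein_nr: list
    noncoding_nr_ids: list[str]
    noncoding_nr_clusters: list
    signal_calls: list[SignalCall]
    walking: list[str]
    n_input_reads: int = 0
    tissues: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    reads: list[SeqRecord],
    hits: list[EvidenceHit],
    params: PipelineParams | None = None,
    vector_seqs: list[str] | None = None,
    mito_seq: str | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    hits_by_query: dict[str, list[EvidenceHit]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)

    annotations: dict[str, ReadAnnotation] = {}
    read_category: dict[str, object] = {}
    tissues = {r.clone_id: r.tissue for r in reads if r.tissue}
    surviving: list[SeqRecord] = []
    for read in reads:
        ann = preprocess_read(
            read,
            vector_seqs=vector_seqs,
            mito_seq=mito_seq,
            min_len=params.min_read_len,
        )
        annotations[read.id] = ann
        if ann.discard_reason is not None:
            read_category[read.id] = ann.discard_reason
        else:
            insert = ann.insert
            insert.tissue = read.tissue
            surviving.append(insert)

    # truncated-coding triage before assembly
    assemble_pool: list[SeqRecord] = []
    for insert in surviving:
        ann = annotations[insert.id]
        truncated = classify.flag_truncated_coding(
            end=insert.end,
            insert_len=len(insert),
            cap_found=ann.cap_found,
            tail_start=ann.tail_start,
            hits=hits_by_query.get(insert.id, ()),
            e_max=params.e_max,
            margin_aa=params.margin_aa,
        )
        if truncated:
            read_category[insert.id] = Category.EST_TRUNCATED
        else:
            assemble_pool.append(insert)

    pairs, orphans = assembly.pair_clone_reads(assemble_pool)
    merged: list[MergedTranscript] = []
    unmerged_pairs: list[assembly.ClonePair] = []
    for pair in pairs:
        m = assembly.merge_overlap(
            pair,
            min_identity=params.merge_min_identity,
            min_overlap_frac=params.merge_min_overlap_frac,
        )
        if m is not None:
            merged.append(m)
        else:
            unmerged_pairs.append(pair)

    # classify merged transcripts on the union of their reads' evidence
    clone_class: dict[str, ClassificationRecord] = {}
    transcript_hits: dict[str, list[EvidenceHit]] = {}
    for m in merged:
        r5_id, r3_id = m.source
        mh = list(hits_by_query.get(r5_id, ()))
        offset3 = len(m.residues) - _read_len(r3_id, assemble_pool)
        for h in hits_by_query.get(r3_id, ()):
            mh.append(_shift_hit(h, m.clone_id, offset3, len(m.residues)))
        mh = [_rename_hit(h, m.clone_id) for h in mh]
        transcript_hits[m.clone_id] = mh
        rec = classify.classify_full_length(m, mh, e_max=params.e_max)
        clone_class[m.clone_id] = rec
        read_category[r5_id] = rec.category
        read_category[r3_id] = rec.category

    # homology-guided ORFs for coding transcripts
    orfs: list[OrfCall] = []
    for m in merged:
        if clone_class[m.clone_id].category is not Category.FL_CODING:
            continue
        sense = [h for h in transcript_hits[m.clone_id]
                 if h.is_sense and h.e_value < params.e_max]
        top = classify.best_hit(sense)
        if top is not None and top.q_end <= len(m.residues):
            transcript = SeqRecord(id=m.clone_id, residues=m.residues, tissue=m.tissue)
            orfs.append(orf_from_evidence(transcript, top))

    # unmerged reads: dedup per end, walking candidates, ESTs
    unmerged_reads = [r for p in unmerged_pairs for r in (p.read5, p.read3)] + orphans
    est5_pool = [r for r in unmerged_reads if r.end == "5p"]
    est3_pool = [r for r in unmerged_reads if r.end == "3p"]
    est5_clusters = cluster.greedy_cluster(
        est5_pool, params.est_cluster_identity, params.est_cluster_coverage
    )
    est3_clusters = cluster.greedy_cluster(
        est3_pool, params.est_cluster_identity, params.est_cluster_coverage
    )

    walking_input = {
        p.clone_id: (
            len(p.read5),
            hits_by_query.get(p.read5.id, ()),
            hits_by_query.get(p.read3.id, ()),
        )
        for p in unmerged_pairs
    }
    walking = classify.select_walking_candidates(
        walking_input, n=params.walking_n, margin_aa=params.margin_aa,
        e_max=params.e_max,
    )
    walking_set = set(walking)
    est_records = classify.retain_ests(
        (
            (r.id, r.end, len(r))
            for r in unmerged_reads
            if r.clone_id not in walking_set
        ),
        min_len=params.min_est_len,
    )
    for clone_id in walking:
        read_category[f"{clone_id}_5p"] = Category.WALKING_CANDIDATE
        read_category[f"{clone_id}_3p"] = Category.WALKING_CANDIDATE
    for rec in est_records:
        read_category[rec.subject_id] = rec.category

    # non-redundant sets
    coding_tx = [
        SeqRecord(id=m.clone_id, residues=m.residues, tissue=m.tissue)
        for m in merged
        if clone_class[m.clone_id].category is Category.FL_CODING
    ]
    noncoding_tx = [
        SeqRecord(id=m.clone_id, residues=m.residues, tissue=m.tissue)
        for m in merged
        if clone_class[m.clone_id].category is Category.FL_NONCODING
    ]
    protein_recs = [
        NamedSeq(id=o.transcript_id, residues=o.protein) for o in orfs if o.protein
    ]
    protein_nr = cluster.greedy_cluster(
        protein_recs, params.protein_nr_identity, params.protein_nr_coverage,
        mode="protein",
    )
    noncoding_nr_ids, noncoding_nr_clusters = cluster.cluster_two_sets(
        noncoding_tx, coding_tx,
        identity=params.noncoding_nr_identity,
        coverage=params.noncoding_nr_coverage,
    )

    # polyadenylation signals on full-length transcripts
    signal_calls: list[SignalCall] = []
    for m in merged:
        if clone_class[m.clone_id].category is Category.DISCARD_RT:
            continue
        r3_ann = annotations.get(m.source[1])
        if r3_ann is None or r3_ann.tail_start is None:
            continue
        offset3 = len(m.residues) - _read_len(m.source[1], assemble_pool)
        tail_start = r3_ann.tail_start + offset3
        if 0 <= tail_start <= len(m.residues):
            signal_calls.append(
                polya.scan_signal(m.residues, tail_start, transcript_id=m.clone_id)
            )

    return PipelineResult(
        annotations=annotations,
        read_category=read_category,
        merged=merged,
        clone_class=clone_class,
        orfs=orfs,
        est5_clusters=est5_clusters,
        est3_clusters=est3_clusters,
        protein_nr=protein_nr,
        noncoding_nr_ids=noncoding_nr_ids,
        noncoding_nr_clusters=noncoding_nr_clusters,
        signal_calls=signal_calls,
        walking=walking,
        n_input_reads=len(reads),
        tissues=tissues,
    )


def _read_len(read_id: str, pool: list[SeqRecord]) -> int:
    for r in pool:
        if r.id == read_id:
            return len(r)
    raise KeyError(read_id)


def _shift_hit(h: EvidenceHit, new_query: str, offset: int, qlen: int) -> EvidenceHit:
    q0 = max(0, h.q_start + offset)
    q1 = min(qlen, h.q_end + offset)
    if q1 <= q0:
        q0, q1 = h.q_start, h.q_end
    frame = h.frame
    mag = (q0 % 3) + 1
    frame = mag if frame > 0 else -mag
    return EvidenceHit(
        query_id=new_query,
        subject_id=h.subject_id,
        subject_desc=h.subject_desc,
        pct_identity=h.pct_identity,
        e_value=h.e_value,
        q_start=q0,
        q_end=q1,
        s_start=h.s_start,
        s_end=h.s_end,
        frame=frame,
        bitscore=h.bitscore,
        subject_len=h.subject_len,
    )


def _rename_hit(h: EvidenceHit, new_query: str) -> EvidenceHit:
    if h.query_id == new_query:
        return h
    return EvidenceHit(
        query_id=new_query,
        subject_id=h.subject_id,
        subject_desc=h.subject_desc,
        pct_identity=h.pct_identity,
        e_value=h.e_value,
        q_start=h.q_start,
        q_end=h.q_end,
        s_start=h.s_start,
        s_end=h.s_end,
        frame=h.frame,
        bitscore=h.bitscore,
        subject_len=h.subject_len,
    )
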