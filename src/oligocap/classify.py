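"""Decision-tree classification of clones and reads.

Routes each clone/read into its terminal bucket: truncated coding reads
become ESTs before assembly; merged transcripts are split into full-length
protein-coding vs noncoding on the strand and significance of their
translated-alignment hits (reverse-transcriptase matches are discarded as
retroelement artifacts); unmerged reads become primer-walking candidates
or 5'/3' ESTs.  Also hosts the differential gene-loss categorizer used to
compare homolog presence between tetrapods and teleost fishes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from oligocap.assembly import MergedTranscript
from oligocap.records import (
    Basis,
    Category,
    ClassificationRecord,
    EvidenceHit,
    LossCat,
    LossCategory,
)

E_MAX = 1e-7
RT_PATTERNS = ("reverse transcriptase",)


def best_hit(hits: Iterable[EvidenceHit]) -> EvidenceHit | None:
    """Lowest e-value, then highest bitscore, then lexicographic subject."""
    ranked = sorted(hits, key=lambda h: (h.e_value, -h.bitscore, h.subject_id))
    return ranked[0] if ranked else None


def _is_rt(hit: EvidenceHit, patterns: Sequence[str] = RT_PATTERNS) -> bool:
    desc = hit.subject_desc.lower()
    return any(p in desc for p in patterns)


def flag_truncated_coding(
    end: str,
    insert_len: int,
    cap_found: bool,
    tail_start: int | None,
    hits: Sequence[EvidenceHit],
    e_max: float = E_MAX,
    margin_aa: int = 20,
) -> bool:
    """True when a read with a significant sense protein hit looks truncated.

    5' reads: the cap tag is missing, or the hit starts deep into the
    subject (missing N-terminus) while the query alignment begins near the
    read start.  3' reads: the poly(A) tail is missing, or the subject
    C-terminus is not reached while the alignment runs to the read end.
    Reads without a significant sense hit are never flagged here; they
    proceed to assembly.
    """
    sense = [h for h in hits if h.is_sense and h.e_value < e_max]
    top = best_hit(sense)
    if top is None:
        return False
    if end == "5p":
        if not cap_found:
            return True
        return top.s_start > margin_aa and top.q_start < 3 * margin_aa
    if end == "3p":
        if tail_start is None:
            return True
        if top.subject_len is None:
            return False
        return (
            top.s_end < top.subject_len - margin_aa
            and top.q_end > insert_len - 3 * margin_aa
        )
    raise ValueError(f"end must be '5p' or '3p', got {end!r}")


def classify_full_length(
    merged: MergedTranscript,
    hits: Sequence[EvidenceHit],
    e_max: float = E_MAX,
    rt_patterns: Sequence[str] = RT_PATTERNS,
) -> ClassificationRecord:
    """FL_CODING / FL_NONCODING / DISCARD_RT for one merged transcript.

    Only hits below e_max count.  A best hit matching reverse transcriptase
    discards the transcript; a sense-frame hit makes it coding; antisense
    hits alone (the protein must lie on the sense strand of an
    oligo-capped clone) or no hits make it noncoding.
    """
    sig = [h for h in hits if h.e_value < e_max]
    top = best_hit(sig)
    if top is not None and _is_rt(top, rt_patterns):
        return ClassificationRecord(
            merged.clone_id, Category.DISCARD_RT, Basis.BLAST_HIT_SENSE, top.subject_id
        )
    sense = [h for h in sig if h.is_sense]
    if sense:
        top_sense = best_hit(sense)
        return ClassificationRecord(
            merged.clone_id, Category.FL_CODING, Basis.BLAST_HIT_SENSE,
            top_sense.subject_id,
        )
    if sig:  # antisense only
        return ClassificationRecord(
            merged.clone_id, Category.FL_NONCODING, Basis.BLAST_HIT_ANTISENSE,
            top.subject_id,
        )
    return ClassificationRecord(merged.clone_id, Category.FL_NONCODING, Basis.NO_HIT)


def select_walking_candidates(
    clones: Mapping[str, tuple[int, Sequence[EvidenceHit], Sequence[EvidenceHit]]],
    n: int = 800,
    margin_aa: int = 20,
    e_max: float = E_MAX,
) -> list[str]:
    """Clones whose unmerged 5'/3' reads bracket one known protein.

    ``clones`` maps clone_id -> (read5_len, hits of the 5' read, hits of
    the 3' read).  A clone qualifies when both ends hit the same subject
    with the 5' hit reaching the subject N-terminus within margin_aa and
    the 3' hit reaching the C-terminus within margin_aa.  Qualifiers are
    sorted by 5'-read length descending (tie: clone id) and the top n kept
    for full-length finishing by primer walking.
    """
    qualifying: list[tuple[int, str]] = []
    for clone_id, (len5, hits5, hits3) in clones.items():
        subj5 = {
            h.subject_id
            for h in hits5
            if h.is_sense and h.e_value < e_max and h.s_start <= margin_aa
        }
        ok = False
        for h in hits3:
            if not (h.is_sense and h.e_value < e_max):
                continue
            if h.subject_id in subj5 and h.subject_len is not None:
                if h.s_end >= h.subject_len - margin_aa:
                    ok = True
                    break
        if ok:
            qualifying.append((len5, clone_id))
    qualifying.sort(key=lambda t: (-t[0], t[1]))
    return [clone_id for _len5, clone_id in qualifying[:n]]


def retain_ests(
    reads: Iterable[tuple[str, str, int]], min_len: int = 300
) -> list[ClassificationRecord]:
    """Keep unmerged, non-walking reads >= min_len as 5'/3' ESTs.

    ``reads`` yields (read_id, end, insert_len); shorter reads are
    discarded.
    """
    out = []
    for read_id, end, length in reads:
        if length < min_len:
            cat = Category.DISCARD_SHORT_EST
        else:
            cat = Category.EST5 if end == "5p" else Category.EST3
        out.append(ClassificationRecord(read_id, cat, Basis.PAIRING))
    return out


def categorize_gene_loss(
    presence: Mapping[str, Mapping[str, object]],
    tetrapod_group: str = "tetrapods",
    teleost_group: str = "teleosts",
) -> list[LossCategory]:
    """Differential-loss category per gene from per-group homolog presence.

    ``presence[gene][group]`` is a bool, or a per-species mapping collapsed
    by OR.  A gene with hits in tetrapods but none in teleosts was lost in
    teleosts (and symmetrically); absent from both groups means the gene is
    missing from bony vertebrates altogether.
    """
    out: list[LossCategory] = []
    for gene_id in sorted(presence):
        groups = presence[gene_id]
        collapsed: dict[str, bool] = {}
        for group, val in groups.items():
            if isinstance(val, Mapping):
                collapsed[group] = any(bool(v) for v in val.values())
            else:
                collapsed[group] = bool(val)
        tet = collapsed.get(tetrapod_group, False)
        tel = collapsed.get(teleost_group, False)
        if tet and tel:
            cat = LossCat.SHARED
        elif tet:
            cat = LossCat.LOST_IN_TELEOSTS
        elif tel:
            cat = LossCat.LOST_IN_TETRAPODS
        else:
            cat = LossCat.ABSENT_IN_BONY_VERTEBRATES
        out.append(LossCategory(gene_id, cat, collapsed))
    return out
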