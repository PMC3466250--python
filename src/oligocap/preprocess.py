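"""Per-read quality control for oligo-capped library Sanger reads.

Each read is quality-trimmed (Mott-style, PHRED < 20), screened for vector,
checked for the 5' cap tag or the 3' poly(A) tail (with orientation to the
sense strand), and filtered on length, low complexity and mitochondrial
origin.  Filters run in a fixed order and the first failing filter wins, so
every read receives exactly one terminal disposition.

The cap tag is the DNA copy of the RNA oligonucleotide ligated to decapped
full-length mRNA; SfiI digestion during cloning can truncate it, so a short
remnant suffix is also accepted.  3'-end reads are primed with an anchored
poly(T) oligo whose head sequence identifies the antisense orientation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from oligocap.records import SeqRecord, reverse_complement

# DNA copy of the cap-tag RNA oligo ligated to decapped full-length mRNA
CAP_TAG = "AGCATCGAGTCGGCCTTGTTGGCCTACTGG"
# remnant left on the read when SfiI digestion truncates the tag
CAP_TAG_SUFFIX = "CTACTGG"
# head of the anchored poly(T) first-strand primer (the T17V anchor follows)
POLYT_PRIMER_HEAD = "GCGGCTGAAGACGGCCTATGTGGCC"


class DiscardReason(str, enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    LOW_COMPLEXITY = "LOW_COMPLEXITY"
    MITOCHONDRIAL = "MITOCHONDRIAL"
    ALL_VECTOR = "ALL_VECTOR"


@dataclass
class ReadAnnotation:
    """Per-read QC outcome.

    ``trimmed_span`` is the retained interval on the raw read (raw
    orientation); ``insert`` is the adapter-free, sense-oriented sequence
    that continues downstream, or None when the read is discarded.
    ``tail_start`` indexes into ``insert``.
    """

    read_id: str
    trimmed_span: tuple[int, int]
    cap_found: bool = False
    cap_end: int | None = None
    tail_start: int | None = None
    oriented_sense: bool = True
    discard_reason: DiscardReason | None = None
    insert: SeqRecord | None = None


def trim_quality(read: SeqRecord, threshold: int = 20) -> tuple[int, int]:
    """Maximal-score window under a Mott-style running sum of (q - threshold).

    Returns a 0-based half-open interval; (0, 0) when every window scores
    <= 0.  Ties broken by smallest start, then smallest end, matching the
    exhaustive all-windows rule.
    """
    if read.qualities is None:
        raise ValueError(
            f"read {read.id!r} has no qualities; skip quality trimming for it"
        )
    best_score = 0
    best = (0, 0)
    prefix = 0
    min_prefix = 0
    min_idx = 0
    for j, q in enumerate(read.qualities, start=1):
        prefix += q - threshold
        score = prefix - min_prefix
        if score > best_score:
            best_score = score
            best = (min_idx, j)
        if prefix < min_prefix:
            min_prefix = prefix
            min_idx = j
    return best


def _extend_seed(
    read: str, ref: str, i: int, j: int, k: int, max_mismatch_rate: float
) -> tuple[int, int, int]:
    """Ungapped extension of an exact k-mer seed at read[i], ref[j].

    X-drop extension (match +1, mismatch -2, drop 10); returns
    (read_start, read_end, matches) of the best-scoring segment.
    """
    drop = 10
    # right
    score, best_score, best_r = 0, 0, 0
    r = 0
    while i + k + r < len(read) and j + k + r < len(ref):
        score += 1 if read[i + k + r] == ref[j + k + r] else -2
        r += 1
        if score > best_score:
            best_score, best_r = score, r
        if score < best_score - drop:
            break
    # left
    score, best_score, best_l = 0, 0, 0
    l = 0
    while i - l - 1 >= 0 and j - l - 1 >= 0:
        score += 1 if read[i - l - 1] == ref[j - l - 1] else -2
        l += 1
        if score > best_score:
            best_score, best_l = score, l
        if score < best_score - drop:
            break
    start, end = i - best_l, i + k + best_r
    matches = sum(1 for a, b in zip(read[start:end], ref[j - best_l : j - best_l + end - start]) if a == b)
    if (end - start - matches) > max_mismatch_rate * (end - start):
        # fall back to the clean seed if the extension is too noisy
        return i, i + k, k
    return start, end, matches


def _match_intervals(
    read: str, refs: list[str], k: int, max_mismatch_rate: float
) -> list[tuple[int, int]]:
    """Approximate match intervals of any reference (either strand) on the read."""
    index: dict[str, list[tuple[int, int]]] = {}
    targets: list[str] = []
    for ref in refs:
        for strand_seq in (ref, reverse_complement(ref)):
            t = len(targets)
            targets.append(strand_seq)
            for j in range(0, len(strand_seq) - k + 1):
                index.setdefault(strand_seq[j : j + k], []).append((t, j))
    intervals: list[tuple[int, int]] = []
    covered_until = -1
    for i in range(0, len(read) - k + 1, 4):
        if i < covered_until:
            continue
        hits = index.get(read[i : i + k])
        if not hits:
            continue
        t, j = hits[0]
        start, end, _ = _extend_seed(read, targets[t], i, j, k, max_mismatch_rate)
        intervals.append((start, end))
        covered_until = end - k
    return _merge_intervals(intervals)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def trim_vector(
    read: SeqRecord,
    vector_seqs: list[str],
    min_match: int = 16,
    max_mismatch_rate: float = 0.1,
) -> tuple[int, int] | DiscardReason:
    """Remove terminal vector segments; flag reads that are (almost) all vector.

    Matches of >= min_match bases chained from either read end are trimmed;
    total vector coverage > 90% of the read returns ALL_VECTOR.
    """
    n = len(read.residues)
    if not vector_seqs or n < min_match:
        return (0, n)
    k = min(12, min_match)
    intervals = [
        (s, e)
        for s, e in _match_intervals(read.residues, vector_seqs, k, max_mismatch_rate)
        if e - s >= min_match
    ]
    if not intervals:
        return (0, n)
    coverage = sum(e - s for s, e in intervals)
    if coverage > 0.9 * n:
        return DiscardReason.ALL_VECTOR
    slack = 5
    start, end = 0, n
    for s, e in intervals:  # chain from the left
        if s <= start + slack:
            start = max(start, e)
    for s, e in reversed(intervals):  # chain from the right
        if e >= end - slack:
            end = min(end, s)
    if start >= end:
        return DiscardReason.ALL_VECTOR
    return (start, end)


def _best_hamming_match(
    seq: str, pattern: str, search_window: int, max_mismatches: int
) -> int | None:
    """Leftmost-best sliding Hamming match start, or None."""
    m = len(pattern)
    best_pos, best_mm = None, max_mismatches + 1
    limit = min(search_window, len(seq) - m + 1)
    for p in range(0, max(0, limit)):
        mm = sum(1 for a, b in zip(seq[p : p + m], pattern) if a != b)
        if mm < best_mm:
            best_mm, best_pos = mm, p
    return best_pos if best_mm <= max_mismatches else None


def detect_cap_tag(
    read5: SeqRecord,
    cap_tag: str = CAP_TAG,
    suffix: str = CAP_TAG_SUFFIX,
    max_mismatches: int = 2,
    search_window: int = 60,
) -> tuple[bool, int | None]:
    """Search the first search_window bases of a 5' read for the cap tag.

    The full tag is accepted with <= max_mismatches substitutions; the
    SfiI-remnant suffix alone must match exactly (it is too short to absorb
    mismatches without false positives).  Returns (cap_found, cap_end);
    the insert starts at cap_end.
    """
    seq = read5.residues
    pos = _best_hamming_match(seq, cap_tag, search_window, max_mismatches)
    if pos is not None:
        return True, pos + len(cap_tag)
    pos = _best_hamming_match(seq, suffix, search_window, 0)
    if pos is not None:
        return True, pos + len(suffix)
    return False, None


def find_polya_tail(
    seq: str, min_tail: int = 8, max_end_gap: int = 3, purity: float = 0.9
) -> int | None:
    """Start of the terminal poly(A) run, or None.

    The run must end within max_end_gap bases of the sequence end, span at
    least min_tail bases, start and end on an A, and contain >= purity
    fraction of A.  Leftward extension is score-based (+1 per A, -2 per
    non-A, extend only on strict improvement): isolated sequencing errors
    inside the tail are absorbed, but the run never creeps into merely
    A-rich upstream sequence (which would eat into the signal window).
    """
    n = len(seq)
    end = None
    for e in range(n, max(0, n - max_end_gap - 1), -1):
        if e >= 1 and seq[e - 1] == "A":
            end = e
            break
    if end is None:
        return None
    score, best_score, best, best_count = 0, 0, end, 0
    count_a = 0
    for s in range(end - 1, max(-1, end - 501), -1):
        if seq[s] == "A":
            score += 1
            count_a += 1
        else:
            score -= 2
        if score > best_score:  # strict: ties never extend the run
            best_score, best, best_count = score, s, count_a
    run_len = end - best
    if run_len < min_tail or best_count / run_len < purity:
        return None
    return best


def orient_and_detect_polya(
    read3: SeqRecord,
    min_tail: int = 8,
    max_end_gap: int = 3,
    purity: float = 0.9,
    primer_head: str = POLYT_PRIMER_HEAD,
) -> tuple[SeqRecord, int | None, bool]:
    """Orient a 3' read to the sense strand and locate its poly(A) tail.

    A raw 3' read typically begins with the poly(T) primer head followed by
    the T-run (the reverse complement of the tail); such reads are
    reverse-complemented after stripping the primer remnant.  Reads already
    in sense orientation pass through unchanged (the operation is
    idempotent).  Returns (sense_read, tail_start, was_flipped).
    """
    seq = read3.residues
    head_pos = _best_hamming_match(seq, primer_head, 10, 2)
    t_run = _leading_t_run(seq) >= min_tail
    if head_pos is not None:
        trimmed = read3.slice(head_pos + len(primer_head), len(seq))
        sense = trimmed.reverse_complement()
        flipped = True
    elif t_run:
        sense = read3.reverse_complement()
        flipped = True
    else:
        sense = read3
        flipped = False
    # strip a trailing primer-head remnant if the caller handed us a sense
    # read that still carries it
    rc_head = reverse_complement(primer_head)
    tail_seq = sense.residues[-len(rc_head) :]
    if len(tail_seq) == len(rc_head):
        mm = sum(1 for a, b in zip(tail_seq, rc_head) if a != b)
        if mm <= 2:
            sense = sense.slice(0, len(sense.residues) - len(rc_head))
    tail_start = find_polya_tail(sense.residues, min_tail, max_end_gap, purity)
    return sense, tail_start, flipped


def _leading_t_run(seq: str) -> int:
    for start in range(min(5, len(seq))):
        run = 0
        while start + run < len(seq) and seq[start + run] == "T":
            run += 1
        if run:
            return run
    return 0


def filter_length(insert_len: int, min_len: int = 150) -> bool:
    """Keep iff the trimmed insert is at least min_len bases (150 kept)."""
    return insert_len >= min_len


def dust_score(window: str) -> float:
    """DUST-style triplet over-representation score for one window."""
    k = len(window) - 2
    if k < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(k):
        t = window[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (k - 1)


def flag_low_complexity(
    seq: str,
    window: int = 64,
    threshold: float = 2.0,
    mask_intervals: list[tuple[int, int]] | None = None,
) -> bool:
    """True when the sequence looks repetitive.

    Windowed DUST-style triplet score (step = window/2); an externally
    supplied repeat mask is honored instead when it covers > 90% of the
    sequence.  The default threshold sits far above the score distribution
    of random sequence and far below that of simple repeats.
    """
    n = len(seq)
    if mask_intervals is not None:
        covered = sum(e - s for s, e in _merge_intervals(list(mask_intervals)))
        if n and covered / n > 0.9:
            return True
    if n < 8:
        return False
    step = max(1, window // 2)
    starts = list(range(0, max(1, n - window + 1), step))
    if starts[-1] + window < n:
        starts.append(n - window)
    for s in starts:
        if dust_score(seq[s : s + window]) > threshold:
            return True
    return False


def flag_mitochondrial(
    read: SeqRecord,
    mito_seq: str,
    min_aln_len: int = 100,
    min_identity: float = 0.95,
    seed_k: int = 16,
) -> bool:
    """True when a local ungapped match of >= min_aln_len at >= min_identity
    to either strand of the mitochondrial genome exists (seed-and-extend)."""
    if not mito_seq:
        return False
    index: dict[str, list[int]] = {}
    for j in range(len(mito_seq) - seed_k + 1):
        index.setdefault(mito_seq[j : j + seed_k], []).append(j)
    for seq in (read.residues, reverse_complement(read.residues)):
        for i in range(0, len(seq) - seed_k + 1, 8):
            for j in index.get(seq[i : i + seed_k], ()):
                start, end, matches = _extend_seed(seq, mito_seq, i, j, seed_k, 1.0)
                if end - start >= min_aln_len and matches / (end - start) >= min_identity:
                    return True
    return False


def preprocess_read(
    read: SeqRecord,
    vector_seqs: list[str] | None = None,
    mito_seq: str | None = None,
    quality_threshold: int = 20,
    min_len: int = 150,
    dust_threshold: float = 2.0,
    mask_intervals: list[tuple[int, int]] | None = None,
) -> ReadAnnotation:
    """Run the full per-read QC cascade in the fixed filter order
    quality -> vector -> length -> low-complexity -> mitochondrial."""
    n = len(read.residues)
    if read.qualities is not None:
        span = trim_quality(read, quality_threshold)
    else:
        span = (0, n)
    ann = ReadAnnotation(read_id=read.id, trimmed_span=span)
    work = read.slice(*span)

    if vector_seqs:
        v = trim_vector(work, vector_seqs)
        if v is DiscardReason.ALL_VECTOR:
            ann.discard_reason = DiscardReason.ALL_VECTOR
            return ann
        ann.trimmed_span = (span[0] + v[0], span[0] + v[1])
        work = work.slice(*v)

    end = read.end
    if end == "5p":
        cap_found, cap_end = detect_cap_tag(work)
        ann.cap_found = cap_found
        ann.cap_end = cap_end
        insert = work.slice(cap_end, len(work)) if cap_found else work
    else:
        insert, tail_start, _flipped = orient_and_detect_polya(work)
        ann.tail_start = tail_start

    if not filter_length(len(insert), min_len):
        ann.discard_reason = DiscardReason.TOO_SHORT
        return ann

    # the poly(A) tail is genuine low-complexity sequence; exclude it from
    # the repeat screen (5' reads of short inserts also run into the tail)
    if end == "3p" and ann.tail_start is not None:
        tail = ann.tail_start
    else:
        t5 = find_polya_tail(insert.residues)
        tail = t5 if t5 is not None else len(insert)
    if flag_low_complexity(insert.residues[:tail], threshold=dust_threshold,
                           mask_intervals=mask_intervals):
        ann.discard_reason = DiscardReason.LOW_COMPLEXITY
        return ann

    if mito_seq and flag_mitochondrial(insert, mito_seq):
        ann.discard_reason = DiscardReason.MITOCHONDRIAL
        return ann

    ann.insert = insert
    return ann
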