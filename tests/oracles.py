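"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by exhaustive enumeration or a full
(naive) dynamic program, sharing no code with the package internals beyond
the rule definitions themselves.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def best_window_bruteforce(quals: list[int], threshold: int = 20) -> tuple[int, int]:
    """Exhaustive O(n^2) maximal-score window of (q - threshold).

    Ties: smallest start, then smallest end; (0, 0) when nothing positive.
    """
    n = len(quals)
    best_score, best = 0, (0, 0)
    for i in range(n):
        s = 0
        for j in range(i + 1, n + 1):
            s += quals[j - 1] - threshold
            if s > best_score:
                best_score, best = s, (i, j)
    return best


def overlap_dp_full(
    seq5: str, seq3: str, match: int = 1, mismatch: int = -1, gap: int = -3
) -> tuple[int, int, int, list[tuple[str, str]]]:
    """Naive full-matrix suffix/prefix overlap alignment.

    Same scoring and tie-break conventions as the pipeline aligner (free
    leading gaps on seq5, free trailing gaps on seq3; end ties prefer the
    larger seq3 extent; traceback diag > up > left), computed cell by cell.
    """
    n, m = len(seq5), len(seq3)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = gap * j
    for i in range(1, n + 1):
        H[i][0] = 0
        row, prev = H[i], H[i - 1]
        c5 = seq5[i - 1]
        for j in range(1, m + 1):
            s = match if c5 == seq3[j - 1] else mismatch
            row[j] = max(prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
    best_j, best_score = 0, None
    for j in range(m + 1):
        if best_score is None or H[n][j] >= best_score:
            best_score, best_j = H[n][j], j
    cols: list[tuple[str, str]] = []
    i, j = n, best_j
    while j > 0:
        h = H[i][j]
        if i > 0 and H[i - 1][j - 1] + (match if seq5[i - 1] == seq3[j - 1] else mismatch) == h:
            cols.append((seq5[i - 1], seq3[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i - 1][j] + gap == h:
            cols.append((seq5[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", seq3[j - 1]))
            j -= 1
    cols.reverse()
    return best_score, i, best_j, cols


def merge_decision_oracle(
    seq5: str, seq3: str, min_identity: float = 0.95, min_overlap_frac: float = 0.5
) -> tuple[bool, int, float]:
    """Merge decision from the full overlap DP: (merge?, overlap_len, identity)."""
    _score, _i0, _j1, cols = overlap_dp_full(seq5, seq3)
    if not cols:
        return False, 0, 0.0
    matches = sum(1 for a, b in cols if a == b and a != "-")
    identity = matches / len(cols)
    ok = len(cols) > min_overlap_frac * min(len(seq5), len(seq3)) and identity >= min_identity
    return ok, len(cols), identity


def glocal_edit_distance_matrix(query: str, target: str) -> int:
    """Minimal edit distance of query aligned end-to-end inside target
    (free end gaps on target), by a full vectorized DP (no heuristics)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = len(t)
    prev = np.zeros(m + 1, dtype=np.int64)  # D[0][j] = 0, free start on target
    for i in range(1, len(q) + 1):
        sub = (t != q[i - 1]).astype(np.int64)
        tmin = np.minimum(prev[:m] + sub, prev[1:] + 1)
        cur = np.empty(m + 1, dtype=np.int64)
        # left chain: cur[j] = min(i + j?, ...) resolved by running min of tmin[k]-k
        arr = np.empty(m + 1, dtype=np.int64)
        arr[0] = i  # cur[0] = i (deleting the query prefix)
        arr[1:] = tmin - np.arange(1, m + 1)
        cur = np.arange(m + 1) + np.minimum.accumulate(arr)
        prev = cur
    return int(prev.min())


def greedy_cluster_oracle(
    named_seqs: list[tuple[str, str]], identity: float
) -> list[tuple[str, list[str]]]:
    """All-pairs greedy clustering with full-DP identities, no prefilter."""
    ordered = sorted(named_seqs, key=lambda t: (-len(t[1]), t[0]))
    clusters: list[tuple[str, list[str], str]] = []
    for name, seq in ordered:
        placed = False
        for rep_name, members, rep_seq in clusters:
            d = glocal_edit_distance_matrix(seq, rep_seq)
            if 1 - d / len(seq) >= identity:
                members.append(name)
                placed = True
                break
        if not placed:
            clusters.append((name, [name], seq))
    return [(rep, members) for rep, members, _seq in clusters]


def smith_waterman_best(a: str, b: str, match: int = 1, mismatch: int = -1,
                        gap: int = -1) -> int:
    """Best local-alignment score (naive Smith-Waterman, both strands of a
    handled by the caller)."""
    n, m = len(a), len(b)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def scan_signal_bruteforce(
    seq: str, tail_start: int, precedence: tuple[str, ...],
    min_gap: int = 5, max_gap: int = 30,
) -> tuple[str | None, int | None]:
    """Enumerate every (hexamer, placement) pair in the legal window and
    apply precedence-then-proximity explicitly.

    Returns (signal label or None, start or None).
    """
    candidates: list[tuple[int, int, int]] = []  # (precedence_rank, gap, start)
    for rank, hexamer in enumerate(precedence):
        pattern = hexamer.replace("U", "T")
        for start in range(0, len(seq) - 5):
            e = start + 6
            gap = tail_start - e
            if min_gap <= gap <= max_gap and seq[start:e] == pattern:
                candidates.append((rank, gap, start))
    if not candidates:
        return None, None
    rank, _gap, start = min(candidates)
    return precedence[rank], start


_GENETIC_CODE = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G
"""
_CODE = dict(zip(_GENETIC_CODE.split()[0::2], _GENETIC_CODE.split()[1::2]))


def translate_table_walk(seq: str) -> str:
    """Codon-by-codon translation against an explicitly listed code table."""
    return "".join(
        _CODE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3)
    )
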