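"""Pairing and overlap-merging of each clone's 5' and 3' reads.

A clone whose two reads overlap is merged into one full-length transcript.
The overlap is found by an exact suffix/prefix overlap alignment (dynamic
programming with free leading gaps on the 5' read and free trailing gaps on
the 3' read, vectorized row-by-row); the merge is accepted when the overlap
exceeds half the shorter read (strict) and its identity clears the floor.
At mismatch columns the consensus takes the higher-quality base, falling
back to the 5' read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from oligocap.records import SeqRecord

MATCH = 1
MISMATCH = -1
GAP = -3


@dataclass
class ClonePair:
    clone_id: str
    read5: SeqRecord
    read3: SeqRecord  # sense-oriented


@dataclass
class MergedTranscript:
    clone_id: str
    residues: str
    overlap_len: int
    overlap_identity: float
    source: tuple[str, str]
    tissue: str = ""


def pair_clone_reads(
    reads: list[SeqRecord],
) -> tuple[list[ClonePair], list[SeqRecord]]:
    """Group surviving reads into per-clone 5'/3' pairs plus orphans.

    Reads whose mate did not survive preprocessing come back as orphans and
    stay eligible for EST status.  Two reads with the same (clone, end) are
    an input error.
    """
    by_clone: dict[str, dict[str, SeqRecord]] = {}
    for read in reads:
        clone, end = read.clone_id, read.end
        slot = by_clone.setdefault(clone, {})
        if end in slot:
            raise ValueError(f"two reads for clone {clone!r} end {end}")
        slot[end] = read
    pairs: list[ClonePair] = []
    orphans: list[SeqRecord] = []
    for clone in sorted(by_clone):
        slot = by_clone[clone]
        if "5p" in slot and "3p" in slot:
            pairs.append(ClonePair(clone, slot["5p"], slot["3p"]))
        else:
            orphans.extend(slot.values())
    return pairs, orphans


def overlap_align(seq5: str, seq3: str) -> tuple[int, int, int, list[tuple[str, str]]]:
    """Best suffix(seq5)/prefix(seq3) overlap alignment.

    Scoring: match +1, mismatch -1, gap -3; leading gaps on seq5 and
    trailing gaps on seq3 are free.  Ties at the end cell prefer the larger
    seq3 extent; traceback prefers diagonal, then up, then left.

    Returns (score, i0, j1, columns) where the alignment spans
    seq5[i0:len(seq5)] against seq3[0:j1] and columns are
    (seq5_char_or_'-', seq3_char_or_'-') pairs.
    """
    n, m = len(seq5), len(seq3)
    a5 = np.frombuffer(seq5.encode(), dtype=np.uint8)
    a3 = np.frombuffer(seq3.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = GAP * np.arange(m + 1)
    H[:, 0] = 0
    gj = GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        s = np.where(a3 == a5[i - 1], MATCH, MISMATCH)
        t = np.maximum(H[i - 1, :m] + s, H[i - 1, 1:] + GAP)
        # resolve the within-row left-gap chain: H[i,j] = gj[j] + runmax(A[0..j])
        A = np.empty(m + 1, dtype=np.int64)
        A[0] = 0  # H[i,0] - gj[0]
        A[1:] = t - gj[1:]
        H[i, :] = gj + np.maximum.accumulate(A)
    j1 = int(m - np.argmax(H[n, ::-1]))  # largest j among score ties
    score = int(H[n, j1])
    # traceback
    cols: list[tuple[str, str]] = []
    i, j = n, j1
    while j > 0:
        h = H[i, j]
        if i > 0 and H[i - 1, j - 1] + (MATCH if seq5[i - 1] == seq3[j - 1] else MISMATCH) == h:
            cols.append((seq5[i - 1], seq3[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i - 1, j] + GAP == h:
            cols.append((seq5[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", seq3[j - 1]))
            j -= 1
    cols.reverse()
    return score, i, j1, cols


def merge_overlap(
    pair: ClonePair,
    min_identity: float = 0.95,
    min_overlap_frac: float = 0.5,
) -> MergedTranscript | None:
    """Merge a clone's reads when they overlap well enough, else None.

    Acceptance: overlap_len > min_overlap_frac * min(len5, len3) (strict,
    shorter-read denominator) AND identity >= min_identity.
    """
    r5, r3 = pair.read5, pair.read3
    n, m = len(r5.residues), len(r3.residues)
    if n == 0 or m == 0:
        return None
    _score, i0, j1, cols = overlap_align(r5.residues, r3.residues)
    overlap_len = len(cols)
    if overlap_len == 0:
        return None
    matches = sum(1 for a, b in cols if a == b and a != "-")
    identity = matches / overlap_len
    if not (overlap_len > min_overlap_frac * min(n, m)) or identity < min_identity:
        return None
    consensus = _consensus(cols, r5, i0, r3, 0)
    residues = r5.residues[:i0] + consensus + r3.residues[j1:]
    return MergedTranscript(
        clone_id=pair.clone_id,
        residues=residues,
        overlap_len=overlap_len,
        overlap_identity=identity,
        source=(r5.id, r3.id),
        tissue=r5.tissue or r3.tissue,
    )


def _consensus(
    cols: list[tuple[str, str]], r5: SeqRecord, i0: int, r3: SeqRecord, j0: int
) -> str:
    out: list[str] = []
    i, j = i0, j0
    for a, b in cols:
        if a == "-":
            out.append(b)
            j += 1
        elif b == "-":
            out.append(a)
            i += 1
        else:
            if a == b:
                out.append(a)
            else:
                q5 = r5.qualities[i] if r5.qualities else None
                q3 = r3.qualities[j] if r3.qualities else None
                if q5 is not None and q3 is not None and q3 > q5:
                    out.append(b)
                else:
                    out.append(a)
            i += 1
            j += 1
    return "".join(out)
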