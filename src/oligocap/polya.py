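"""Polyadenylation-signal detection and usage tables.

A transcript's signal is the highest-precedence hexamer whose end falls
5-30 bases (inclusive) upstream of the first base of the poly(A) tail.
Precedence runs canonical-first (AAUAAA, AUUAAA, then the alternative
signals); among several placements of the winning hexamer the one closest
to the tail is reported.  Matching is on the DNA alphabet (U = T); labels
are reported in the RNA alphabet.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from oligocap.records import SignalCall

# precedence order, canonical signals first
SIGNAL_PRECEDENCE: tuple[str, ...] = (
    "AAUAAA",
    "AUUAAA",
    "AGUAAA",
    "UAUAAA",
    "UUUAAA",
    "CAUAAA",
    "AAGAAA",
    "AAUACA",
    "GAUAAA",
    "AAUAUA",
    "AAAACA",
    "ACUAAA",
    "AAUGAA",
    "AAAAAG",
    "AAUAGA",
)

MIN_GAP = 5
MAX_GAP = 30


def _dna(hexamer: str) -> str:
    return hexamer.replace("U", "T")


def scan_signal(
    seq: str,
    tail_start: int,
    transcript_id: str = "",
    precedence: Sequence[str] = SIGNAL_PRECEDENCE,
    min_gap: int = MIN_GAP,
    max_gap: int = MAX_GAP,
) -> SignalCall:
    """Call the polyadenylation signal of one transcript.

    Scans, for each hexamer in precedence order, every placement whose end
    ``e`` satisfies min_gap <= tail_start - e <= max_gap; the first
    precedence rank with a placement wins, and the placement closest to
    the tail is reported.  Content downstream of tail_start never affects
    the call.
    """
    if not (0 <= tail_start <= len(seq)):
        raise ValueError(
            f"tail_start {tail_start} outside sequence of length {len(seq)}; "
            "transcripts without a detected tail must be filtered by the caller"
        )
    for hexamer in precedence:
        pattern = _dna(hexamer)
        # hexamer end e ranges over [tail_start - max_gap, tail_start - min_gap];
        # scan closest-to-tail first
        for e in range(tail_start - min_gap, tail_start - max_gap - 1, -1):
            s = e - 6
            if s < 0:
                break
            if seq[s:e] == pattern:
                return SignalCall(
                    transcript_id=transcript_id,
                    signal=hexamer,
                    start=s,
                    distance=tail_start - e,
                )
    return SignalCall(transcript_id=transcript_id, signal=None)


def usage_table(
    calls: Iterable[SignalCall],
    group_labels: Mapping[str, str] | None = None,
    precedence: Sequence[str] = SIGNAL_PRECEDENCE,
) -> pd.DataFrame:
    """Counts and percentages per signal per group.

    ``group_labels`` maps transcript_id -> group (e.g. coding/noncoding);
    with None, every call lands in one group called "all".  Percentages
    use all transcripts of the group as denominator, with an explicit
    "Not identifiable" row, and are rounded to one decimal.
    """
    counts: dict[str, Counter] = {}
    for call in calls:
        group = group_labels.get(call.transcript_id, "all") if group_labels else "all"
        counts.setdefault(group, Counter())[call.label] += 1
    row_order = list(precedence) + [SignalCall.NOT_IDENTIFIABLE]
    records = []
    for label in row_order:
        rec: dict[str, object] = {"signal": label}
        for group in sorted(counts):
            total = sum(counts[group].values())
            n = counts[group].get(label, 0)
            rec[f"{group}_count"] = n
            rec[f"{group}_pct"] = round(100 * n / total, 1) if total else 0.0
        records.append(rec)
    if not counts:
        records = [{"signal": label} for label in row_order]
    return pd.DataFrame.from_records(records)
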