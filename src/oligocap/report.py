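"""Per-tissue summary tables and count-conservation checks.

Mirrors the shape of the study-style summaries: full-length coding and
noncoding counts per tissue, 5'/3'-EST counts, non-redundant set sizes and
the signal-usage table, plus a conservation line asserting that every
input read ended in exactly one terminal bucket.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from oligocap.pipeline import PipelineResult
from oligocap.polya import usage_table
from oligocap.preprocess import DiscardReason
from oligocap.records import Category


def _tissue_of(result: PipelineResult, subject_id: str) -> str:
    clone = subject_id.rsplit("_", 1)[0]
    t = result.tissues.get(clone)
    if t:
        return t
    if "-" in clone:
        return clone.split("-", 1)[0]
    return "unknown"


def conservation_check(result: PipelineResult) -> tuple[bool, Counter]:
    """Every input read must occupy exactly one terminal bucket."""
    counts: Counter = Counter()
    for cat in result.read_category.values():
        counts[getattr(cat, "value", str(cat))] += 1
    ok = sum(counts.values()) == result.n_input_reads
    return ok, counts


def summarize_pipeline(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Report bundle: tissue table, disposition counts, nr sizes, signal usage."""
    rows: dict[str, Counter] = {}
    for read_id, cat in result.read_category.items():
        tissue = _tissue_of(result, read_id)
        label = getattr(cat, "value", str(cat))
        rows.setdefault(tissue, Counter())[label] += 1
    tissue_order = sorted(rows)
    all_labels = [c.value for c in Category] + [d.value for d in DiscardReason]
    tissue_df = pd.DataFrame(
        [
            {"tissue": t, **{lab: rows[t].get(lab, 0) for lab in all_labels}}
            for t in tissue_order
        ]
    )

    ok, counts = conservation_check(result)
    conservation_df = pd.DataFrame(
        [
            {
                "n_input_reads": result.n_input_reads,
                "n_classified": sum(counts.values()),
                "conserved": ok,
            }
        ]
    )

    nr_df = pd.DataFrame(
        [
            {
                "set": "protein_nr",
                "size": len(result.protein_nr),
            },
            {"set": "noncoding_nr", "size": len(result.noncoding_nr_clusters)},
            {"set": "est5_unique", "size": len(result.est5_clusters)},
            {"set": "est3_unique", "size": len(result.est3_clusters)},
        ]
    )

    group_labels = {
        m.clone_id: (
            "coding"
            if result.clone_class[m.clone_id].category is Category.FL_CODING
            else "noncoding"
        )
        for m in result.merged
        if m.clone_id in result.clone_class
    }
    signal_df = usage_table(result.signal_calls, group_labels)

    return {
        "per_tissue": tissue_df,
        "conservation": conservation_df,
        "nr_sets": nr_df,
        "signal_usage": signal_df,
    }


def render_text_summary(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for name in ("conservation", "per_tissue", "nr_sets", "signal_usage"):
        if name in tables:
            parts.append(f"== {name} ==")
            parts.append(tables[name].to_string(index=False))
            parts.append("")
    return "\n".join(parts)
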