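"""Homology-guided ORF prediction on full-length coding transcripts.

The reading frame comes from the best sense translated-alignment hit; the
CDS is seeded on the hit's query interval, extended upstream codon-by-codon
to the furthest in-frame ATG not separated from the seed by a stop, and
downstream to the first in-frame stop.  Transcripts are assumed
sense-oriented (oligo-capped clones encode their protein on the sense
strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from oligocap.records import EvidenceHit, SeqRecord

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
START_CODON = "ATG"


@dataclass
class OrfCall:
    transcript_id: str
    frame: int  # +1..+3
    cds_start: int  # 0-based half-open, nucleotides
    cds_end: int
    has_start_codon: bool
    has_stop_codon: bool
    protein: str


def translate_cds(seq: str, frame: int = 1) -> str:
    """Standard-code translation of a frame; '*' for stops, 'X' for codons
    containing N; a trailing partial codon is dropped."""
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be +1, +2 or +3, got {frame}")
    out = []
    for i in range(frame - 1, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TABLE[codon])
    return "".join(out)


def _is_stop(codon: str) -> bool:
    return "N" not in codon and codon in STOP_CODONS


def _is_start(codon: str) -> bool:
    return codon == START_CODON


def orf_from_evidence(transcript: SeqRecord, best_sense_hit: EvidenceHit) -> OrfCall:
    """Predict the ORF of a transcript from its best sense hit.

    Upstream extension: the furthest in-frame ATG with no in-frame stop
    between it and the seed; if a stop is met before any ATG, the CDS
    begins at the first in-frame codon after that stop with
    has_start_codon=False; running off the 5' end likewise leaves
    has_start_codon=False.  Downstream: the first in-frame stop closes the
    CDS (included in cds_end, excluded from the protein).
    """
    if best_sense_hit.frame <= 0:
        raise ValueError(
            f"hit {best_sense_hit.query_id}->{best_sense_hit.subject_id} is antisense; "
            "ORF prediction requires a sense hit"
        )
    seq = transcript.residues
    if best_sense_hit.q_end > len(seq):
        raise ValueError("hit interval lies outside the transcript")
    offset = best_sense_hit.frame - 1
    seed = best_sense_hit.q_start - ((best_sense_hit.q_start - offset) % 3)
    if seed < 0:
        seed += 3

    # upstream: collect in-frame ATGs until a stop or the 5' end
    furthest_atg: int | None = None
    stop_pos: int | None = None
    p = seed
    while p >= 0:
        codon = seq[p : p + 3]
        if len(codon) == 3 and _is_stop(codon) and p != seed:
            stop_pos = p
            break
        if len(codon) == 3 and _is_start(codon):
            furthest_atg = p
        p -= 3
    if furthest_atg is not None:
        cds_start, has_start = furthest_atg, True
    elif stop_pos is not None:
        cds_start, has_start = stop_pos + 3, False
    else:
        cds_start, has_start = seed % 3, False

    # downstream: first in-frame stop closes the CDS
    q = cds_start
    cds_end = None
    while q + 3 <= len(seq):
        if _is_stop(seq[q : q + 3]):
            cds_end = q + 3
            break
        q += 3
    if cds_end is not None:
        has_stop = True
        protein = translate_cds(seq[cds_start : cds_end - 3])
    else:
        has_stop = False
        cds_end = cds_start + 3 * ((len(seq) - cds_start) // 3)
        protein = translate_cds(seq[cds_start:cds_end])
    return OrfCall(
        transcript_id=transcript.id,
        frame=best_sense_hit.frame,
        cds_start=cds_start,
        cds_end=cds_end,
        has_start_codon=has_start,
        has_stop_codon=has_stop,
        protein=protein,
    )
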