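"""Reading and writing the file formats the pipeline touches.

FASTA and FASTQ (Sanger offset-33 qualities) go through Biopython.
Translated-alignment evidence arrives as a 13-column tab-separated table
(the 12 standard tabular-BLAST columns plus a subject description); an
optional 14th column carries the subject length in amino acids, which the
truncation tests downstream need.  File coordinates are 1-based inclusive
with minus-strand query hits encoded by ``q_start > q_end``; this module is
the single point where they are normalized to the package-internal 0-based
half-open forward-strand convention.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from oligocap.records import EvidenceHit, SeqRecord

EVIDENCE_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bitscore",
    "subject_desc",
]


class ParseError(ValueError):
    """Malformed record in an input file."""


def read_seq_records(path: str | os.PathLike, format: str = "fasta") -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file in file order.

    Lowercase residues are uppercased; gap ('-') or stop ('*') characters
    and duplicate identifiers are rejected.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {format!r}")
    seen: set[str] = set()
    for bio in _BioSeqIO.parse(os.fspath(path), format):
        if bio.id in seen:
            raise ParseError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        quals = bio.letter_annotations.get("phred_quality")
        try:
            yield SeqRecord(
                id=bio.id,
                residues=str(bio.seq),
                qualities=list(quals) if quals is not None else None,
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc


def write_seq_records(
    records: Iterable[SeqRecord], path: str | os.PathLike, format: str = "fasta"
) -> None:
    """Write records; round-trips with :func:`read_seq_records`."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {format!r}")
    bios = []
    for rec in records:
        bio = _BioRecord(Seq(rec.residues), id=rec.id, description="")
        if format == "fastq":
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            bio.letter_annotations["phred_quality"] = list(rec.qualities)
        bios.append(bio)
    with open(path, "w") as fh:
        _BioSeqIO.write(bios, fh, format)


def _infer_frame(q0: int, minus: bool) -> int:
    # reading-frame index from the alignment start offset; the sign is the
    # strand, which is the only part classification relies on
    mag = (q0 % 3) + 1
    return -mag if minus else mag


def read_evidence_table(path: str | os.PathLike) -> Iterator[EvidenceHit]:
    """Stream evidence hits, normalizing coordinates.

    Input: 1-based inclusive; minus-strand query hits have q_start > q_end.
    Output: 0-based half-open on the forward query strand, frame sign set
    from the input orientation.  Renormalizing already-normalized hits never
    happens because the convention switch lives only here.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ParseError(
                    f"{path}:{lineno}: expected >=13 tab-separated columns, got {len(fields)}"
                )
            try:
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                e_value = float(fields[10])
                pct = float(fields[2])
                bits = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            minus = qs > qe
            if minus:
                qs, qe = qe, qs
            q0, q1 = qs - 1, qe
            s0, s1 = ss - 1, se
            subject_len = int(fields[13]) if len(fields) > 13 and fields[13] != "" else None
            yield EvidenceHit(
                query_id=fields[0],
                subject_id=fields[1],
                subject_desc=fields[12],
                pct_identity=pct,
                e_value=e_value,
                q_start=q0,
                q_end=q1,
                s_start=s0,
                s_end=s1,
                frame=_infer_frame(q0, minus),
                bitscore=bits,
                subject_len=subject_len,
            )


def write_evidence_table(hits: Iterable[EvidenceHit], path: str | os.PathLike) -> None:
    """Write hits back to the 1-based inclusive file convention."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.q_start + 1, h.q_end
            if h.frame < 0:
                qs, qe = qe, qs
            aln_len = h.q_end - h.q_start
            mismatches = round(aln_len / 3 * (1 - h.pct_identity / 100))
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:.2f}",
                str(aln_len),
                str(mismatches),
                "0",
                str(qs),
                str(qe),
                str(h.s_start + 1),
                str(h.s_end),
                f"{h.e_value:.2g}",
                f"{h.bitscore:.1f}",
                h.subject_desc,
            ]
            if h.subject_len is not None:
                row.append(str(h.subject_len))
            fh.write("\t".join(row) + "\n")


def write_report_table(
    rows: Sequence[Mapping[str, object]], path: str | os.PathLike
) -> None:
    """Write a deterministic tab-separated report (rows sorted by first column)."""
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    header = list(rows[0].keys())
    for row in rows:
        if list(row.keys()) != header:
            raise ValueError("report rows do not share a common header")
    ordered = sorted(rows, key=lambda r: str(r[header[0]]))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in ordered:
            fh.write("\t".join(str(row[k]) for k in header) + "\n")
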