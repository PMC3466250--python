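"""Core record types shared across pipeline stages.

Coordinates are 0-based half-open on the forward strand everywhere inside
the package; 1-based inclusive conventions exist only at file boundaries
(see :mod:`oligocap.seqio`).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

_VALID_RESIDUES = frozenset("ACGTN")
_READ_ID_RE = re.compile(r"^(?P<clone>.+)_(?P<end>5p|3p)$")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """One Sanger read or assembled transcript.

    Read identifiers follow ``<clone>_<end>`` with end in {5p, 3p};
    transcript identifiers are free-form.  ``qualities`` are PHRED scores
    aligned base-for-base with ``residues``.
    """

    id: str
    residues: str
    qualities: list[int] | None = None
    tissue: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def clone_id(self) -> str:
        m = _READ_ID_RE.match(self.id)
        if m is None:
            raise ValueError(f"read id {self.id!r} does not match <clone>_<5p|3p>")
        return m.group("clone")

    @property
    def end(self) -> str:
        """'5p' or '3p' for reads; raises for free-form transcript ids."""
        m = _READ_ID_RE.match(self.id)
        if m is None:
            raise ValueError(f"read id {self.id!r} does not match <clone>_<5p|3p>")
        return m.group("end")

    def reverse_complement(self) -> "SeqRecord":
        quals = None if self.qualities is None else self.qualities[::-1]
        return SeqRecord(
            id=self.id,
            residues=reverse_complement(self.residues),
            qualities=quals,
            tissue=self.tissue,
        )

    def slice(self, start: int, end: int) -> "SeqRecord":
        quals = None if self.qualities is None else self.qualities[start:end]
        return SeqRecord(
            id=self.id,
            residues=self.residues[start:end],
            qualities=quals,
            tissue=self.tissue,
        )


@dataclass
class NamedSeq:
    """Minimal (id, residues) container for non-DNA sequences (e.g. proteins)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class EvidenceHit:
    """One row of translated-alignment evidence (a BLASTX-style hit).

    Query coordinates are nucleotide, 0-based half-open on the forward
    strand of the query; subject coordinates are amino-acid, 0-based
    half-open.  The sign of ``frame`` encodes the strand.
    """

    query_id: str
    subject_id: str
    subject_desc: str
    pct_identity: float
    e_value: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int
    bitscore: float
    subject_len: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bad query interval")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bad subject interval")
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"frame must be in +-1..3, got {self.frame}")

    @property
    def is_sense(self) -> bool:
        return self.frame > 0


class Category(str, enum.Enum):
    """Terminal buckets of the classification decision tree."""

    EST_TRUNCATED = "EST_TRUNCATED"
    FL_CODING = "FL_CODING"
    FL_NONCODING = "FL_NONCODING"
    EST5 = "EST5"
    EST3 = "EST3"
    WALKING_CANDIDATE = "WALKING_CANDIDATE"
    DISCARD_RT = "DISCARD_RT"
    DISCARD_SHORT_EST = "DISCARD_SHORT_EST"


class Basis(str, enum.Enum):
    BLAST_HIT_SENSE = "blast_hit_sense"
    BLAST_HIT_ANTISENSE = "blast_hit_antisense"
    NO_HIT = "no_hit"
    TRUNCATION = "truncation"
    PAIRING = "pairing"


@dataclass
class ClassificationRecord:
    subject_id: str  # clone or read id
    category: Category
    basis: Basis
    evidence_id: str | None = None


class LossCat(str, enum.Enum):
    SHARED = "SHARED"
    LOST_IN_TELEOSTS = "LOST_IN_TELEOSTS"
    LOST_IN_TETRAPODS = "LOST_IN_TETRAPODS"
    ABSENT_IN_BONY_VERTEBRATES = "ABSENT_IN_BONY_VERTEBRATES"


@dataclass
class LossCategory:
    gene_id: str
    category: LossCat
    per_group_presence: dict[str, bool]


@dataclass
class SignalCall:
    """Polyadenylation-signal call for one transcript.

    ``signal`` is an RNA-alphabet hexamer label or ``None`` when no signal
    lies in the legal window (reported as "Not identifiable" in tables);
    ``distance`` is the gap in bases between the hexamer end and the first
    base of the tail.
    """

    transcript_id: str
    signal: str | None
    start: int | None = None
    distance: int | None = None

    NOT_IDENTIFIABLE = "Not identifiable"

    @property
    def label(self) -> str:
        return self.signal if self.signal is not None else self.NOT_IDENTIFIABLE


@dataclass
class Cluster:
    rep_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_used: dict[str, float] = field(default_factory=dict)


@dataclass
class TruthRecord:
    """Simulator ground truth for one clone."""

    clone_id: str
    gene_id: str
    full_length: bool
    cds_start: int  # on the insert (adapter-free molecule), -1 for noncoding
    cds_end: int
    signal_used: str | None
    tail_len: int
    tissue: str
    insert_len: int = 0
    coding: bool = True
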