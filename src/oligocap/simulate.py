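"""Synthetic oligo-capped cDNA library generator with per-clone ground truth.

Emulates the molecule population an oligo-capped, size-selected, Sanger-
sequenced full-length cDNA library produces: mRNAs with UTRs, CDS, a
polyadenylation signal placed 5-30 bases upstream of a poly(A) tail;
5'-truncated molecules that fail cap ligation and therefore carry no cap
tag; the cap-tag and anchored-poly(T) adapters; size-selection windows;
paired 5'/3' reads with substitution errors and two-tier qualities.
Evidence tables equivalent to translated-alignment (BLASTX-style) hits are
derived from the truth linkage, so the whole pipeline runs without any
external database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from oligocap.preprocess import CAP_TAG, POLYT_PRIMER_HEAD
from oligocap.records import EvidenceHit, SeqRecord, TruthRecord, reverse_complement

TISSUES = ("gills", "intestine", "kidney", "liver", "spleen", "testis")

# Observed polyadenylation-signal composition of noncoding full-length
# transcripts (counts); the "None" key is the not-identifiable mass.
SIGNAL_COUNTS_NONCODING: dict[str | None, int] = {
    "AAUAAA": 3825,
    "AUUAAA": 1145,
    "AGUAAA": 120,
    "UAUAAA": 164,
    "UUUAAA": 63,
    "CAUAAA": 47,
    "AAGAAA": 36,
    "AAUACA": 54,
    "GAUAAA": 45,
    "AAUAUA": 56,
    "AAAACA": 16,
    "ACUAAA": 19,
    "AAUGAA": 22,
    "AAAAAG": 13,
    "AAUAGA": 7,
    None: 597,
}

SIGNAL_COUNTS_CODING: dict[str | None, int] = {
    "AAUAAA": 754,
    "AUUAAA": 199,
    "AGUAAA": 14,
    "UAUAAA": 33,
    "UUUAAA": 12,
    "CAUAAA": 11,
    "AAGAAA": 3,
    "AAUACA": 9,
    "GAUAAA": 10,
    "AAUAUA": 9,
    "AAAACA": 3,
    "ACUAAA": 1,
    "AAUGAA": 1,
    "AAAAAG": 2,
    "AAUAGA": 2,
    None: 110,
}


def signal_distribution_from_counts(
    counts: dict[str | None, int], include_unidentifiable: bool = True
) -> dict[str | None, float]:
    items = {
        k: v for k, v in counts.items() if include_unidentifiable or k is not None
    }
    total = sum(items.values())
    return {k: v / total for k, v in items.items()}


# length distributions: (kind, *params); normal/lognormal carry (loc, scale, lo, hi)
LenDist = tuple


def sample_len(rng: np.random.Generator, dist: LenDist) -> int:
    kind = dist[0]
    if kind == "uniform":
        _, lo, hi = dist
        return int(rng.integers(lo, hi + 1))
    if kind == "normal":
        _, loc, scale, lo, hi = dist
        return int(np.clip(round(rng.normal(loc, scale)), lo, hi))
    if kind == "lognormal":
        _, mu, sigma, lo, hi = dist
        return int(np.clip(round(rng.lognormal(mu, sigma)), lo, hi))
    if kind == "const":
        return int(dist[1])
    raise ValueError(f"unknown length distribution {dist!r}")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic library."""

    n_genes: int = 200
    fraction_coding: float = 0.4
    cds_len_dist: LenDist = ("lognormal", math.log(250), 0.4, 60, 900)  # codons
    utr5_len_dist: LenDist = ("normal", 120, 40, 20, 300)
    utr3_len_dist: LenDist = ("normal", 400, 150, 60, 1200)
    noncoding_len_dist: LenDist = ("lognormal", math.log(900), 0.4, 200, 3200)
    tail_len_dist: LenDist = ("normal", 30, 8, 15, 60)
    signal_distribution: dict[str | None, float] = field(
        default_factory=lambda: signal_distribution_from_counts(SIGNAL_COUNTS_NONCODING)
    )
    truncation_prob: float = 0.2
    error_rate: float = 0.005
    read_len_dist: LenDist = ("normal", 750, 60, 400, 1000)
    size_window: tuple[int, int] = (500, 3500)
    low_quality_tail: int = 30  # Q10 bases at the read ends
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.signal_distribution.values())
        if abs(total - 1.0) > 1e-9:
            self.signal_distribution = {
                k: v / total for k, v in self.signal_distribution.items()
            }


@dataclass
class Gene:
    gene_id: str
    mrna: str  # UTR5 + CDS + UTR3 + tail (coding) or body + tail (noncoding)
    cds_start: int  # -1 for noncoding
    cds_end: int
    protein: str | None
    signal_used: str | None
    tail_len: int
    tail_start: int
    coding: bool


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODON_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _CODON_BASES
    for b in _CODON_BASES
    for c in _CODON_BASES
    if a + b + c not in _STOPS
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return rng.choice(BASES, size=n).tobytes().decode()


def _dna(hexamer: str) -> str:
    return hexamer.replace("U", "T")


def _window_clean(window: str, keep_span: tuple[int, int] | None = None) -> bool:
    """True when no signal hexamer occurs in the window except inside keep_span."""
    patterns = [_dna(h) for h in SIGNAL_COUNTS_NONCODING if h is not None]
    for i in range(len(window) - 5):
        if keep_span is not None and keep_span[0] <= i < keep_span[1]:
            continue
        if window[i : i + 6] in patterns:
            return False
    return True


def _make_signal_region(
    rng: np.random.Generator, signal: str | None, min_gap: int = 5, max_gap: int = 30
) -> str:
    """Terminal 3'UTR stretch covering the whole 5-30 bp signal window.

    Returns the max_gap+6-base region immediately upstream of the tail,
    containing exactly the planted hexamer (at a uniform gap) or none.
    """
    width = max_gap + 6  # positions whose hexamer end falls within the window
    for _ in range(1000):
        region = _random_seq(rng, width)
        if signal is None:
            if _window_clean(region):
                return region
            continue
        gap = int(rng.integers(min_gap, max_gap + 1))
        # hexamer end sits gap bases before the tail (= region end)
        e = width - gap
        s = e - 6
        region = region[:s] + _dna(signal) + region[e:]
        if _window_clean(region, keep_span=(s, s + 1)):
            # clean except the planted placement itself; also require that
            # no *other* placement of any hexamer survives inside the window
            return region
    raise RuntimeError("failed to build a clean signal region")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [
        _NONSTOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=max(0, n_codons - 2))
    ]
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    return "ATG" + "".join(codons) + stop


def make_transcriptome(config: SynthConfig, rng: np.random.Generator | None = None) -> list[Gene]:
    """Generate genes and their mRNAs (deterministic under config.seed).

    Each mRNA embeds exactly one planted signal hexamer whose end lies a
    uniform 5-30 bases upstream of the tail (or a scrubbed window for the
    not-identifiable fraction).  Coding mRNAs carry an in-frame stop
    immediately upstream of the true ATG so that homology-guided ORF
    extension recovers exactly the true protein.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = list(config.signal_distribution.keys())
    probs = np.array([config.signal_distribution[k] for k in labels])
    genes: list[Gene] = []
    for idx in range(config.n_genes):
        gene_id = f"g{idx:05d}"
        coding = rng.random() < config.fraction_coding
        signal = labels[int(rng.choice(len(labels), p=probs))]
        tail_len = sample_len(rng, config.tail_len_dist)
        region = _make_signal_region(rng, signal)
        if coding:
            n_codons = sample_len(rng, config.cds_len_dist)
            cds = _random_cds(rng, n_codons)
            utr5 = _random_seq(rng, sample_len(rng, config.utr5_len_dist))
            # in-frame stop just upstream of the ATG pins the ORF start
            if len(utr5) >= 3:
                utr5 = utr5[:-3] + "TAA"
            utr3_len = sample_len(rng, config.utr3_len_dist)
            utr3_head = _random_seq(rng, max(0, utr3_len - len(region)))
            body = utr5 + cds + utr3_head + region
            cds_start = len(utr5)
            cds_end = cds_start + len(cds)
            from oligocap.orf import translate_cds

            protein = translate_cds(cds[:-3])
        else:
            body_len = sample_len(rng, config.noncoding_len_dist)
            body = _random_seq(rng, max(0, body_len - len(region))) + region
            cds_start = cds_end = -1
            protein = None
        mrna = body + "A" * tail_len
        genes.append(
            Gene(
                gene_id=gene_id,
                mrna=mrna,
                cds_start=cds_start,
                cds_end=cds_end,
                protein=protein,
                signal_used=signal,
                tail_len=tail_len,
                tail_start=len(body),
                coding=coding,
            )
        )
    return genes


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


@dataclass
class LibraryClone:
    clone_id: str
    read5: SeqRecord
    read3: SeqRecord
    truth: TruthRecord
    molecule_span: tuple[int, int]  # span of the (possibly truncated) molecule on the mRNA


def simulate_library(
    genes: list[Gene], config: SynthConfig, rng: np.random.Generator | None = None
) -> list[LibraryClone]:
    """Clone and sequence the transcriptome: one clone per mRNA.

    With probability truncation_prob a molecule loses a random 5' prefix
    and gets no cap tag (it cannot be ligated); intact molecules receive
    the cap tag.  Inserts outside the size-selection window are dropped.
    The 5' read covers the first read-length bases of the insert; the 3'
    read is the reverse complement of the last read-length bases (tail and
    poly(T)-primer remnant included).  Substitution errors at error_rate;
    qualities Q40 with Q10 tails.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    clones: list[LibraryClone] = []
    rc_primer = reverse_complement(POLYT_PRIMER_HEAD)
    for gene in genes:
        tissue = TISSUES[int(rng.integers(0, len(TISSUES)))]
        clone_id = f"{tissue}-{gene.gene_id}"
        mol = gene.mrna
        truncated = rng.random() < config.truncation_prob
        trunc_at = 0
        if truncated and len(mol) > 150:
            trunc_at = int(rng.integers(1, len(mol) - 100))
            mol = mol[trunc_at:]
        insert = ("" if truncated else CAP_TAG) + mol + rc_primer
        if not (config.size_window[0] <= len(insert) <= config.size_window[1]):
            continue
        len5 = sample_len(rng, config.read_len_dist)
        len3 = sample_len(rng, config.read_len_dist)
        raw5 = insert[: min(len5, len(insert))]
        raw3 = reverse_complement(insert[max(0, len(insert) - len3) :])
        raw5 = _mutate(rng, raw5, config.error_rate)
        raw3 = _mutate(rng, raw3, config.error_rate)
        read5 = SeqRecord(
            id=f"{clone_id}_5p", residues=raw5,
            qualities=_qualities(len(raw5), config.low_quality_tail), tissue=tissue,
        )
        read3 = SeqRecord(
            id=f"{clone_id}_3p", residues=raw3,
            qualities=_qualities(len(raw3), config.low_quality_tail), tissue=tissue,
        )
        truth = TruthRecord(
            clone_id=clone_id,
            gene_id=gene.gene_id,
            full_length=not truncated,
            cds_start=gene.cds_start - trunc_at if gene.coding else -1,
            cds_end=gene.cds_end - trunc_at if gene.coding else -1,
            signal_used=gene.signal_used,
            tail_len=gene.tail_len,
            tissue=tissue,
            insert_len=len(mol),
            coding=gene.coding,
        )
        clones.append(LibraryClone(clone_id, read5, read3, truth, (trunc_at, len(gene.mrna))))
    return clones


def _qualities(n: int, low_tail: int) -> list[int]:
    if n <= low_tail:
        return [40] * n
    return [40] * (n - low_tail) + [10] * low_tail


def simulate_evidence(
    seqs: list[SeqRecord],
    genes: list[Gene],
    clone_of: dict[str, str],
    truths: dict[str, TruthRecord],
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    min_overlap_nt: int = 30,
) -> list[EvidenceHit]:
    """Truth-derived translated-alignment evidence for sense-oriented sequences.

    Each sequence deriving from a coding gene gets one sense hit to its
    true protein, with coordinates found by locating the sequence on the
    clean mRNA; with probability ``noise`` a decoy (antisense or
    reverse-transcriptase) hit is added to exercise the downstream
    filters.  ``clone_of`` maps sequence id -> clone id.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    by_gene = {g.gene_id: g for g in genes}
    hits: list[EvidenceHit] = []
    for rec in seqs:
        clone = clone_of.get(rec.id)
        truth = truths.get(clone) if clone else None
        gene = by_gene.get(truth.gene_id) if truth else None
        true_hit = None
        if gene is not None and gene.coding:
            true_hit = _true_hit(rec, gene, rng, min_overlap_nt)
            if true_hit is not None:
                hits.append(true_hit)
        if rng.random() < noise:
            hits.append(_decoy_hit(rec, rng))
    return hits


def _true_hit(
    rec: SeqRecord, gene: Gene, rng: np.random.Generator, min_overlap_nt: int
) -> EvidenceHit | None:
    aln = edlib.align(rec.residues, gene.mrna, mode="HW", task="locations")
    if aln["editDistance"] < 0 or not aln["locations"]:
        return None
    if aln["editDistance"] > 0.2 * len(rec.residues):
        return None
    a, b_incl = aln["locations"][0]
    b = b_incl + 1
    coding_lo, coding_hi = gene.cds_start, gene.cds_end - 3  # exclude the stop
    o0, o1 = max(coding_lo, a), min(coding_hi, b)
    if o1 - o0 < min_overlap_nt:
        return None
    c0 = gene.cds_start - a  # CDS start in sequence coordinates (may be < 0)
    q_start = o0 - a
    shift = (q_start - c0) % 3
    if shift:
        q_start += 3 - shift
    n_aa = (o1 - a - q_start) // 3
    if n_aa < min_overlap_nt // 3:
        return None
    q_end = q_start + 3 * n_aa
    s_start = (q_start - c0) // 3
    s_end = s_start + n_aa
    ident = 100.0 * (1 - aln["editDistance"] / max(1, len(rec.residues)))
    protein_len = (gene.cds_end - gene.cds_start) // 3 - 1
    return EvidenceHit(
        query_id=rec.id,
        subject_id=f"P_{gene.gene_id}",
        subject_desc=f"hypothetical protein {gene.gene_id}",
        pct_identity=round(ident, 2),
        e_value=10.0 ** -float(rng.uniform(20, 60)),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        frame=(c0 % 3) + 1,
        bitscore=round(2.0 * n_aa, 1),
        subject_len=protein_len,
    )


def expected_clone_categories(
    clones: list[LibraryClone],
    annotations: dict,
    hits: list[EvidenceHit],
    e_max: float = 1e-7,
    margin_aa: int = 20,
    min_est_len: int = 300,
    min_overlap_frac: float = 0.5,
    walking_n: int = 800,
) -> dict[str, tuple[object, object]]:
    """Expected terminal bucket of each clone's two reads, derived from
    ground truth and read geometry rather than from alignment outcomes.

    The merge decision is predicted arithmetically: the 5' insert covers
    the first l5 bases of the (possibly truncated) molecule and the 3'
    insert the last l3, so their true overlap is l5 + l3 - molecule
    length; a merge is expected when that exceeds half the shorter
    insert.  Everything else follows the decision-tree rules applied to
    the truth-derived evidence.  Serves as the independent oracle for
    end-to-end recovery checks; discrepancies against the pipeline are
    attributable to size-selection or read-length boundary effects.
    """
    from oligocap.records import Category

    hits_by_query: dict[str, list[EvidenceHit]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)

    def _sense_best(read_id: str):
        sense = [
            h for h in hits_by_query.get(read_id, ())
            if h.is_sense and h.e_value < e_max
        ]
        return min(sense, key=lambda h: (h.e_value, -h.bitscore, h.subject_id)) if sense else None

    expected: dict[str, tuple[object, object]] = {}
    state: dict[str, dict] = {}
    for lc in clones:
        t = lc.truth
        ann5 = annotations.get(lc.read5.id)
        ann3 = annotations.get(lc.read3.id)
        cat5 = ann5.discard_reason if ann5 else None
        cat3 = ann3.discard_reason if ann3 else None
        l5 = len(ann5.insert) if ann5 and ann5.insert is not None else 0
        l3 = len(ann3.insert) if ann3 and ann3.insert is not None else 0
        # truncation triage
        if cat5 is None:
            top5 = _sense_best(lc.read5.id)
            if top5 is not None and (
                not t.full_length
                or (top5.s_start > margin_aa and top5.q_start < 3 * margin_aa)
            ):
                cat5 = Category.EST_TRUNCATED
        if cat3 is None:
            top3 = _sense_best(lc.read3.id)
            if top3 is not None and ann3.tail_start is None:
                cat3 = Category.EST_TRUNCATED
            elif (
                top3 is not None
                and top3.subject_len is not None
                and top3.s_end < top3.subject_len - margin_aa
                and top3.q_end > l3 - 3 * margin_aa
            ):
                cat3 = Category.EST_TRUNCATED
        both_free = cat5 is None and cat3 is None
        overlap_true = l5 + l3 - t.insert_len
        merged = both_free and overlap_true > min_overlap_frac * min(l5, l3)
        if merged:
            coding = _sense_best(lc.read5.id) is not None or _sense_best(lc.read3.id) is not None
            cat = Category.FL_CODING if coding else Category.FL_NONCODING
            expected[lc.clone_id] = (cat, cat)
            continue
        state[lc.clone_id] = {
            "cat5": cat5, "cat3": cat3, "l5": l5, "l3": l3,
            "free5": cat5 is None, "free3": cat3 is None,
        }
    # walking qualification among unmerged clones with both reads free
    qualifying: list[tuple[int, str]] = []
    for clone_id, st in state.items():
        if not (st["free5"] and st["free3"]):
            continue
        subj5 = {
            h.subject_id
            for h in hits_by_query.get(f"{clone_id}_5p", ())
            if h.is_sense and h.e_value < e_max and h.s_start <= margin_aa
        }
        for h in hits_by_query.get(f"{clone_id}_3p", ()):
            if (
                h.is_sense and h.e_value < e_max and h.subject_id in subj5
                and h.subject_len is not None
                and h.s_end >= h.subject_len - margin_aa
            ):
                qualifying.append((st["l5"], clone_id))
                break
    qualifying.sort(key=lambda x: (-x[0], x[1]))
    walkers = {clone_id for _l, clone_id in qualifying[:walking_n]}
    for clone_id, st in state.items():
        if clone_id in walkers:
            expected[clone_id] = (Category.WALKING_CANDIDATE, Category.WALKING_CANDIDATE)
            continue
        cat5, cat3 = st["cat5"], st["cat3"]
        if cat5 is None:
            cat5 = Category.EST5 if st["l5"] >= min_est_len else Category.DISCARD_SHORT_EST
        if cat3 is None:
            cat3 = Category.EST3 if st["l3"] >= min_est_len else Category.DISCARD_SHORT_EST
        expected[clone_id] = (cat5, cat3)
    return expected


def _decoy_hit(rec: SeqRecord, rng: np.random.Generator) -> EvidenceHit:
    n = len(rec.residues)
    q_start = int(rng.integers(0, max(1, n - 90)))
    q_end = min(n, q_start + 90)
    if rng.random() < 0.5:
        return EvidenceHit(
            query_id=rec.id,
            subject_id="RT_decoy",
            subject_desc="pol-like reverse transcriptase",
            pct_identity=55.0,
            e_value=1e-80,
            q_start=q_start,
            q_end=q_end,
            s_start=0,
            s_end=30,
            frame=(q_start % 3) + 1,
            bitscore=200.0,
            subject_len=300,
        )
    return EvidenceHit(
        query_id=rec.id,
        subject_id="AS_decoy",
        subject_desc="uncharacterized protein (antisense decoy)",
        pct_identity=40.0,
        e_value=1e-20,
        q_start=q_start,
        q_end=q_end,
        s_start=0,
        s_end=30,
        frame=-((q_start % 3) + 1),
        bitscore=80.0,
        subject_len=200,
    )
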