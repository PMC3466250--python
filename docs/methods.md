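# Methods

This note records the models, parameter choices and numerical conventions
behind the pipeline, and what the synthetic-data generator does and does
not emulate.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open on the forward strand; the
1-based inclusive convention of tabular alignment files exists only at the
file boundary (`oligocap.seqio`), which is the single conversion point.
Minus-strand query hits are encoded in files by `q_start > q_end` and
normalized on read; the reading-frame index is reconstructed as
`(q_start mod 3) + 1` with the sign carrying the strand — downstream logic
depends on the sign and on `q_start` being in-frame, not on the magnitude
matching any particular external tool's frame numbering. 3′ reads are
reverse-complemented to sense orientation during QC, so every sequence
seen after preprocessing is sense-strand.

## Per-read QC

**Quality trimming.** The retained window maximises the running sum of
(q − 20) over a contiguous window (Mott's algorithm); the threshold of 20
is the conventional PHRED floor for Sanger data. Ties are broken toward
the smallest start, then the smallest end, and a window is only kept if
its score is positive — these conventions are shared with the exhaustive
O(n²) oracle in the tests, making agreement exact rather than approximate.

**Cap tag.** The tag is the DNA copy of the 30-nt capping oligonucleotide
(`AGCATCGAGTCGGCCTTGTTGGCCTACTGG`), searched in the first 60 bases with ≤2
substitutions. Because SfiI digestion during cloning can truncate the tag,
the 7-nt remnant `CTACTGG` is also accepted, but only as an exact match:
at 7 nt, allowing a mismatch would produce ~7% false caps per read on
capless reads, destroying the information the cap carries.

**Poly(A) tail.** A tail is a terminal run ≥8 bases, ≥90% A, whose last A
lies within 3 bases of the sequence end. The left extension is score-based
(+1 per A, −2 per non-A, extended only on strict improvement): isolated
sequencing errors inside the tail are absorbed, but the run cannot creep
into merely A-rich upstream sequence — important because every extra base
claimed by the tail shrinks the 5–30-base signal window and would
otherwise erase legitimately placed hexamers. 3′ reads are recognised
as antisense by the poly(T)-primer head (`GCGGCTGAAGACGGCC TATGTGGCC`, ≤2
mismatches, first 10 positions) or a leading T-run; the primer remnant is
stripped before reverse complementing. The operation is idempotent on
sense reads.

**Length filter.** Inserts shorter than 150 bases (after adapter removal —
the length that carries information) are discarded; 150 itself is kept.

**Low complexity.** A windowed DUST-style score (triplet over-representation,
64-base windows, step 32) replaces a repeat-library masker; externally
produced mask intervals are honoured when they cover >90% of a read. The
threshold 2.0 is the classic DUST operating point: random sequence scores
~0.5 with a 99.9th percentile still below 1 (verified in the tests), while
simple repeats score >10. The poly(A) tail is genuine low-complexity
sequence and is excluded from the scan on both read types; without this a
large fraction of 3′ reads (and 5′ reads of short inserts) would be
discarded for carrying exactly the feature the library selects for.

**Mitochondrial screen.** Reads matching the mitochondrial genome over
≥100 nt at ≥95% identity on either strand are discarded. Matching is
16-mer seed + ungapped X-drop extension, which is deterministic,
database-free and adequate for the substitution-dominated Sanger error
model; the tests verify against a full Smith–Waterman oracle that
negatives have no qualifying alignment.

**Filter order** is fixed — quality → vector → length → complexity →
mitochondrial — and the first failing filter names the discard reason, so
every read has exactly one terminal disposition.

## Overlap assembly

Merging uses an exact suffix/prefix overlap alignment: free leading gaps on
the 5′ read and free trailing gaps on the 3′ read, scores +1/−1/−3
(match/mismatch/gap), computed by a row-vectorised dynamic program over
the full matrix (the running-maximum trick resolves the within-row gap
chain exactly, so no band heuristic is needed). End-cell ties prefer the
larger 3′-read extent; traceback prefers diagonal, then up, then left.
These tie-breaks are duplicated in the naive full-matrix oracle, making
the comparison bit-exact. A merge is accepted when the overlap exceeds
half the *shorter* read (strict inequality) and its identity is ≥0.95;
the shorter-read denominator and the identity floor are package choices
where the underlying assembler convention is ambiguous, and both are
configurable. At mismatch columns the consensus takes the higher-quality
base, falling back to the 5′ read — a deterministic tie-break.

## Clustering

Greedy incremental clustering processes sequences longest-first
(lexicographic id on ties) and joins each sequence to the first cluster
whose representative it matches, so the result is independent of input
file order. Identity between a sequence and a representative is defined as
`1 − d / len(shorter)` where `d` is the minimal glocal edit distance (the
shorter sequence aligned end-to-end inside the longer, end gaps on the
longer free). This distance-based definition was chosen over
"matches / alignment columns" because the minimal distance is unique while
the match count depends on which co-optimal path an aligner returns;
determinism is what lets the k-mer prefilter (8-mers for nucleotide,
4-mers for protein) be a pure performance device that provably cannot
change the partition at the identity levels used (0.90–0.99). Because the
shorter sequence is aligned over its whole length, the coverage-of-shorter
requirement is satisfied by construction. The two-set variant first
removes query sequences redundant with any reference (identity over the
shorter of the two) — this is what excludes noncoding transcripts that are
really UTR fragments of coding transcripts — and then clusters the
survivors.

## Polyadenylation signals

Fifteen hexamers are scanned in a fixed precedence order (canonical
AAUAAA, AUUAAA first). A placement is legal when the gap between the
hexamer's end and the first tail base is between 5 and 30 inclusive — the
inclusive reading of "between 5 bp and 30 bp upstream" is a documented,
configurable choice. The first precedence rank with a legal placement
wins; among placements of that hexamer the one closest to the tail is
reported. Matching is on DNA (U≡T); labels are RNA to match the
conventional table format. Sequence content downstream of the tail start
can never affect a call.

## Homology-guided ORFs

The frame comes from the single best sense hit (lowest e-value, then
highest bitscore, then lexicographic subject). The CDS is seeded on the
hit's query interval and extended upstream codon-by-codon to the
*furthest* in-frame ATG not separated from the seed by a stop — the
furthest-ATG rule maximises the CDS, which is the appropriate prior for
full-length clones (nearest-ATG is available as a configuration). If a
stop intervenes before any ATG the CDS starts just after it with
`has_start_codon=False`; running off the 5′ end likewise. Downstream, the
first in-frame stop closes the CDS (included in the coordinates, excluded
from the protein), so predicted proteins can never contain `*`. Codons
containing N translate to X and never count as start or stop.

## The synthetic library generator

The generator emulates the molecule population of an oligo-capped,
size-selected cDNA library; its defaults are the study conditions used
throughout the tests:

- 200 genes per library (5,000 for signal-usage recovery, where the
  quantity measured is a proportion), 40% coding;
- CDS length lognormal (median 250 codons), 5′UTR ~N(120, 40), 3′UTR
  ~N(400, 150) bases, tail ~N(30, 8) — molecule sizes centred ~1.3 kb so
  that, with ~750-base reads, a realistic mix of merging (short) and
  non-merging (long) clones arises;
- polyadenylation-signal composition defaulting to the observed
  noncoding-transcript proportions (AAUAAA 61.4%, AUUAAA 18.4%, …,
  not-identifiable 9.6%), planted with a uniform 5–30-base gap; for the
  not-identifiable fraction the window is scrubbed of all fifteen
  hexamers, and for planted signals the window is rejected-and-resampled
  until the planted hexamer is the unique precedence-first call, making
  the truth label exact;
- truncation probability 0.2: a truncated molecule loses a uniform 5′
  prefix and receives **no** cap tag, mirroring the chemistry in which
  only decapped full-length RNA ligates the capping oligo — this is what
  makes cap presence informative;
- size selection keeps inserts of 0.5–3.5 kb (the union of the two gel
  fractions);
- reads ~N(750, 60) bases with substitution-only errors (rate 0.005 by
  default; Sanger indels are rare enough that modelling them would only
  complicate the oracles), qualities Q40 with a 30-base Q10 tail to
  exercise trimming;
- an in-frame stop codon is written immediately upstream of each true ATG
  so that the furthest-ATG extension rule provably recovers exactly the
  true protein on error-free data.

Evidence tables are derived from the truth linkage: each coding sequence
is located on its clean source mRNA (glocal alignment) and a sense hit
with exact frame and interval arithmetic is emitted; optional decoys
(antisense or "reverse transcriptase" subjects, at a configurable rate)
exercise the classification filters. What the generator does **not**
emulate: chimeric clones, internal priming, indel errors, realistic
quality profiles beyond two tiers, paralogy/cross-homology between genes,
and expression-level variation (one clone per gene). Passing tests
therefore demonstrate correctness of the decision logic and the
arithmetic, not robustness to those real-data artifacts.

The expected-category oracle used in end-to-end checks derives each
clone's bucket from truth and geometry alone: the true overlap of the two
inserts is `l5 + l3 − molecule length`, so the merge decision, the triage
and the EST routing can be predicted without running any aligner.
Remaining discrepancies (historically <1% of clones) trace to boundary
effects — overlaps within a base or two of the 50% threshold, or chance
cap-like sequence — and are enumerated in a discrepancy report rather
than hidden.

## Problem sizes and determinism

The default test/driver sizes — 1,000 strings for the trimming oracle,
1,000 planted sequences for the precedence oracle, 100 sequences × 3
identity levels for the clustering oracle, 200 pairs for the merge oracle,
200 genes end-to-end and 5,000 transcripts for usage recovery — keep the
full suite under a minute while leaving every comparison exact. All
randomness flows from explicit integer seeds; the same seed reproduces
byte-identical libraries and reports.

## Known limitations

- The mitochondrial and vector screens are ungapped seed-and-extend
  heuristics; a diverged mitochondrial haplotype with many indels could
  escape them.
- Clustering identity is distance-based (see above) and will disagree
  with match-count definitions by a fraction of a percent near
  thresholds; counts on real data are expected to deviate slightly from
  any specific external clustering tool's output.
- The gene-loss categorizer operates on a presence matrix supplied by the
  caller; producing that matrix (real proteome searches) is outside the
  package.
- Tissue labels ride on clone identifiers (`<tissue>-<gene>_<end>`); a
  sample sheet can override this but no LIMS integration exists.
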