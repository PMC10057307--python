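# Methods

This note documents the models, conventions and numerical choices behind
`vdjrep`, and what its tests do and do not demonstrate.

## Read merging

Amplicon pairs are merged by exhaustive overlap search: the reverse mate is
reverse-complemented and every overlap length `o ≥ min_overlap` (default 10)
is scored as `matches − mismatches`; the best-scoring admissible overlap
(mismatch fraction ≤ `max_mismatch_frac`, default 0.25) wins. Consensus
rules: agreeing bases get quality `min(q1+q2, 41)`; disagreeing bases are
resolved in favour of the higher quality with consensus quality `|q1−q2|`
(ties go to the forward mate); `N` is mismatch-neutral and always loses to a
called base. This is a deliberately explicit-parameter merger: the
maximum-likelihood significance test used by dedicated merging tools is
omitted because designed amplicon overlaps (≥ 50 nt here) make the
maximum-score criterion unambiguous. Adapter/quality trimming is out of
scope.

## Germline reference and the toy set

Segments are keyed by IMGT-style allele names (`IGHV4-34*01`). Subfamily and
gene labels are derived deterministically from the name (`VH4`, `VH4-34`);
`D`-duplicated genes (e.g. `IGKV2D-29`) fold into the non-D subfamily but
keep their own gene label. IMGT-gapped input is accepted by stripping `.`
characters; Kabat numbering is carried by a tab-separated sidecar
(`segment_id <TAB> H1,H2,...`). A V segment without a sidecar entry gets its
map transferred through a protein alignment against a mapped same-family
segment, and is rejected if none exists.

The packaged toy set is **fully synthetic** (random codons with a few
conserved landmarks: the FR1 start, the CDR1-flanking cysteine, the FR2
tryptophan, the FR3 cysteine): 7 V + 4 J for the heavy locus, 7 V + 3 J for
kappa. Toy heavy V segments span Kabat H1–H96 (two residues into HCDR3),
kappa V segments L1–L95 (seven residues into LCDR3), matching where real V
genes end. Segments within a locus are pairwise ≳ 28% divergent at the
nucleotide level so that top-hit assignment is unambiguous at zero noise —
this intentionally removes the allele-level ambiguity of real germline
databases, so recovery tests certify the pipeline, not the separability of
real alleles. J segments carry no Kabat map; instead the loader locates the
conserved FR4 anchor motif (W-G-x-G on heavy, F-G-x-G on kappa) and records
its nucleotide offset.

## Alignment and annotation

V and J assignment is local (Smith–Waterman) alignment with match +1,
mismatch −1, and affine gaps where a gap of length *n* costs 4 + (*n*−1)·1 —
the nucleotide scoring of standard immunogenetic annotators. Backend:
biotite's C-accelerated `align_optimal`; tests verify score-and-call
agreement against an independent brute-force dynamic program. Minimum
accepted scores are 40 (V) and 8 (J); ties break by higher identity, then
lexicographically smaller allele name. The J search runs on the region
downstream of the V alignment.

The reading frame is inherited from the V germline: the first aligned column
sitting on a germline codon start anchors translation. Germline codons are
mapped to read codons through the nucleotide trace; codons disrupted by
non-codon gaps mark the record unnumberable (treated as an incomplete-CDR
failure). Insertions in codon units receive Kabat insertion letters at the
sanctioned sites (H35a–b, H52a–c, H82a–c, H100a–k, L27a–f, L95a–f);
insertions elsewhere are unnumberable.

**CDR3 junction numbering.** Residues between the last V-templated Kabat
position and the J FR4 anchor (H103 / L98) are labelled by a fixed
convention: insertion letters attach after H100 / L95; short loops drop
positions working outward from that point (H100 first, then H101, 99, 98,
…; L95 first, then L96, 94, 93, …); the anchor-adjacent positions H102 / L97
are never dropped. Under this convention the label generator expresses HCDR3
lengths 3–19 and LCDR3 lengths down to 8 when seven positions are
V-templated, covering the observed biological ranges.

**Productivity filters.** A record fails QC if it has: no V or no J call; a
frameshift (net indel in the V alignment not a multiple of 3, or a J anchor
out of frame relative to the V frame); an internal stop codon anywhere in
the numbered domain; or a missing CDR after numbering. `qc_filter` is
idempotent and accounts for every record. The **stringent filter** used
before SHM analysis additionally requires the V alignment to cover every
germline CDR1/CDR2 position without deletions and a framework amino-acid
identity ≥ 0.8 (default); the threshold is this package's choice — published
analyses of this kind report the surviving counts but not their criteria.

## Repertoire statistics

Redundancy is exact multiset counting; `histogram[n]` is the fraction of
*sequences* (not distinct classes) occurring exactly n times, and defaults
to the amino-acid sequence of the numbered V domain (nucleotide level via
flag). Family/gene abundances and V–J pairing matrices are percentages of
all records; pairing marginals equal the respective abundances by
construction. Position composition is computed over the records possessing
each Kabat position (unoccupied insertion positions are omitted, keeping
normalization exact; only the 20 canonical residues are counted). The
positional diversity statistic is

    D(p) = distinct_residue_count(p) / max_residue_frequency(p),

hence 1 for a monomorphic position and bounded by distinct² ≤ 400. The
library-vs-germline diversity ratio is `D_lib(p)/D_ref(p)` over shared
positions (the reference composition weights each germline segment equally);
library-only positions (insertion codes) are reported separately, never
averaged. Whether such mean ratios should average CDR positions only or the
whole domain is genuinely open; this package averages over the CDR positions
passed in, which is what its acceptance reporting uses.

## Somatic hypermutation

SHM is measured at the amino-acid level as `observed ≠ germline` over
germline-templated Kabat positions inside a chosen CDR set; junction
residues without a germline template (including insertion codes) are never
counted. Heavy-chain analyses use HCDR1+2 only — HCDR3 is junction-encoded
and has no single germline template. Kappa supports LCDR1+2 and LCDR1+2+3.
Per-position denominators are coverage counts (records whose germline map
covers that position), not total records. The introduced-residue ranking
reports per-sequence incidence as the primary statistic (one sequence can
introduce several distinct residues, so incidences legitimately sum to more
than 100%) with per-event shares (summing to 1) alongside.

**Known limitation — the junction edge.** Nucleotide-level V-3′ trimming
makes the V/N boundary fundamentally ambiguous to any aligner: a point
mutation in the last one or two V codons can be clipped from the local
alignment, and a chance-matching N nucleotide can extend it over trimmed
germline. Positions that deep in the V gene lie inside CDR3 (L94–L95 on
kappa; H95–H96 on heavy). Consequently per-sequence SHM counts are exact for
CDR1/2 region sets (verified at 100% against simulation truth at zero
sequencing error) but only ≈ 97–98% exact per sequence for LCDR1+2+3; the
LCDR123 statistics remain well-defined as aggregates. This is why the
per-sequence exactness guarantee is stated for the germline-templated CDR1/2
sets.

## Simulator: what it emulates, and what it does not

Per sequence: V and J drawn from usage maps (uniform by default); SHM as
independent per-nucleotide substitutions at `shm_rate` (default 0.01) with a
×3 multiplier inside CDR1/2 nucleotide spans; junction built from geometric
V-3′/J-5′ trims (p = 0.25, mean 3 nt, capped at 6) and a Poisson N-insertion
(mean 21 nt heavy / 4 nt kappa) of uniform base composition, with the
N-length adjusted by 0–2 nt to keep the J anchor in frame and the junction
re-drawn until the CDR3 length lands in the designed window (4–19 aa heavy,
8–15 kappa) and its codons are stop-free. A configurable fraction of
sequences (default 0.05) receives an engineered TAA in a framework codon,
making it non-productive by construction. Constant-region primer tails (20
and 24 nt) flank the amplicon; 300-nt read pairs are cut from both ends,
guaranteeing at least `overlap_length` (default 50 nt) of overlap;
sequencing errors are uniform substitutions at `seq_error_rate` (default
0.002) with low Phred values at error positions. Identical configuration and
seed give byte-identical FASTQ output.

Defaults were chosen once as a plausible moderately-hypermutated-library
regime: 0.01/nt with a ×3 CDR multiplier puts ~24% of heavy chains at zero
amino-acid change in HCDR1+2 with a mean of ~1.4 — the neighbourhood real
libraries of this kind occupy. The N-insertion means centre HCDR3 near 12–13
aa and LCDR3 near 9–11 aa.

Deliberately **not** modelled: SHM hotspot motifs (WRC/GYW) and
transition/transversion bias — the analyses here are position-frequency
based, and a uniform rate admits closed-form recovery checks; indel SHM; PCR
chimeras and amplification bias; realistic quality-score error profiles;
clonal lineage structure (every simulated sequence is an independent
rearrangement, which is why simulated redundancy is ~100% unique — real
libraries contain genuine clonal duplicates). Passing tests therefore
certify the measurement machinery, not that real libraries look like the
simulation.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and 1-based inclusive in the
exported AIRR-style TSV. Percentages normalize to 100 within 1e−6; bin and
histogram fractions to 1 within 1e−9. K_D values are rounded to 3
significant figures (matching how such constants are printed); when an
expected K_D column is provided, computed values deviating by more than 0.2%
are flagged as discrepant — beyond what printed-value rounding explains.
Problem sizes in the test and acceptance runs (1000–2000 sequences per
repertoire) were chosen so that 3-standard-error recovery bounds are tight
while a full run stays in the minutes range on one core.
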