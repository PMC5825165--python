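# Methods

## Model and procedure

The pipeline identifies genomic loci that produce 24-nt phased secondary
siRNAs (phasiRNAs) in developing anthers and verifies their biogenesis
model: an EAT1-activated long noncoding precursor, cleaved by an
AGO/miR2275 complex at a 22-mer complementary site, is diced by DCL5 into
24-nt increments starting at the cleavage position (one-hit processing).
The stages analysed are ST.1 (premeiotic), ST.2 (early meiosis) and ST.4
(late meiosis); the genotypes are wild type, the *eat1* loss-of-function
mutant (no 24-PHAS transcription) and the *mel1* Argonaute mutant (the
RIP-seq control).

All internal coordinates are 0-based half-open; GFF3 is converted at the
parse boundary, BED is native.  Aligned reads travel as BED6+3 tables
(position, strand, copy number, read length, mismatches, genomic hits) —
the analysis needs nothing else from an alignment, so SAM semantics are
deliberately kept out (a thin SAM converter is provided).

## Decision rules and their parameters

| parameter | default | unit | note |
| --- | --- | --- | --- |
| fold_change_min | 2 | ratio | strict `>`, conditions 1 and 2 |
| sd_over_mean_max | 0.5 | ratio | strict `<`, condition 3, sample SD (ddof=1) |
| lincrna_min_len | 200 | bp | strict `>` |
| phas_min_srna_fpkm | 10 | FPKM | strict `>`, any wild-type sample |
| max_hits / max_mismatches | 50 / 0 | count | reads above/beyond are discarded |
| srna_len / degradome_lens | 24 / {20, 21} | nt | |
| masirna_min_rpm / masirna_min_fold | 15 / 4 | RPM / ratio | both `>=` |
| window / step | 50,000 / 25,000 | bp | landscape tracks |
| mir_site_len / cleavage_offset_in_site | 22 / 13 | nt | phase origin = site's 13th base |
| antisense_offset | 2 | nt | dicer-duplex 3' overhang |
| max_site_mismatch | 4 | weighted | G:U wobble = 0.5 mismatch |
| pseudocount | 0.01 | FPKM/RPM | all fold-change denominators |
| window_cycles | 9 | cycles | phasing-score window |

Choices made where the procedure is genuinely open:

* **Fold-change zero handling.**  Mutant and premeiotic FPKM can be
  exactly zero while the published effect sizes (hundreds-fold) imply a
  ratio was still formed; a fixed pseudocount ε = 0.01 FPKM/RPM in every
  denominator makes the ratios finite and scale-consistently (the
  scale-invariance test scales ε with the data).
* **Condition semantics.**  ">2-fold" and "less than a half" are read as
  strict inequalities.  Condition 1 compares replicate means (a `max`
  alternative is exposed); condition 3 uses the sample SD, conventional
  for three replicates, with ddof configurable.
* **FPKM formula.**  count x 10^9 / (length x library_total), reads
  assigned to every locus containing their biological 5' end.
  Multi-mapped reads weigh 1/hits by default ("fractional"); a "primary"
  mode counts them once.  Both are exposed because the counting mode of
  the original tooling is not recoverable.
* **PHAS condition scope.**  The >10 FPKM test uses wild-type samples
  only (the definition is nested inside wild-type-based selection) and
  "any single WT sample" rather than a mean; both are configurable.
* **Coding overlap.**  Any overlap (≥1 bp) with a protein-coding gene
  disqualifies a candidate region — conservative, and consistent with the
  existence of a rescue path for loci lost this way.
* **Transcribed regions.**  Derived from mRNA coverage at a configurable
  floor (default 1 read) with merging of overlapping/bookended segments.
  This replaces assembler-merged annotation with an explicit, reproducible
  rule; it is a documented divergence from transcript assembly.
* **Trigger-site discovery.**  A deterministic complementarity scan on
  both orientations replaces de-novo motif discovery: the conserved motif
  at these loci is the trigger complement itself, so the scan is the
  reproducible equivalent.  Weighted mismatches ≤4 with G:U wobble = 0.5;
  N scores as a full mismatch.  With multiple sites, the most 5' site in
  its own orientation defines the origin (sites concentrate at the
  precursor 5' region under one-hit processing); ties break to lowest
  mismatch, then leftmost.
* **Register convention.**  In-phase means `(start − origin) mod 24 == 0`
  on the plus strand and `(end − origin − 2) mod 24 == 0` on the minus
  strand.  The 2-nt offset is the standard 3' overhang of a dicer duplex;
  it is exposed (`antisense_offset`) because the original counting
  convention for antisense reads is not stated.
* **Phasing score.**  The log-form score
  `(k − 2) · ln(1 + 10 P / (1 + U))` in a sliding window of
  `window_cycles` phase positions (P/U = copy-weighted in-/off-phase
  counts, k = distinct occupied in-phase positions, reported only when
  k ≥ 3, locus score = window maximum).  The score family is cited, not
  printed, in the source analysis; this variant is therefore a documented
  choice, unit-tested and isolated behind one function.
* **Degradome.**  Tolerance 0 nt ("the same position") by default but
  exposed, since real 5' ends jitter; evidence from the precursor sense
  strand by default; loci under 5 supporting reads are "undetermined" and
  excluded from the matched/total denominator.
* **masiRNA pairing.**  The ≥4-fold wild-type/mel1 test is evaluated at
  the wild-type stage of maximal RPM against the stage-matched mel1
  library (stage pairing is not stated in the source; stage-matched is
  the stricter reading).  Origin precedence PHAS > coding > repeat >
  intergenic; "intergenic except 24-PHAS" forces at least PHAS >
  intergenic, the rest follows specificity.  Stage compositions are
  RPM-weighted; the 5'-nucleotide table is species-level.

## The synthetic-data generator

`SimConfig` defaults define the study conditions: 2 chromosomes of
200 kbp; 30 coding genes, 20 repeat families (2–60 genomic copies, so
the >50-hit filter boundary is exercised); 20 planted EAT1-dependent
PHAS loci of 500–1,000 bp; and four decoy classes of 10 loci, one per
filter — ST.2-enriched but EAT1-independent (condition 2), constitutive
(condition 1), erratic replicates (condition 3), and phased-but-siteless
(site confirmation).  Each site-bearing locus embeds exactly one exact
22-nt trigger complement in the 5' third of its precursor orientation;
locus sequences are rejection-sampled so no *chance* site at ≤4 weighted
mismatches exists, making the truth labels exact.

Libraries: 3 replicates x {WT, eat1} x {ST.1, ST.2, ST.4} for mRNA and
sRNA (~1–2 x 10^5 reads each), 2 replicates x {WT, mel1, eat1} for RIP
(5 x 10^4 reads), one degradome library.  Mean expression per locus class
encodes the published effect structure — precursor abundance 688-fold
(vs ST.1), 24-fold (vs ST.4) and 55-fold (vs eat1 ST.2) — and 24-nt
sRNAs persist into ST.4.  Replicate counts are Poisson around a
mean-one lognormal multiplier with CV 0.15, a typical replicate
variability for strongly expressed loci and safely below the
condition-3 bound; the source states no dispersion model, so this is a
modelling choice.  The erratic-replicate decoys scale their WT ST.2
replicate means by (0.05, 0.05, 2.9), putting SD/mean near 1.6
regardless of noise.

In-phase sRNA reads sit exactly on the register grid of both strands;
off-phase reads are uniform but never on-grid, so the planted in-phase
fraction (default 0.8, the neighbourhood of the empirically observed
medians) is recovered as an exact binomial.  The degradome plants the
dominant 5'-end stack at the predicted position for 70% of loci
(displaced 10–49 nt otherwise), with half of each locus's reads in the
stack.  RIP libraries draw 24-nt species from PHAS/coding/intergenic/
repeat pools with stage-dependent mixtures (PHAS-derived species absent
premeiotically, 5.2% at ST.2, 9.0% at ST.4); PHAS species start with C
with probability 0.9; mel1 libraries carry the same species at 1/20
abundance, topped up with background species, so every pooled species
clears the 4-fold filter.  Every random draw comes from a
`numpy.random.default_rng` stream keyed by the seed plus a fixed
per-library tag, so a seed fixes every output byte.

The packaged default trigger is a synthetic 22-mer stand-in
(`DEFAULT_MIR2275`); the trigger is a configuration input and nothing in
the pipeline depends on its identity.

**What the generator does not emulate** — sequencing error, adapter
artifacts, quality scores, GC/ligation bias, genome repeat structure
beyond annotated families, transcript isoforms, and biological coupling
between neighbouring loci.  Passing tests therefore demonstrate the
correctness of the decision rules and estimators under the stated
statistical structure, not performance on real libraries, where
threshold-adjacent loci and imperfect trigger sites will behave less
cleanly.

## Numerical and degenerate-input behaviour

Empty read sets quantify to zero (not an error); a zero-read locus makes
the in-phase fraction undefined and raises.  Degradome peak ties break
leftmost.  FPKM requires a positive library total and positive locus
lengths.  Window tracks must share a grid before subtraction.  Filtering
operations log records-in/records-out at INFO.

## Problem sizes

Tests and the worked example run the full default design (36
mRNA/sRNA libraries at ~1–2 x 10^5 reads, 18 RIP libraries, one
degradome library) in well under a minute on a single core; the
reduced design used by the unit-test fixtures keeps the same structure
with 6 planted loci and 3 decoys per class on a 2 x 60 kbp genome.

## Known limitations

* The phasing-score variant is one member of the cited family; absolute
  score values should not be compared across tools.
* 21-nt register logic is parameterised (`cycle`, `srna_len`) but not
  validated against any reference values.
* The EAT1-dependence call is a deterministic filter, not a statistical
  test; no replicate-aware differential testing or multiple-testing
  correction is performed, matching the procedure it implements.
* Real degradome data need a nonzero tolerance and a considered minimum
  read support; the defaults encode the idealised criterion.
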