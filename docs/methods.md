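# Methods

## Overview

`diverseq` implements a two-population transcriptome divergence analysis as
a deterministic pipeline over six stages: synthetic data generation → sample
QC → read alignment → SNP calling/classification → RPKM differential
expression → divergence statistics. Every stage is importable on its own;
the pipeline driver adds configuration, seeding, caching, and artifact
output (FASTA/FASTQ/SAM/VCF/TSV/JSON/Newick).

## Synthetic data generator

The generator emulates the structure of a legacy 454 study contrasting an
anadromous (AO) and a landlocked (LM) population:

- **Reference transcripts.** Random sequences with a configurable GC
  fraction; lengths truncated-normal (default mean 351 bp, sd 120, min
  100 — the scale of a short-read transcriptome assembly). A configurable
  fraction carries a CDS beginning with ATG, free of internal in-frame
  stops, and ending in a stop codon, placed between random UTRs.
- **Planted variants** in three classes: shared polymorphisms (both groups
  segregate ref/alt), group-exclusive fixed differences (one group fixed
  for the alternative), and group-restricted polymorphisms (the carrier
  group segregates ref/alt; the other group is fixed for ref, so one allele
  is always shared). A configurable number of variants use a single-base
  gap allele instead of a substitution. Gap positions are left-normalized
  within homopolymer runs so planted coordinates agree with the leftmost-gap
  convention of alignment. Variants avoid transcript ends (configurable
  margin) because coverage tapers over roughly one read length there.
- **Sample plans.** 4 AO + 3 LM samples by default. Per-transcript
  expression weights are log-normal (sd 1 in log2 units) and shared across
  samples; LM samples get the planted fold changes (log-uniform magnitudes
  over 2–200×, alternating direction) multiplied in. Libraries are not
  normalized: each read picks its transcript multinomially from the
  weights, which is exactly the property RPKM exploits.
- **Reads.** Per read: a haplotype is built by applying each variant
  carried by the sample's group with probability equal to its within-group
  frequency (a Bernoulli per read models a pooled library of individuals);
  the start is uniform; length is truncated-normal (default mean 187 bp,
  sd 60, min 40); strand is uniform; independent per-base substitution
  (default 0.5 %) and single-base indel (default 0.2 %) errors are applied.
  Homopolymer-specific 454 errors and flowgram space are not modelled.
  Quality strings are a constant Q30 placeholder. Because real 454 noise
  is bursty and alignment references are imperfect assemblies, passing
  recovery tests here bounds method error under idealized noise, not
  performance on real libraries.
- **Seeding.** One master seed; each sample's stream is derived via
  `SeedSequence(master, spawn_key=(crc32(sample_id),))`, so adding or
  removing a sample never changes the other samples' reads. All outputs
  are bit-reproducible for a fixed config.

## Alignment

Seed-and-extend against the transcript set, parameterised like a classic
overlap assembler: exact k-mer seeds (k = 15; the index stores every
forward-strand k-mer), percent-identity floor 0.90, mismatch penalty 20.
Matches score +10 and affine gaps cost 20 to open plus 5 per base, chosen
so a 1-base gap (25) costs more than a mismatch (20); the assembler's
"expected coverage" knob has no analogue here and is intentionally unused.
Seeds are sampled every 5 bases (stride 1 recovers full sensitivity for
short reads); seed diagonals within twice the gap cap are clustered, and
each cluster's reference window (cluster span + read length + padding) is
aligned in full with a numba-compiled local affine-gap (Gotoh) dynamic
program. The reported score is therefore the exact local-alignment optimum
whenever the window covers it, which the test suite verifies against an
independent full-DP oracle.

Reads are aligned on both strands; the best score wins, with exact ties
broken by (transcript id, start, '+' before '−') so multi-mapping reads are
counted once and RPKM totals stay conserved. An alignment is discarded when
identity (matches / aligned columns, soft-clips excluded) falls below 0.90
or any single gap exceeds 15 bases.

**Dangling-gap trimming.** A local optimum occasionally ends in a gap held
by a short terminal anchor: when a read's last base mismatches and the next
reference base happens to agree, gap (−25) + match (+10) beats the mismatch
(−20) once the anchor has ≥ 2 more matching bases. Left in place, these
artifact gap alleles accumulate at real SNP sites (the mismatching reads
end near the variant) and pollute downstream allele sets. Terminal gaps
whose outer anchor is shorter than 5 aligned columns are therefore trimmed
into soft-clips; the reported score remains the DP optimum.

Pileups are dense per-transcript arrays of per-sample counts over
{A, C, G, T, gap}: deleted reference positions count as gap alleles;
insertions do not occupy a reference column and are recorded separately.

## SNP funnel

1. **Putative sites**: any column with ≥ 2 alleles supported by ≥ 2 pooled
   reads each and total (supported) depth ≥ 10. The reference allele is the
   majority base over all samples, standing in for an assembly consensus;
   the minimum depth default (10) is conservative relative to the observed
   depths of published group-specific sites (≥ 18).
2. **Frequency window**: a site survives iff every non-reference allele's
   fraction of raw reads lies in [0.25, 0.75], boundaries inclusive. The
   window is applied per minor allele (the alternative — total non-consensus
   fraction — is available as an option); with the reference defined as the
   majority allele the effective window is [0.25, 0.5], which matches the
   filter's intent of removing error-dominated and near-fixed calls.
3. **Group classification**: an allele is *present* in a group with ≥ 2
   reads and *absent* with 0; a single read is neither. A site is
   group-exclusive iff some *witness* allele is present in one group and
   absent from the other. This per-allele rule means one stray error read
   can never create exclusivity (presence needs ≥ 2 vs exactly 0) and
   disqualifies only the allele it touches rather than the whole site — at
   depth d the other group collects ≥ 1 stray read of a true allele with
   probability ≈ 1 − exp(−d·ε/3), which would otherwise erase most true
   fixed sites at realistic depths. Subtypes from the present sets:
   both singletons and different → `fixed_divergent`; exactly one group
   polymorphic with a private allele → `polymorphic_in_{AO,LM}`; both
   polymorphic with private alleles (not observed outside simulation) →
   the larger present set carries the label, AO on ties.
4. **Coding effect**: substitutions inside a CDS are translated in frame
   (standard code); a gap allele in a CDS is an `indel`; positions outside
   any CDS are `noncoding`; unresolvable codons are `unknown`. With several
   alternative alleles the most consequential effect (indel > unknown >
   nonsynonymous > synonymous) is reported.

Output: a VCF (per-group allele depths as two samples; classification,
subtype, and effect as INFO keys; gap alleles as anchored deletions) and a
tab-separated site table with 1-based positions and per-group allele sets.

## Differential expression

RPKM[g,s] = count / (length/10³) / (total mapped reads/10⁶). Tests run on
log2(RPKM + 1) (the pseudocount avoids log 0); fold change is computed on
untransformed group-mean RPKM with pseudocount 0.1 in numerator and
denominator. Contigs with zero counts everywhere are dropped. Samples
failing QC (defaults at study scale: ≥ 60 000 reads, mean length ≥ 150 bp;
scaled in the toy config) are excluded from this stage only — their reads
still feed the pileups, mirroring a design where a weak library is dropped
from quantification but participated in assembly.

The moderated t-test shrinks each contig's pooled two-group variance s²_g
(d_g = n₁+n₂−2) toward a prior: s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g), with
t̃ on d0 + d_g degrees of freedom (capped at 10⁶ when d0 is infinite; d0 = 0
recovers the ordinary pooled t exactly). The prior is fitted by matching
the mean and variance of log s²_g against the scaled-inverse-chi-square
model via digamma/trigamma identities, inverting the trigamma by Newton
iteration. When the observed spread of log variances does not exceed the
chi-square sampling component the fit returns d0 = ∞ with s0² equal to the
mean sample variance, so identical variances recover exactly that common
value. The fit requires ≥ 10 contigs with positive variance and is run on
all expressed contigs (the widest stable pool); the fold-change tier
(default ≥ 8×) is applied first and the BH step-up FDR is computed within
the tier, mirroring an analysis that narrows before adjusting.

Clustering of the tier uses Euclidean distance with centroid linkage on
both axes (genes and samples); dendrograms are emitted as Newick and the
doubly-reordered matrix as the heat-map table. Centroid linkage can invert
(non-monotone heights); negative branch lengths are clamped to zero in the
Newick rendering only.

## Divergence statistics

The Fisher exact test is two-sided under the probability-ordering
convention: with both margins fixed, p sums the hypergeometric
probabilities of all tables no more probable (within 1 + 10⁻⁷ relative
tolerance) than the observed one. On the within-group polymorphism
contrast — 8 of 22 group-specific sites polymorphic in AO vs 2 of 22 in LM,
i.e. the table (8, 14 / 2, 20) — this gives p = 0.0689, confirmed in the
tests by exact-rational enumeration and by an independent library
implementation. The SNP/DE overlap reports |SNP loci ∩ DE genes| and its
fraction of SNP loci (integer percent; undefined and omitted when no SNP
loci exist). Report percentages always recompute from the printed
numerator/denominator at the displayed precision (e.g. 22/6 835 → "0.3%",
4/13 → "31%", 572 065/817 488 → "70%"); stored values keep full precision.

## Recovery experiments and problem sizes

The default toy run uses 20 transcripts, 7 samples, and 5 000 reads per
sample — large enough for ~700× pooled depth and stable DE, small enough
to run interactively. Two dedicated experiments quantify inference quality:

- **SNP recovery** (`snp_recovery_config`): 26 planted variants (10 fixed,
  10 group-polymorphic, 6 shared, 2 gap alleles), uniform expression
  weights, no fold changes, substitution/indel errors 0.02 %/0.01 %, and
  within-group polymorphism frequency 0.75. These conditions are chosen so
  the planted truth is recoverable *in principle* through the 25–75 %
  window: a within-LM polymorphism at frequency f has expected pooled alt
  fraction f·(3/7), so f = 0.5 (0.21) cannot pass the window at all, while
  f = 0.75 (0.32) sits several binomial standard deviations inside it at
  the experiment's ~260× depth. Witness-destroying stray errors scale with
  depth·ε while window noise scales with 1/√depth, and the chosen operating
  point keeps both below ~1 % per site. Expected full-funnel sensitivity
  is ≥ 0.95 with false-discovery proportion ≤ 0.05. Under the paper-like
  default error rates and f = 0.5 the funnel *by design* loses most
  group-restricted polymorphisms in the smaller group — the same asymmetry
  that makes the smaller population appear to retain less polymorphism.
- **Prior recovery**: variances for 5 000 contigs simulated from a known
  scaled-inverse-chi-square prior (d0 = 4, s0² = 0.05); the moment-matching
  fit recovers d0 within ±30 % and s0² within ±10 %.
- **DE recovery** is scored against *realized* concentration ratios: with
  non-normalized libraries, planting a fold change on some transcripts
  renormalizes every other transcript's library share (the composition
  effect), so the ground truth for the RPKM analysis is the ratio of
  per-sample weight vectors, not the planted multiplier.

## Numerical and degenerate-input choices

- Identity comparisons at the 0.90 floor are inclusive (≥).
- Alignment candidate ties break deterministically (transcript id, start,
  strand) so outputs are order-independent and bit-reproducible.
- t statistics with zero standard error are ±∞ (p = 0) unless the mean
  difference is also zero (t = 0, p = 1).
- `bh_adjust` rejects p-values outside [0, 1]; the trigamma inversion uses
  limma-style Newton steps with a 10⁻¹⁰ relative tolerance.
- All-zero variance matrices, empty reads, k < 8 seeds, zero library
  totals, nonpositive lengths, and window bounds with low ≥ high raise
  explicit errors; an empty putative-SNP set is a valid (empty) result.
- Constant matrices cluster into a single flat dendrogram at height 0.

## Known limitations

- The error model is i.i.d. per base; real 454 homopolymer error bursts
  would inflate the putative-SNP count and stress the window filter more
  than these simulations do.
- The aligner assumes the reference transcript set is correct; assembly
  (the upstream step in the motivating design) is out of scope, so
  chimeric or collapsed-paralog contigs — a real source of spurious
  "divergent" sites — are not modelled.
- The 25–75 % window interacts with group sample share (see above);
  cross-study comparisons of within-group polymorphism counts should
  account for this censoring.
- `fixed_divergent` labels describe the sampled reads, not the populations;
  at modest depth a low-frequency allele can be missed entirely.
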