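# Methods

`malines` re-implements the analysis of a long-running *Daphnia obtusa*
mutation-accumulation (MA) experiment as a reusable pipeline: eight clonal
lines propagated by single-female descent for ~480–510 generations, deep
whole-genome sequencing, and recovery of de novo single-nucleotide mutations
(SNMs), small indels, and loss-of-heterozygosity (LOH) tracts against a
heterozygous diploid ancestor. Because the raw sequencing data are far
beyond desk scale, the package ships a synthetic-experiment generator with a
ground-truth table; every detection component is validated by recovering
what was planted.

## The estimators

**Mutation rate.** Per line, μ = x / (g · 2n): x accepted de novo events, g
generations, n callable sites (read depth in [20, 300], inclusive). The
factor 2 reflects diploidy — events are recovered as heterozygotes, so each
site exposes two mutable copies. The experiment-wide rate is the unweighted
mean of per-line rates with CI = mean ± q·SD/√L. Two quantile choices are
provided: `method="normal"` (q = 1.96 at 95%) is the arithmetic that
reproduces the published interval bounds from the per-line tables, and is
used wherever those printed values are being reconstructed;
`method="t"` (the default, Student t with L−1 df) is used for the
pipeline's own estimates because with only eight lines the plain-z interval
is not a 95% interval — under purely Poisson between-line variation it
covers the true rate only ~91% of the time, while the t interval holds the
nominal 95%.

**Ancestral inference and calling.** All lines share one ancestor, so the
ancestral genotype at a polymorphic site is the genotype shared by at least
n−1 lines (7 of 8 in the original design; configurable). A call requires:
exactly one deviating line; the deviation Hom→Het; the site callable and
genotyped in every line; zero reads of the novel allele in any non-mutant
line; and ≥20 bp distance from any indel record. Het→Hom changes are never
mutations here (they feed the LOH detector), and Hom→Hom allele switches are
treated as artifacts.

**Filters.** The nine-rule stack mirrors GATK-style hard filtering: indel
proximity (20 bp), multi-allelic exclusion, depth bounds [20, 300], FS ≤ 60,
MQRankSum ≥ −12.5, ReadPosRankSum ≥ −8 (absent annotations pass — they only
exist when both allele classes are observed), and for heterozygous
genotypes: alternate-read fraction in [0.2, 0.8], ≥5 alternate reads, and an
exact two-sided binomial test of the read ratio against 1:1. The balance
test is a hard cut at α = 1e-3 by default. The source analysis states the
test but not its level; 0.05 would discard ~4–5% of genuine heterozygotes at
80× (the test rejects its own null at rate α), silently deflating μ by the
same fraction, while real imbalance artifacts (e.g. 90:10 ratios at 80×)
have p-values tens of orders of magnitude below any sensible cut. 1e-3
keeps the null loss near 0.1% without weakening artifact rejection; the
level is a config field.

**Spectra.** Six strand-collapsed substitution classes with conditional
rates — count divided by 2 · Σ_lines g_l · n_l(source base pair) — plus the
96-trinucleotide pyrimidine-centred spectrum and Ts/Tv. From the conditional
fluxes u (A/T→G/C) and v (G/C→A/T), the equilibrium GC content under
mutation pressure alone is GC_eq = u/(u+v). Note: arithmetic on the
published conditional rates gives 0.326; the published text prints 0.320,
presumably from unrounded inputs that are not recoverable. The operation is
defined by the formula and the discrepancy is recorded, not matched.

**Selection correction.** Nonsynonymous sites are ~21% of the genome but
show only ~53% of the mutation density of other compartments, i.e. a 47%
deficit attributable to selection during the MA phase; the corrected rate is
f·(1+d)·μ + (1−f)·μ. The same structure applies to exonic indels (f = 0.30,
d = 0.71). Both constants are exposed as parameters; the 21%/30% pair is
taken as given rather than reconciled, since they describe different
compartment unions.

**Impact annotation.** A minimal strand-aware codon annotator:
stop-gained/stop-lost/start-lost → HIGH, missense → MODERATE, silent → LOW,
non-coding → MODIFIER. Splice-site effects are deliberately not modelled —
the synthetic gene models carry no splice signal worth annotating. The
neutral expectation for impact categories places n SNMs uniformly over
(callable) sites and draws the substitution type from the six-class spectrum
conditioned on the reference base, so realized Ts/Tv matches the target in
expectation, then annotates each placement; mean ± SD over 1000 replicates.

**LOH.** Over the ordered ancestral heterozygous sites of each line, a
two-state hidden Markov model {RETAINED, LOH} is Viterbi-decoded
(p_entry = 1e-6/site, p_exit = 1e-3/site, miscall rates 0.01). Decoded runs
become tracts if the span between first and last homozygous-converted sites
exceeds 1 kb, at least 3 converted sites exist, and ≥90% of those sites stay
heterozygous in every other line ("consistently het in non-target lines";
the 90% quantifies a criterion the source leaves verbal). Tracts report a
minimum span (first to last converted site) and maximum span (to just inside
the flanking retained heterozygotes). The per-het-site rate is
μ = x/(g · n_het); the experiment-wide value is the unweighted mean over
lines, zero-event lines included. (The published per-line values average to
3.03e-5 against a printed 2.93e-5 total; the footnote formula is what is
implemented.) The published analysis used an ROH tool driven by population
allele frequencies; with the ancestral heterozygous set known, an explicit
two-state HMM is equivalent and self-contained — the substitution is
validated on the same surface, tract recovery on simulation.

**Mechanism classification.** Standardized coverage = mean tract depth ÷ the
line's mean callable-site depth. A hemizygous deletion removes one copy:
focal standardized coverage ≤0.70 of both its 50-kb flanks and the
genome-wide mean, while every other line holds ≥0.80 on the same region;
otherwise gene conversion. Tracts with depth missing over half the region
stay unclassified. GC-biased gene conversion is tested on conversion tracts
only, at strong/weak (G/C vs A/T) heterozygous sites, with an exact binomial
test of the GC-resolution fraction against 0.5.

**Population comparison.** Per-site diversity π = 2p(1−p) on minor-allele
frequency p; gene-level π_N/π_S uses Nei–Gojobori fractional site counts
(each coding position contributes the fraction of its three substitutions
that are silent; weights sum to the CDS length). SNM/SNP overlap counts a
de novo mutation as present in a population when a site exists at the same
position with MAF strictly > 0.02 and (by default) the identical minor
allele; position-only matching is a flag, since the source does not state
which was used.

## The synthetic experiment

The generator emulates the study conditions as its defaults: 8 lines with
the published per-line generation counts; ancestral heterozygosity 0.57% of
sites (alternate alleles uniform over the three non-reference bases); SNM
rate 2.23e-9 and indel rate 2.75e-10 per site per generation; genome GC
0.409; ~118 genes/Mb laid out so that ~21% of the genome is nonsynonymous,
~29% exonic, ~28% intronic; mean depth 79× with negative-binomial
overdispersion (var = mean·1.5); per-het-site LOH rate 2.93e-5 with 8/48 of
events deletions and log-normal tract lengths spanning 1 kb–2.5 Mb. The
genome itself is scaled to 12 × 1 Mb chromosomes by default so the full
pipeline runs in seconds; recovery experiments in the test suite use 10–20
Mb genomes, stated where they run.

Design choices worth knowing:

- **The six-type spectrum weights are conditional rates.** They control both
  where mutations land (G:C sites accept proposals at a higher rate than
  A:T sites, by rejection sampling) and which substitution occurs. Weighting
  only the substitution type, with uniform placement, cannot reproduce the
  observed GC→AT vs AT→GC flux asymmetry — realized GC_eq would sit near
  0.44 rather than ~0.33.
- **Depth model.** Negative binomial via an exact tabulated inverse CDF
  (uint32 uniforms through a lookup table with binary-search fallback at CDF
  boundaries); deleted tracts binomially thin the carrier's depth by half,
  which is exactly the hemizygous expectation. Allele depths at het sites
  are Binomial(DP, 0.5).
- **No parallel mutations.** Planted event positions are globally unique and
  never coincide with ancestral het sites, matching the rarity assumption
  the caller relies on.
- **Genotype-level miscalls default to 0.** A flipped genotype is emitted
  with self-consistent allele depths, so any flip rate much above 2μg would
  swamp the caller with undetectable false positives; realistic noise lives
  in the evidence layer (depth, allele counts, FS/rank-sum draws), which is
  always on. The knob exists for robustness experiments.
- **Artifact injection.** Each filter rule has a labelled artifact class
  (FS=80, MQRankSum=−20, ReadPosRankSum=−10, 90:10 allele imbalance, 4
  supporting reads, SNP 10 bp from an indel, tri-allelic site); the truth
  list lets tests assert per-class removal.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: read-level errors and mapping artifacts (evidence is
drawn from null distributions rather than alignments), linked ancestral
haplotype structure (conversion resolves each site independently at 1:1),
repeat-driven indel clustering, population demography and linkage in the
frequency tables, and splice architecture. Recovery statistics here bound
pipeline logic errors, not wet-lab error modes.

## Numerical notes

- The exact two-sided binomial p-value under p₀ = 0.5 uses the symmetric
  closed form min(1, 2·P(X ≤ min(k, n−k))), which equals the
  minimum-likelihood-sum definition for this symmetric null; it is
  vectorised and verified against brute-force enumeration and
  `scipy.stats.binomtest`.
- χ² tests are Pearson, no continuity correction, expectations proportional
  to callable exposure; pairwise compartment tests use df = 1.
- Depth bounds are inclusive at both ends ("between 20 and 300"); the source
  does not state inclusivity, and both bounds are configurable.
- Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention); BED
  output converts to 0-based half-open.
- Viterbi ties break toward staying in the current state; missing
  observations contribute emission probability 1 to both states.
- One global seed; stages draw from `SeedSequence.spawn` children in a fixed
  order (reference, ancestor, evolution, evidence, population), so any stage
  can be regenerated independently and all outputs are byte-stable.

## Problem sizes used by the test suite

Unit tests run on hand-built tables and a 2 × 400 kb experiment. The
rate-recovery check uses 20 replicates of an 8-line, 20 Mb (4 × 5 Mb),
500-generation experiment with planted μ = 1e-8; the LOH-recovery check uses
a 10 Mb genome at the study's LOH rate with tract lengths clipped to
[5 kb, 150 kb] so every planted tract meets the ≥5 kb condition being
scored. These sizes keep the whole suite around two minutes on one CPU while
leaving per-line event counts in the hundreds.

## Known limitations

- The annotator omits splice-site (HIGH) effects and UTR-specific subtypes.
- The LOH HMM uses per-site (not per-bp) transition probabilities, so very
  uneven het spacing slightly reshapes the effective tract-length prior.
- Crossover vs non-crossover conversion cannot be resolved (short-read
  phasing limit inherited from the study design).
- π_N/π_S classification assumes the major allele is the reference base, as
  holds in the synthetic frequency tables.
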