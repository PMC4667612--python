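# Methods

This note documents the models, estimators and design choices behind
`palmscan`, in the order data flows through the package.

## Scope and conventions

`palmscan` starts from *called genotypes* — a biallelic-SNP VCF with GT
fields — not from read alignments or genotype likelihoods.  All coordinates
are 0-based half-open internally; the only conversion happens at the VCF
boundary (POS `p` ↔ interval `[p−1, p)`), which removes ±1 ambiguity from
windowing.  Genotypes are alternate-allele dosages {0, 1, 2} with −1 for
missing; phase is discarded and half-missing genotypes are treated as
missing.  Multiallelic and indel records are skipped rather than decomposed.
The reader applies only a call-rate filter (default: keep records with ≤ 5%
missing genotypes); depth- and mapping-quality-based site filters are
treated as upstream of this package because they require raw alignments.
Repeat-region exclusion is supported through an optional exclusion BED
rather than a bundled repeat annotation.

## The synthetic-data generator

The generator exists so that every downstream stage can be exercised against
known truth.  It emulates a two-population domesticated-crop panel: a clean
population split, admixed individuals, per-site scaled mutation rate θ near
0.01 (the empirical scale of the study system), planted low-diversity sweep
windows, whole-locus identity-by-descent inbreeding, and per-gene coverage
breadth with planted homozygous deletions.

**Coalescent loci.**  Each locus is an independent Kingman coalescent with
infinite sites: while k lineages remain, the waiting time to the next
coalescence is exponential with rate k(k−1)/2 (time in units of 2N
generations); mutations are Poisson with rate θ·L/2 per unit branch length
and land on branches proportionally to their length, so E[S] = θ·L·a_{n−1}
and E[π] = θ per site.  Site positions are uniform draws without replacement
on the locus.  There is no recombination within a locus; loci are laid end
to end on one synthetic scaffold and are statistically independent.  This
keeps the coalescent exact and simple; linkage disequilibrium is produced by
a separate forward simulator (below).

**Structure and admixture.**  Population-1 and population-2 lineages
coalesce in separate demes until `split_time` (default 1.0 in 2N units — an
illustrative value, as the study system's demography is not calibrated
here), after which the demes merge.  Each lineage of an admixed individual
joins deme 1 with that individual's admixture fraction, independently per
locus; realized ancestry draws are recorded in the truth object.

**Sweeps.**  A planted sweep is a local diversity reduction: at loci
overlapping the sweep interval, the swept population's haplotypes are drawn
from an independent single-population coalescent with θ multiplied by the
reduction factor.  This directly controls the quantity the scan consumes
(the within-population θ footprint) without simulating a selection
trajectory.  The cost is that shared polymorphism between populations is
broken inside swept windows, which the ratio scan does not use.

**Inbreeding and ROH.**  With probability F (per individual, per locus), or
deterministically inside planted ROH intervals, an individual's second
haplotype is a whole-locus copy of its first.  One parameter thus yields
both genome-wide excess homozygosity (E[F̂] ≈ F) and contiguous
ROH-like tracts.

**Forward Wright–Fisher simulator.**  A diploid population of N individuals
(2N haplotypes over L finite sites) evolves for a fixed number of discrete
generations; each offspring haplotype is a recombinant gamete of a random
parent with Poisson(r·L) crossovers, and Poisson(2N·L·μ) mutations flip
single alleles per generation.  Defaults (N = 50, 200 generations,
L = 5 kb, μ = 5·10⁻⁵/bp, r = 10⁻⁴/bp) give 4Nμ per bp of 0.01 and strong
distance-dependent LD at desk scale.

**Coverage breadth.**  Non-deleted gene/sample cells draw breadth from
Uniform(0.92, 1.0) and deleted cells from Uniform(0, 0.10).  The gap between
the two supports and the calling thresholds (0.15 / 0.90) makes truth
recovery exact by construction — the corresponding tests check the caller's
logic (eligibility, mappability guard, frequency accounting), not its
robustness to borderline breadth values, which real data would exercise.

**What the generator does not emulate:** sequencing and genotyping error,
missing data patterns correlated with depth, intra-locus recombination,
selection trajectories, gene conversion, and reference/mapping biases.
Passing recovery tests therefore validates the estimators and calling logic
under the stated models, not their behaviour under real-data artefacts.

## Diversity statistics

Per site, n = 2 × (called genotypes) and k = Σ dosages over the chosen
sample subset.  For a window of genomic span L:

* θ̂_W = S / (a_{n̄−1} · L), where S counts sites with 0 < k < n and n̄ is the
  mean n over the window's usable sites, rounded to the nearest integer.
  Windows are scaled by genomic span (monomorphic sequence counts toward L),
  with an optional callability override.
* π̂ = (1/L) Σ 2k(n−k)/(n(n−1)) with exact per-site (n, k); sites with n < 2
  are skipped and logged.
* Tajima's D uses the standard 1989 constants evaluated at n̄.  D is
  undefined (NaN, propagated as missing) when S = 0, and also for n̄ < 4
  where the 1989 variance expression vanishes.  Mixing per-site n into D
  exactly is ill-defined (the constants need one n), hence the n̄ convention;
  this is a package choice where missing-data handling is not standardized.

Windows tile each scaffold from coordinate 0; full windows start at
multiples of `step`, and one trailing partial window (with its true span) is
emitted so tilings conserve totals.  The folded SFS uses minor-allele
counts; sites with missing data can be projected to a common n by the
hypergeometric expectation.  The single-genome θ estimator is heterozygous
calls divided by callable span (declared scaffold lengths when available) —
a moment estimator standing in for likelihood-based single-genome methods,
with accuracy assessed by simulation recovery rather than by equality with
those methods.

## Sweep scan

x = log₂(θ̂_W,pop1/θ̂_W,pop2) per window; windows where either population has
θ̂ = 0 or S < 2 are excluded before standardization (log of 0 is undefined;
an optional pseudocount retains them instead, off by default).  Z-scores use
the mean and population s.d. (divisor n) of all scored windows, matching an
empirical-distribution outlier approach; the opposite orientation is the
exact sign flip.  Region calling: a window seeds a region only if a second
outlier window starts within `pair_distance` (start-to-start, unambiguous
under fixed tiling); qualifying windows merge into maximal regions with
start gaps ≤ `pair_distance`.  Defaults: 5-kb windows, |Z| ≥ 5, 10-kb
pairing.  The enrichment test tabulates (outlier at |Z| ≥ 3) × (D < 0)
over windows with defined D and applies Pearson's χ² (df = 1, no continuity
correction — window counts are large; expected cells < 1 trigger a
warning).

At genome scale (thousands of windows) a handful of swept windows leaves
the empirical s.d. essentially untouched; on toy genomes of a few hundred
windows the outliers themselves inflate it, and a lower threshold is
appropriate (the README demo uses 4).

## Population structure

The pairwise distance is the mean over SNP sites, called in both samples,
of the fraction of the four cross-sample allele pairings that differ —
equivalently the probability that one allele drawn from each individual
differs; in dosages, (g_x/2)(1−g_y/2) + (1−g_x/2)(g_y/2).  Note the
self-comparison of this definition is not 0 but half the sample's
heterozygosity; the DistanceMatrix diagonal is fixed to 0 by convention.
The divisor defaults to pairwise-complete sites (robust to missing data); a
global-L mode divides by the total SNP count instead — both are shipped
because the choice is not standardized for this metric.

Neighbour joining is the standard Saitou–Nei agglomeration (Q-criterion,
usual branch-length and distance-update formulas), ties broken by the lowest
index pair, negative branch lengths clamped to 0 with a log entry; the
result is an unrooted `skbio.TreeNode` (newick I/O).  PCA standardizes
dosages by 2p̂ and √(2p̂(1−p̂)), imputes missing calls to the site mean,
drops monomorphic sites, and eigendecomposes the sample covariance.
Evanno's ΔK(K) = |m(K+1) − 2m(K) + m(K−1)| / sd(K) over replicate clustering
log-likelihoods (sample s.d.); the clustering itself is out of scope — the
table is an input.  A uniform random SNP subsampler (default ~25,000 sites)
supports LD thinning for PCA/clustering.

## Heterozygosity, ROH, inbreeding

Window heterozygosity is heterozygous / called genotypes per non-overlapping
window (20- and 50-kb defaults), a SNP-conditioned proportion (it
deliberately understates per-bp genome heterozygosity).  Scaffolds shorter
than one window are skipped.  ROH are maximal runs of windows with
proportion ≤ ε spanning > 500 kb, allowing ≤ 1 interrupting window; "near
zero" is formalized as ε = max(5% of the sample's median window proportion,
one het call per typical window) — a reproducible stand-in for by-eye
calls, exposed as a flag.  The inbreeding coefficient is the moment
estimator F̂ = 1 − H_obs/Σ2p̂(1−p̂) over sites with reference-panel frequency
in [0.05, 0.95] (panel excludes the focal sample; ≥ 100 usable sites
required).  With small panels the MAF ascertainment leaves a residual bias
of order +0.02 (panels of ~20 samples) shrinking below 0.01 at panel sizes
around 60; recovery tests therefore run at study-scale panel sizes.

## Gene presence/absence

Samples under 15× mean depth are excluded; a gene is callable only if some
eligible sample has breadth ≥ 0.90; eligible samples with breadth < 0.15 in
callable genes are called deleted.  Boundaries follow the defining wording
literally: "fewer than 15%" strict, "90% or more" inclusive.  Cohort
frequencies are over eligible samples only, and the frequency spectrum bins
gene-loss events into singleton, (1 carrier, 20%], and > 20% classes.  The
per-sample reading of the candidate criterion is used (each low-breadth
sample in a callable gene is a call).

## LD and association

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (genotype r², the vcftools `--geno-r2`
convention), same-scaffold pairs within 100 kb, MAF ≥ 0.1.  The decay curve
is the mean r² per 1-kb distance bin; the "loss" summaries report the
smallest bin midpoint with mean r² ≤ (1−f)·(maximum bin mean) for
f ∈ {0.5, 0.9} — an operational formalization of reading a decay curve
(with a 10⁻⁹ relative tolerance on the comparison so that exact-boundary
bins qualify).  Empty bins are missing, not zero.

χ² tests are Pearson with no continuity correction (zero margins are
errors).  The Fisher exact test enumerates every table with the observed
margins (feasible for totals ≤ 500) and sums the probabilities of tables no
more probable than the observed one; probabilities use log-factorials, and a
10⁻⁹ slack absorbs floating-point ties.  Fruit-texture style tables printed
as percentages can be reconstructed with a rounding helper; because rounding
does not uniquely determine the counts, conclusions from reconstructed
tables are checked qualitatively (p below a coarse threshold), not as exact
values.

## Pipeline

`palmscan run` executes simulate → diversity → sweep scan → structure →
ROH/inbreeding → deletions → LD with one YAML config and one seed, writing
re-loadable per-stage outputs plus a JSON/markdown report; all thresholds
are echoed to the log at start, and reruns with the same config and seed are
byte-identical.  Stage failures abort with the stage name, preserving
partial outputs.

## Problem sizes and numerical choices

The recovery benchmarks run at desk scale chosen to make Monte-Carlo error
small relative to the quantities checked: pooled θ_W and π use 2,000
independent 1-kb loci at n = 124 chromosomes (MC s.e. ≈ 6·10⁻⁵, under 1% of
θ); the sweep-recovery scenario uses a 10-Mb genome (2,000 5-kb windows)
with three planted 20-kb sweeps at factor 0.05, where the planted
log₂-ratio (≈ 4.3) sits far beyond five empirical s.d. (≈ 0.5 per window);
inbreeding recovery averages five individuals at F = 0.125 over 900
independent 250-bp loci (≥ 10⁴ usable sites) in a 62-sample panel.  Seeds
are fixed in tests; every stochastic function takes an explicit
`numpy.random.Generator` or seed.

## Known limitations

* Estimation is genotype-based; there is no genotype-likelihood machinery,
  so low-depth data should be filtered upstream.
* The sweep scan detects diversity-ratio footprints only; haplotype- and
  composite-likelihood statistics are out of scope.
* ROH detection is window-threshold based, not HMM-based, and window
  granularity bounds boundary precision.
* The folded SFS has no outgroup polarization.
* The Fisher enumeration grows combinatorially with table size; totals
  above 500 are rejected in favour of χ².
* Simulated data omit the real-data artefacts listed above, so recovery
  results bound estimator correctness, not robustness.
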