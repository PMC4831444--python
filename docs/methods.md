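# Methods

This note documents the models and procedures implemented in `radscan`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Weir–Cockerham F_st

The estimator is the two-level ANOVA for diploid biallelic data: per locus,
the among-group (`a`), among-individual-within-group (`b`) and
within-individual (`c`) variance components are computed from per-group
sample sizes, allele frequencies and observed heterozygote fractions, with
the usual `n_c` correction for unequal sample sizes.  Conventions:

- **Missing data** are excluded locus-wise.  A group contributes to a locus
  only with ≥ 2 called individuals; a locus needs ≥ 2 usable groups to be
  defined.  Undefined loci (including loci monomorphic across the usable
  samples, where a + b + c = 0) are flagged and excluded from multilocus
  sums but kept in the per-locus tables.
- **Negative estimates are preserved.**  The estimator's sampling
  distribution extends below zero and the percentile stratification relies
  on that lower tail; nothing is truncated at 0.
- **Multilocus combination is ratio-of-sums** (Σa / Σ(a+b+c)), never a mean
  of per-locus ratios.  This is the convention of the standard F-statistics
  software and makes the multilocus value of L copies of a locus equal that
  locus's estimate.
- The implementation is vectorized over loci; tests verify exact agreement
  with an independent brute-force nested-ANOVA oracle over every 2-group
  configuration of ≤ 6 individuals.

Pairwise tables emit one ratio-of-sums estimate per (stratum, group pair)
along either axis of the species × location design, plus pooled rows.
Diversity summaries report Ho, unbiased He (2n/(2n−1) · 2p̂q̂), per-site π
and F_is = 1 − Ho/He per group.  π is computed over the retained variant
sites only: a SNP matrix carries no invariant-site information, so a
genome-wide per-nucleotide π is not recoverable from it and the per-site
value coincides with unbiased He.

## Percentile stratification

Loci are partitioned by per-locus F_st into half-open bins at the 60/70/80/90
percentiles (configurable).  The edge for break q is the sorted value at
0-based rank ⌊q·n/100⌋, so each upper bin holds ≈ (100−q)% of loci; tied
values share a bin, so realized counts may deviate from exact percentages —
the behavior expected of rank-based binning on heavily tied estimates.

## Distance trees and clustering

The allele-sharing distance between individuals is
1 − mean(1 − |x−y|/2) over loci called in both.  Neighbor-joining (via
scikit-bio) builds the tree; negative NJ branch lengths are clamped to zero
with the deficit absorbed by a sibling edge.  Bootstrap support resamples
*loci* with replacement (honouring multiplicity through per-locus weights)
and scores each internal bipartition by the percentage of replicates that
contain it.

PCA clustering mean-imputes missing dosages per locus, centers, projects to
the top components, and runs k-means for k = 1..k_max; k is selected by mean
silhouette with k = 1 chosen when no k ≥ 2 reaches 0.25 (an unstructured
cloud should not be partitioned).  All stochastic steps are seeded.

## Island-model simulator

A frequency-level Wright–Fisher island model: `n_demes` demes of N diploids,
each locus an independent biallelic frequency.  Per generation:
reproduction (binomial drift with 2N trials), symmetric mutation (binomial
allele flips at rate μ), then migration, where an individual emigrates with
total probability m split equally among the other demes; the census is
taken **after** migration.  Frequency-level simulation is statistically
exchangeable with an individual-based model for unlinked loci; diploid
genotypes are realized only at sampling, under Hardy–Weinberg proportions.

The census point is a deliberate life-cycle choice: offspring disperse as
juveniles (for marine larvae, before recruitment), so the population is
observed post-dispersal.  The ordering matters quantitatively at high
migration: at m = 0.5 with 9 demes of 1000, the stationary multilocus F_st
is ≈ 1e-4 censused after migration versus ≈ 6e-4 censused before it, because
migration immediately homogenizes most of each generation's drift.  Only
the post-migration census reproduces the near-zero differentiation a
"panmictic" scenario is meant to represent.

Ancestral frequencies are drawn Uniform(0.05, 0.95), identical across demes,
so F_st starts at exactly 0 and most loci stay polymorphic over the run
lengths used.  Quasi-stationarity is detected on a 2,000-locus probe
monitored every 10 generations: the trajectory is declared stationary when
|F(t) − F(t−50)| < max(0.05·F(t), 2e-4) — the absolute floor keeps
high-migration (near-zero F_st) trajectories from chasing noise — capped at
`max_generations` (default 500) with a warning.  Replicate runs then sample
14 diploids per deme at times spaced roughly twice the scenario's
decorrelation time (max(10, min(50, 1/m)) generations).

At the default scale (9 × 1000 demes, 80,000 loci) the panmictic scenario
stabilizes within ~60 generations at multilocus F_st ≈ 1e-4 and the
structured scenario (m = 0.02) within ~110–150 generations at ≈ 0.010–0.011
(the analytical island-model stationary value for these parameters).

## Outlier scan

The decision rule is an expected false discovery rate: a locus is an
outlier when its q-value is below 0.2 (0.05 as the stringent setting).  The
null is simulation-calibrated rather than parametric:

1. **Calibration.**  For a comparison with d groups of n sampled diploids
   and observed multilocus F_st θ*, the island model (d demes, N = 1000) is
   tuned so its stationary value matches θ*: the censored-after-migration
   stationary relation F = β(F + (1−F)c), with β the squared per-generation
   deviation-retention factor and c ≈ (1−1/d)/2N, is inverted for the
   migration rate, then refined once against a 20,000-locus probe run.
   Targets are clamped below at 1e-6; targets ≥ 0.95 are rejected as
   uncalibratable.  A calibrated ensemble of ≥ B = 200,000 defined null
   (F_st, He) draws is then sampled with the same d and n.
2. **Heterozygosity conditioning.**  Drift allows higher F_st at higher
   diversity, so null draws are partitioned into ≥ 20 contiguous He classes
   of near-equal occupancy.  He from small samples is heavily tied
   (p̂ moves in steps of 1/2n), so classes are built over unique values and
   any class below the occupancy floor B/(2·20) is merged into its smaller
   neighbor — without this, tie blocks (notably He = 0.5) strand undersized
   classes whose raised p-floor distorts the tail.
3. **Empirical p and FDR.**  p = (1 + #{null draws in the locus's He class
   with F_st ≥ observed}) / (B_class + 1); Benjamini–Hochberg converts the
   p-values of all considered loci in a comparison into q-values.

The granularity bound is intrinsic: p is floored at 1/(B_class+1), so with m
loci in a comparison a lone extreme locus can only reach q < 0.2 when
B_class ≳ m/0.2.  At the default B this makes the scan conservative on
80,000-locus null data (zero discoveries, mirroring the low false-positive
rate of Bayesian posterior-odds scans) while remaining powerful on scans of
a few thousand loci, or whenever several strong outliers share the extreme
rank.  B should be scaled with the number of loci when single-locus
discovery on very large scans is required.

Scans follow the study design: per_pair mode emits one scan per (species,
location pair) — nine for the 3×3 design — and global mode one scan per
species across all locations.  Null ensembles are cached across comparisons
keyed by (group count, sample size, target rounded to 3 decimals).  A locus
is a *repeated* outlier when flagged in ≥ 2 species (any pair) and
*triple-repeated* when flagged in all three; a stricter same-location-pair
matching is reported alongside, since either matching rule is defensible.
The shared-consideration ratio (fraction of flagged loci also tested in
another species) separates "few repeats because loci were not comparable"
from "few repeats despite comparability".  The randomization null permutes
individuals into a random equal-cell 3×3 design and reruns the entire
pipeline under a recorded seed.

## LD network analysis

LD is the squared Pearson correlation of dosage vectors over
pairwise-complete individuals (the Burrows-type composite surrogate —
RAD genotypes are unphased); pairs sharing < 80% of individuals are
undefined, and the dense matrix is soft-capped at 12,000 loci.  Edges enter
as the threshold descends from 1.0 on a 0.01 grid; clusters are connected
components (single linkage) and every union of two components is a recorded
merge event.  At each merge, for each focal constituent with ≥ 2 members,

λ = n_focal · (median within-cluster r² before merge − median after),

i.e. how much the merge dilutes the focal cluster's cohesion, scaled by its
size (the verbal definition of the method this module reimplements admits
exactly this form).  Outlier clusters satisfy λ > median(λ) + φ·MAD(λ)
(default φ = 4) and carry ≥ |E|min internal edges at their merge threshold
(default 16); SOCs are outlier clusters with no outlier nested inside.
Per-SOC summaries (multilocus F_st across sample groups, median within-SOC
r², PC centroid-separation score) separate the two signatures of interest:
admixture LD (elevated F_st, diffuse linkage) versus physical linkage such
as an inversion (F_st ≈ 0, high median r²).

## Synthetic data generator

The generator emulates the study conditions: 3 species × 3 locations × 14
diploids (126 individuals), 30,000 stacks with 1/2/3 SNPs at probabilities
0.45/0.30/0.25 (mean 1.8, max 3), ancestral frequencies Beta(0.8, 0.8)
truncated to [0.02, 0.98] (a realistic He spread), per-stack × individual
negative-binomial depth with mean 31 and shape 8, genotypes dropped to
missing when depth < 10 plus a 2% missing-completely-at-random component
(≈ 6% total missingness), and depth set to 0 wherever a genotype is missing.

Divergence uses **crossed additive Balding–Nichols effects**: per SNP, a
location deviation (parameter F_loc) shared by all species and a species
deviation (F_sp) shared by all locations, added to the ancestral frequency
and clipped to [0, 1].  Sharing each effect across the other factor is what
lets both axes carry their full parameter as a main effect — a literal
location-then-species hierarchy would dilute the species axis to F_sp/3 and
inflate the location axis by the same amount, contradicting the intended
near-equal ≈ 0.004 divergence on both axes.  Defaults F_loc = F_sp = 0.004
reproduce multilocus W&C estimates of ≈ 0.004 on both axes (verified over
10 seeds in the suite).  SNPs within a stack share the stack's ancestral
frequency plus N(0, 0.03) jitter, reproducing the redundancy the
one-SNP-per-stack filter resolves.

Planted signals overwrite neutral frequencies and are recorded in a truth
table: fixed differences (frequency 0 in one location, 1 elsewhere, all
species), location- or species-divergent loci (frequency pattern
(0.5+Δ, 0.5−Δ, 0.5) with Δ = √(1.5·F·0.25), giving among-group variance
F·p̄q̄), and linked blocks (two latent haplotypes per individual copied into
each block locus with flip probability (1 − r²^¼)/2, so realized pairwise
r² approaches the target; a target of 0.6 lands in [0.45, 0.75] across
seeds).

What the generator does **not** emulate: read-level error and allele
dropout, null alleles, paralog merging, selection dynamics (planting is
static), linkage outside planted blocks, and non-random missingness beyond
the depth rule.  Passing tests therefore demonstrate correctness of the
estimators and decision rules under the stated sampling model, not
robustness to RAD artefacts.

## Filtering conventions

Coverage filtering acts at the stack level using the per-stack mean depth
across its SNPs (coverage is a property of the read pile; a stack passes or
fails as a unit).  The rare-allele rule removes loci whose globally minor
allele has ≤ 1 carrier in every grouping unit; monomorphic loci pass this
filter (handled downstream).  The heterozygosity filter drops loci with
observed heterozygote fraction strictly above 0.5 (undefined all-missing
loci are dropped with a warning).  Individual missingness uses a strict
20% threshold.  All thresholds are inclusive/strict exactly as tested, and
all filters are idempotent.

## Problem sizes

The test suite runs the island-model scenarios at the full stated scale
(9 × 1000 demes, 80,000 loci, 30 datasets per scenario) and the scan
machinery at 200,000-draw null ensembles; generator-based tests use
500–2,000 stacks, which preserves the design (126 individuals, both
divergence axes, planted truth) at a fraction of the locus count.  The
outlier-recovery tests respect the granularity bound above: a single
planted locus is scanned at ~900 loci per comparison, three planted loci at
~3,600.

## Known limitations

- The empirical-FDR scan cannot flag a lone outlier among ≫ B_class/5 loci
  (granularity bound); this is a property of empirical p-values with BH,
  not a bug, and is the reason the reference Bayesian tool uses posterior
  odds instead.
- The calibration inversion assumes the island model's stationary regime;
  observed F_st values produced by non-equilibrium histories are matched in
  stationary F_st only.
- π is per-variant-site; no invariant-site reconstruction is attempted.
- LD matrices are dense; very large locus sets must be pre-filtered.
- NJ bootstrap support on very shallow structure is conservative: with few
  loci the full-group bipartition is rarely exactly reproduced.
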