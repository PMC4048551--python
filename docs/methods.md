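# Methods

## The problem

Admixed genomes are mosaics of ancestry tracts inherited from two diverged
source populations. Each generation of recombination breaks tracts at a
rate of about one crossover per Morgan, so tract length decays roughly as
1/g for an admixture pulse g generations ago. `blockclock` estimates local
ancestry along phased haplotypes, summarizes the intactness of the minority
("introgressed") ancestry with the scaled block size (SBS), and uses SBS to
separate recent from ancient admixture — comparatively, against reference
individuals of known recent hybrid origin, never as an absolute date.

## Local ancestry: the two-panel copying HMM

Each target haplotype is modelled as an imperfect mosaic copy of donor
haplotypes from two reference panels (A and B). Hidden states are the
individual donors. The chain starts with probability 1/2 on each panel
(uniform within a panel); between adjacent markers at genetic distance d cM
it switches to a uniformly chosen donor (over both panels) with probability
1 − exp(−ρ·d), otherwise stays; the target allele matches the donor's with
probability 1 − ε; missing alleles on either side emit probability 1.
Posteriors come from the scaled forward–backward recursion with per-site
renormalization (numerically equivalent to log-space for these chain
lengths); each chromosome is an independent chain. The per-site ancestry
estimate is the posterior mass on panel A. The implementation exploits the
rank-one transition kernel ((1−r)I + (r/n)𝟙𝟙ᵀ), so one chromosome costs
O(markers × donors).

Donor panels are selected from individuals with < 2% ancestry from the
other source (strict inequality); panel priors are equal because the method
is aimed at admixed targets, not at estimating panel proportions.

Simplifications relative to full chromosome-painting machinery, deliberate
because downstream statistics consume only the two-panel posterior: no EM
estimation of copying parameters, no donor-specific copying proportions,
no chunk-count outputs, exactly two panels. The painter is deterministic
and order-independent, so no averaging over runs is needed.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ρ (switch rate) | 0.1 | per cM | ~10 expected copying switches per Morgan; coarse enough to track ancestry tracts rather than fine haplotype sharing. Plays the role usually filled by an effective-population-size scaling (the pooled-breed surrogate is ~4000); exposed in config. |
| ε (miscopy) | 0.15 | probability | absorbs genotyping error *and* the fact that a target is never a literal copy of a finite donor panel. Calibrated once against the simulator: with ε = 0.15, ρ = 0.1, 100+100 donor haplotypes, F = 0.2, g = 10 and 0.05 cM marker spacing, ≥ 90% of markers give the true ancestry posterior > 0.75 (the test suite checks this). Small ε (~0.01) over-penalizes single-site mismatches and degrades tract recovery when donors carry no LD. |
| cM/Mb | 1.0 | — | genetic positions default to physical positions at a uniform rate when the map carries no cM column; configurable. |
| prior P(panel A) | 0.5 | — | fixed; equal a-priori copying from either source. |

## Blocks and SBS

Markers are called A when P(A) > 0.75, B when P(A) < 0.25 (both strict),
uncertain between. Runs of equal calls merge into blocks; boundaries sit at
the integer midpoint between adjacent differing markers, terminal blocks at
the first/last marker. Coordinates are 0-based half-open bp everywhere.

The minority ancestry is decided once per individual, genome-wide: the
label with less total autosomal block length over both haplotypes
(uncertain bp excluded from numerator and denominator; an exact 50/50 tie
is an error). For each haplotype-autosome, with minority blocks b₁..b_k as
proportions of the first-to-last-marker span: SBS = median(bᵢ)/Σbᵢ;
k = 0 leaves the component undefined. Per individual, SBS is the plain
mean over all defined haplotype × autosome components (X excluded). Even-k
medians are midpoints of the central pair. Since median ≤ sum, SBS ∈ (0,1]
with SBS = 1 exactly when k = 1; under strict-minority ancestry the median
block proportion itself stays below 0.5.

Denominators use the painted marker span, not assembly lengths, so values
are comparable across marker panels but not across very different panel
designs.

Classification: the cutoff is the minimum defined SBS among reference
individuals of known recent hybrid origin; an individual is flagged recent
when SBS ≥ cutoff, so references always self-classify as recent.

## Chromosome-level tests

Per-chromosome ancestry proportions are the A-fraction of labelled bp,
averaged over an individual's two haplotypes (the package also accepts an
externally estimated individual × chromosome matrix, so model-based
clustering output can be dropped in).

**Bootstrap median test.** Under the null of uniform admixture across
chromosomes, every (individual, chromosome) value of a group is
exchangeable. The pool of all such values is resampled: each of 50 000
replicates draws n values with replacement (n = group size — one synthetic
chromosome) and records the median. Cutoffs are the empirical α/2 and
1 − α/2 quantiles of replicate medians at the Bonferroni-corrected level
α = (0.05/2)/(30 chromosomes × 4 groups) ≈ 0.0002. Per-chromosome p-values
are reported as the bound (c + 1)/n_reps, c counting replicates at least
as extreme in the nearer tail (not doubled) — bounds land on multiples of
1/n_reps. n_reps < 1/α is rejected as unresolvable.

**Permutation variability ANOVA.** Deviations d[i,c] = |value − group
median of chromosome c| (per-chromosome median, not the grand median; the
alternative reading exists but is not used). The observed one-way F with
chromosomes as groups is compared against F under random permutation of
chromosome labels over the pooled deviations; p = (#{F* ≥ F} + 1)/(R + 1)
with R = 5000. The F statistic is computed by hand so degenerate cases are
explicit (zero within-group variance → +inf; zero between → 0; zero total
variance → p = 1 with a warning). Tiny pools (≤ 8 values) can be
enumerated exhaustively, giving exact p.

Both tests are seeded and bit-reproducible.

## Preprocessing

Filters follow standard multi-breed SNP-chip curation, in a fixed order:
loci with mean observed heterozygosity > 0.5 in ≥ 10 breeds (paralogy
proxy), then call rate < 0.8 in ≥ 10 breeds (null-allele proxy), then
missing in ≥ 70% of individuals; afterwards individuals with > 10% missing
data, then loci missing in > 10% of the survivors. All comparisons strict
except the 70% rule ("at least"). Removal reasons record the first rule
that fired, so reasons partition the removed set, and each filter is
idempotent. An optional exclusion list handles markers undecodable against
a chip manifest (no computable rule). The X pseudoautosomal boundary is
quoted in 1-based assembly coordinates (137 109 768) and converted at its
single point of use to the package's 0-based convention. Sex is assigned
from non-PAR X heterozygosity: < 1% heterozygous calls → male (the margin
absorbs genotyping error), and residual male X hets are recoded missing.
The 10%-missingness individual filter counts X loci before hemizygous
recoding.

## The simulator

What it emulates: two source populations diverged by drift — ancestral
frequencies Uniform(0.05, 0.95), population frequencies Balding–Nichols
with parameter F (independently per population), chip-style ascertainment
redrawing loci whose combined minor-allele frequency falls below 0.1 — and
a single admixture pulse of proportion m, g generations ago, with Poisson
recombination. Defaults (m = 0.33, g = 25, F = 0.2, N = 1000 diploids,
50 sampled individuals, 10 chromosomes × 100 cM × 300 evenly spaced
markers, 1 cM/Mb) describe a tractable cattle-like design: m matches the
introgressed fraction reported for known recent hybrid breeds, g sits in
their 20–50-generation age range, and F produces Hudson-Fst ≈ 0.2 panels
(the test suite verifies the estimator lands in [0.15, 0.25]).

Two engines share this configuration:

* **forward** — explicit diploid Wright–Fisher: founder *individuals* are
  wholly A or B (so first-generation gametes are unrecombined, as in real
  F1s), each offspring haplotype is a Poisson-crossover recombinant of one
  random parent's two haplotypes, n_sample individuals drawn after g
  generations. Exact but O(N·g).
* **pulse** — the classical Markov approximation: breakpoints Poisson with
  rate g per Morgan, tract labels i.i.d. B with probability m, adjacent
  same-label segments merged. Valid for g ≪ N. At very small g the two
  engines differ structurally by ≈ g/(g−1) in mean tract length (the
  forward model's first meiosis creates no junctions); they agree within
  15% by g ≈ 25 in the tested regime. Large or old cohorts use the pulse
  engine.

What it does **not** emulate: background LD within source populations
(loci are independent given frequencies — ancestry structure, not
haplotype structure, is what downstream statistics consume), continuous
migration, selection, X-specific transmission, variable recombination
maps. Passing tests therefore validate the method's behaviour on ancestry
mosaics with clean frequency divergence; on real data, background LD and
map heterogeneity will add noise the simulation does not represent.

Every simulated haplotype carries its true tracts, so the painter, block
caller and SBS can be validated against ground truth, and "truth
paintings" (posterior 0/1) let the block/SBS stages be studied in
isolation from painter error.

## Problem sizes used by the test suite

Simulation-backed checks run on cohorts of 50 individuals, 10 chromosomes
× 100 cM × 300 markers (10 replicates for the age-monotonicity check,
5 seeds for classification recovery, 4 ages × 5 seeds for the
independence check), bootstrap calibration on 40 × 29 matrices over 20
seeds at 5000 replicates, and HMM exactness on ≤ 5-marker, ≤ 6-donor
instances against full path enumeration (tolerance 1e-10). These sizes
were chosen so the full suite completes in well under a minute per module
while keeping Monte Carlo error far from the asserted margins.

## Known limitations

* SBS is comparative. Absolute dating would require trusted recombination
  maps and population sizes; the CLI deliberately reports no generations.
* At chip-scale marker spacing the painter cannot resolve tracts shorter
  than a few marker intervals; for old admixture (large g) painted SBS
  saturates and the age signal must come from denser maps. Ground-truth
  experiments (simulator) are unaffected.
* SBS couples weakly to the introgressed proportion through its
  denominator: at fixed age, individuals with more introgressed tracts
  score slightly lower. Across the simulated age range the correlation
  with minority fraction is weak at most ages but can reach ≈ −0.3 for
  mid-aged, moderately admixed cohorts, and the statistic is least
  reliable at very low introgression levels where few blocks exist.
* The exact-tie minority case (precisely 50/50 labelled bp) is refused
  rather than resolved arbitrarily.
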