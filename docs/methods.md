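# Methods

## The load model and its assumptions

The closed-form model predicts the diploid male proportion (DMP) among
diploids from four ingredients: the number of sex loci (1 or 2), the
sex-allele diversity per locus (k, and l for the second locus), the
sibmating rate α, and the relative developmental survival of diploid males
(default 1).

Assumptions, all inherited from the verbal model the package formalizes:

- **Equal sex-allele frequencies.** A random male matches a heterozygous
  locus with probability 2/k and a homozygous locus with probability 1/k.
  This is what makes θ = 2/k for single-locus CSD. Unequal frequencies are
  out of scope.
- **Female-class frequencies conditioned on viability.** Under random
  mating a diploid is heterozygous at a locus with probability 1 − 1/k
  independently across loci; diploids homozygous at *all* loci are male,
  so the two-locus female classes (het-both, hom-at-locus-1,
  hom-at-locus-2) are renormalized by 1 − 1/(kl). Without this
  normalization the class frequencies do not sum to one among females, and
  the 9–20 allele consistency range is not reproduced.
- **Sibmating conditionals.** Half of sibmatings with single-locus (or
  single-locus-homozygous) females are matched; a quarter of sibmatings
  with double-heterozygous females are matched at both loci. These are the
  stated conditionals of the verbal model, not a full-pedigree derivation;
  see "Known discrepancy" below.
- **Linearity in α.** With survival 1 both predictions are affine in α, so
  prediction bands over an α interval are exactly the evaluations at the
  endpoints (sorted — the slope is negative for k < 4).
- **Survival adjustment.** With diploid-male survival s < 1 the reported
  DMP is s·m / (s·m + 1 − m) where m is the conceived-diploid male
  fraction. s = 1 (the default) reproduces the plain formulas; the
  adjustment is an extension and is disabled by default.

The inverse mapping between the inbreeding coefficient and the sibmating
rate, α = 4·F_IS/(3·F_IS + 1) and F_IS = α/(4 − 3α), is the equilibrium
relation for partial full-sib mating. Negative F_IS estimates (heterozygote
excess) floor α at 0 with a logged warning: a sibmating rate cannot be
negative, and small negative F_IS is expected sampling noise.

### Known discrepancy, quantified rather than corrected

The "half of sibmatings with homozygous females are matched" conditional is
exactly true only when the female's homozygosity descends from a homozygous
mother. When it arises from a heterozygous mother plus a matched father,
the brother (whose alleles are purely maternal) matches the homozygous
locus half the time instead of always, and the overall matched rate for
such females is 1/4, not 1/2. The pedigree simulation mode
(`simulate_matings(..., mode="pedigree", daughter_class="hom1")`) measures
both rates; the closed forms are implemented as stated and the deviation is
reported, never silently corrected. At realistic allele numbers the hom
classes are rare (frequency ≈ 2/k among females), so the effect on DMP is
second-order.

## Mating oracle

`enumerate_mating_table` builds the exact joint distribution of female
class × per-locus match pattern, mixing the sibmating component (at the
stated conditionals) and the random component (independent per-locus match
probabilities) by α. Its expected DMP — probability-weighted mean of the
per-class diploid-male fractions (0.5 for matched single-locus/hom-class
matings, 0.25 for matched double-het matings) — agrees with the closed
forms to 1e-12 across k = l ∈ 2..30 and all α, which is the package's
primary internal consistency guarantee. Equal diploid brood sizes across
mating classes are assumed when converting per-mating fractions to a
population DMP.

`simulate_generations` is an individual-based haplodiploid population with
discrete generations: a fixed number of mated females; each daughter's mate
is a brother with probability α, else a random male; diploid males are
never recruited (reproductive dead ends); unlinked neutral biallelic loci
are co-transmitted. It reports per-generation multi-locus F_IS
(1 − ΣHo/ΣHe over polymorphic loci), realized DMP among diploid eggs, and
surviving sex-allele counts. At α = 0.081 with 500 females the F_IS series
reaches the equilibrium α/(4 − 3α) ≈ 0.0216 within ~5 generations; the
acceptance suite uses 20 seeds × 10 generations, a problem size chosen to
give standard errors well below the quantity being verified while running
in about a second. If sex-allele diversity collapses until no viable
daughters can be drawn, the series is truncated with an `extinct` flag
rather than raising.

Fertilization probability (primary sex ratio) defaults to 0.5, matching a
near-even field sex ratio; it scales the haploid-male class only and
cancels out of DMP.

## Population-genetic estimators

- **F-statistics** are Weir–Cockerham variance components (a: among
  groups, b: among individuals within groups, c: within individuals),
  summed over alleles and loci; multi-locus estimates are ratios of summed
  components, so (1 − F_IT) = (1 − F_IS)(1 − F_ST) holds by construction.
  95 % CIs are percentile bootstrap over loci (seeded; 20,000 replicates by
  default in the library, smaller in the pipeline defaults). Per-field
  F_IS is 1 − ΣHo/ΣHe with unbiased gene diversity
  He = n/(n−1)·(1 − Σp²).
- **Missing data** are handled pairwise-complete per locus; a group needs
  at least 2 non-missing individuals (4 gene copies) at a locus to
  contribute.
- **Pairwise F_ST** uses the same estimator restricted to the two fields,
  with p-values from permuting individuals between the pair,
  p = (exceedances + 1)/(permutations + 1) — the convention used for all
  permutation tests here, which keeps p ≥ 1/(n+1) and uniform under the
  null.
- **AMOVA** is locus-by-locus at the gene-copy level on allelic mismatch
  distances, with the standard nested-design coefficients for unequal
  sizes; sums of squares and variance components are summed over loci, and
  negative moment estimates are reported as computed. Degrees of freedom
  are reported for the complete design (regions − 1, fields − regions,
  2N − fields), the usual presentation even when a few calls are missing
  per locus.
- **HWE** is the exact conditional test. For biallelic loci a full
  enumeration over heterozygote counts is available; the general route is
  a Markov chain over random pairings of the labelled allele copies
  (uniform transposition proposals; uniform over pairings is exactly the
  conditional null on genotype tables), with dememorization followed by
  counting tables no more probable than the observed one. Ties in table
  probability are counted as extreme, using a 1e-9 relative tolerance.
- **LD** between unphased loci: haplotype frequencies by EM over the
  unknown phases (individuals aggregated into weighted two-locus genotype
  classes, ≤ 9 for a SNP pair), LRT = 2(logL(ĥ) − logL(p̂_A ⊗ p̂_B)),
  permutation p-values by shuffling one locus across individuals. The
  observed statistic uses 5 random EM restarts plus the allele-frequency
  product start; permuted replicates use 1 restart plus the product start,
  since for SNP pairs the likelihood is effectively unimodal and this keeps
  the all-pairs filter tractable.
- **Locus filtering** removes HWE-deviant loci first (raw α = 0.05 per
  locus by default, sequential Bonferroni optional), then applies
  sequential Bonferroni to all pairwise LD p-values and removes one
  randomly chosen (seeded) member of each remaining significant pair until
  none is left. A minimum-vertex-cover removal mode (brute force up to 20
  involved loci, greedy beyond) is provided but not default, mirroring the
  random-removal practice of field studies.
- **Panel selection** drops candidates with MAF below the floor (default
  0.2), more than two alleles, or any other candidate within the spacing
  window (default 50 bp) on the same scaffold — spacing is judged against
  the *full* candidate list, because a neighbouring polymorphism spoils
  assay primer design regardless of its own MAF — then fills MAF-bin
  quotas (defaults (0.2,0.3] : 20, (0.3,0.4] : 40, (0.4,0.5] : 40) by
  descending quality with at most one SNP per scaffold.

## DMP estimation

DMP = diploid males / (diploid males + females); haploid and
unknown-ploidy males never enter the estimate. Intervals are
Clopper–Pearson (exact binomial; conservative coverage ≥ nominal at the
study-scale n ≈ 1500, verified exactly in the tests), level 0.95 by
default. Weighted field summaries use normalized reliability weights with
the unbiased weighted variance, SE² = Var·Σw² — the natural choice when
weights express sample sizes per plant.

## Synthetic data: what it emulates, and what it does not

`gen_structured_genotypes` follows the Balding–Nichols model: ancestral
frequencies uniform on [MAF floor, 0.5], field frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at F = target F_ST, genotypes with a
homozygote excess of target F_IS, uniform missingness. Defaults copy the
study shape: 4 regions × 2 fields × 17 individuals, 81 biallelic loci,
F_ST = 0.05, F_IS = 0.02, 2.5 % missing. This reproduces the first two
moments of structure and inbreeding that the estimators consume, which is
what the recovery tests check (estimator means within ±0.01 of truth over
50 seeds). It does **not** emulate linkage, allele-frequency correlations
between regions (fields are exchangeable draws), locus-specific missing
patterns, genotyping error, or the clinal/clustered structure of real
landscapes — so passing tests demonstrate estimator correctness under the
model's assumptions, not robustness to real-data pathologies.

`gen_sibmating_genotypes` is pedigree-true: it runs the population
simulator, so its F_IS is an emergent property, making it a genuine
ground-truth check of the α ↔ F_IS mapping rather than a restatement of
it.

## Numerical choices

- All proportions are kept at full precision; rounding happens only in
  report writers and the acceptance summary.
- Band containment is inclusive at the endpoints; the allele-number grid
  defaults to 3..100.
- Every stochastic routine requires an explicit seed and is bit-reproducible
  under it; the pipeline derives per-stage seeds from the run seed and logs
  them.
- Pipeline test-size defaults (HWE chain 20,000 steps, 100 LD permutations,
  2,000 bootstrap replicates) trade p-value resolution for runtime; the
  heavier settings used by desktop population-genetics suites (10⁶-step
  chains, 16,000 permutations) are plain config values when finer
  resolution is required.
- EM convergence: absolute log-likelihood change < 1e-10, max 500
  iterations; non-convergence is flagged, and the permutation p-value is
  still produced from the best statistic found.

## Known limitations

- Unequal sex-allele frequencies, more than two sex loci, triploid
  offspring of diploid males, mate choice, sperm competition and biased
  fertilization are not modelled.
- AMOVA reproduces the standard locus-by-locus decomposition but the exact
  treatment of missing genotypes differs between published programs;
  agreement with any particular one is to estimator-choice precision, not
  to the last printed decimal.
- The LD permutation null uses a cheaper EM restart schedule than the
  observed statistic (see above); with badly multimodal likelihoods (not
  observed for SNP pairs) this could bias p-values slightly downward.
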