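# Methods

`gartergen` couples two views of a small, fragmented wildlife
population: a genetic view (SNP panels sampled from each site) and a
demographic view (daily capture histories from trapping campaigns).
This note records the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducing results.

## Genotype data model and filters

All genetic analyses run on a diploid dosage matrix (individuals x
biallelic loci; cells count alternate-allele copies, with a missing
sentinel). Two filters mirror standard panel construction for
reduced-representation SNP data:

* **Presence filter** — a locus is retained only if genotyped in at
  least a fraction `min_fraction` (default 0.8) of the individuals in
  *every* population. The per-population reading is deliberate: a locus
  that dropped out of one site entirely would otherwise bias
  between-site comparisons. A pooled-fraction mode exists behind a
  flag. The threshold is boundary-inclusive and the filter is
  idempotent.
* **MAF screen (`Pcrit`)** — loci with minor-allele frequency below
  `pcrit` (default 0.05, the conventional cutoff for LD-based Ne
  estimation) are removed before Ne estimation. A frequency exactly
  equal to `pcrit` is retained, matching the "exclude alleles with
  frequency *less than* the critical value" convention of the standard
  Ne-estimation software.

Multi-allelic VCF records are skipped with a logged warning: every
estimator here is defined for biallelic SNPs.

## Diversity statistics

Per population (and sampling period): mean observed heterozygosity
`Ho`, plug-in expected heterozygosity `He = 1 - sum p^2`, nucleotide
diversity `pi = (2n/(2n-1)) He` at variant sites (the unbiased
pairwise-difference estimator, hence `pi >= He` on the same sample),
and rarefied allelic richness

    Ar = sum_a [ 1 - C(2n - n_a, g) / C(2n, g) ],

the expected number of distinct alleles in a hypergeometric subsample
of `g` gene copies. The pairing of a biased `He` with an unbiased `pi`
is intentional — it reproduces the estimator conventions of the stacks
summary-statistics module that field datasets of this kind are
processed with, and it is why diversity tables show `pi` slightly
above `He` throughout. The rarefaction baseline `g` defaults to the
smallest per-locus gene-copy count across the groups being compared;
it is exposed as a parameter because site-level and cluster-level
tables legitimately use different baselines.

## Differentiation and isolation by distance

Weir-Cockerham theta is computed from the diploid variance components
a (among populations), b (among individuals within populations), and
c (within individuals); multi-locus estimates use the ratio of sums
`sum(a) / sum(a+b+c)`, which is robust to low-information loci.
Negative estimates are reported as computed. Pairwise significance
comes from permuting individual site labels with the add-one rule
`p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1)`, and a
Bonferroni-corrected alpha is reported for the number of pairs.

The Mantel test correlates off-diagonal genetic and geographic
distances (Pearson r, with R^2 = r^2 reported), permuting population
labels jointly on rows and columns; geographic distances are
great-circle kilometres from decimal-degree site coordinates. The
regression is on raw theta versus km (not theta/(1-theta)); 1000
permutations by default.

## Effective population size

**LD method (single sample).** For every pair of loci surviving the
MAF screen, the Burrows composite disequilibrium is estimated from
unphased dosages over the individuals complete for the pair:

    Delta = (1/(2S)) sum x_i y_i - 2 p q
    r^2   = Delta^2 / (v_x v_y),   v = p(1-p) + D_hat

where `D_hat` is the within-locus departure from Hardy-Weinberg
homozygosity (so `v` is half the empirical dosage variance, and the
denominator reduces to `p(1-p)q(1-q)` at exact HW proportions). The
composite denominator matters: the published sampling expectations
below were calibrated for it, and using the HW-assumed denominator
instead biases Ne upward by ~25-45% at the designs this package
targets. The weighted mean r^2 (weights = per-pair sample size) is
put on the calibrated scale with the finite-sample factor
`(S/(S-1))^2`, the sampling expectation

    E[r^2_sample] = 1/S + 3.19/S^2            (S >= 30)
                  = 0.0018 + 0.907/S + 4.44/S^2  (S < 30)

is subtracted, and the drift signal is inverted with the
random-mating coefficients

    Ne = (1/3 + sqrt(1/9 - 2.76 r^2_drift)) / (2 r^2_drift)   (S >= 30)
    Ne = (0.618 + sqrt(0.618^2 - 5.24 r^2_drift)) / (2 r^2_drift)  (S < 30)

A non-positive drift signal maps to infinite Ne — never a negative
estimate. `S` is the harmonic mean of per-pair sample sizes
(pairwise-complete handling of missing data). Confidence intervals
are a delete-one-individual jackknife on the `r^2_drift` scale,
transformed through the (monotone) Ne formula; when the interval
crosses zero drift the upper bound is reported as infinite.

**Temporal method (two samples).** Per locus the standardized
frequency change between samples taken t generations apart is

    Fc = (1/2) sum_a (x_a - y_a)^2 / ((x_a + y_a)/2 - x_a y_a)

(mean over the two alleles; loci fixed for the same allele in both
samples are undefined and skipped). After removing the sampling
contributions,

    Ne = t / (2 (Fc - 1/(2 S0) - 1/(2 St))),

again with non-positive corrected signals mapping to infinity.
The CI treats the mean Fc as chi-square with degrees of freedom equal
to the number of independent alleles (one per biallelic locus).
Sampling plan II is the assumed design. **t is a required user
parameter**: converting calendar years between sampling periods into
generations needs a species-specific generation time that the package
cannot guess.

**Ne/Na.** The effective-to-census ratio uses the temporal point
estimate when finite and available, otherwise the LD estimate, over
the modal adult abundance; reported to two decimals with half-up
rounding.

## Capture-mark-recapture abundance

The closed-population model uses parameter-expanded data
augmentation: observed histories are padded with all-zero
pseudo-histories to a fixed pool M, each row gets a latent inclusion
indicator `z_i ~ Bernoulli(psi)` with `psi ~ Uniform(0,1)`, and — in
multi-site runs — a latent site membership `g_i ~ Categorical(pi)`,
`pi ~ Dirichlet(1,...,1)`; abundance is `N_s = sum z_i 1[g_i = s]`.
One pooled augmentation pool with latent site allocation is the
default (per-site pools are available by fitting sites separately).
Capture probability is logit-linear:

    logit p_id = logit(p_mean) + a_s + b_sd + e_i
                 + bT temp_zd + bSex male_i + bSVL svl_zi + bBeh c_id

with Uniform(0,1) prior on `p_mean`, Normal(0, 3.16) on fixed
effects, and half-Cauchy(1) on the random-effect SDs (site a, date
within site b, individual e). Date effects are nested within site
because sites are trapped over different windows. The behavioural
covariate `c_id` is 1 on occasions directly following an *observed*
capture (a trap response defined on data, not on latent state), and 0
on each site's first occasion and for pseudo rows. Temperature and
SVL are standardized by observed-data mean/SD; unknown sexes are
imputed from a per-site Bernoulli with uniform prior, and missing
standardized SVL from a standard normal. Individual random effects
apply to pseudo rows too — exchangeability between observed and
pseudo rows is what makes the augmentation valid, at some
computational cost.

Two samplers share one interface. When every covariate and random
effect is disabled (constant p), all full conditionals are conjugate
and a pure Gibbs sampler runs (joint z/site updates, Beta updates for
p and psi, Dirichlet for pi); this path is exact against an
enumeration oracle on tiny pools and fast enough for repeated
calibration runs. The general model runs Metropolis-within-Gibbs:
conjugate updates for z, pi, psi and sex; vectorized elementwise
random-walk updates for random effects and imputations; random-walk
updates with the appropriate priors for location parameters and log
random-effect SDs. Default run lengths mirror the monitoring protocol
this model is built for (5 chains x 200,000 iterations, 10,000
burn-in, thin 10); tests and examples use far shorter, empirically
well-mixed runs. Convergence is summarized with potential scale
reduction and effective sample size (via arviz); a warning is raised
above 1.1, and a pool-saturation check raises an error when posterior
mass reaches M (the prior would truncate the abundance posterior —
rebuild with a larger pool).

Summaries follow the field's reporting conventions: the posterior
mode of integer abundance (ties toward the smaller value), the
shortest contiguous interval containing 95% of sorted draws (HPDI),
covariate evidence as the fraction of draws sharing the median's sign
(flagged "strong" at >= 0.9), and per-draw male/female ratios with a
bias call when the HPDI excludes 1 (draws with zero females are
tracked as undefined rather than discarded silently).

A Huggins-type conditional-likelihood estimator is kept as a separate,
simpler alternative: each observed history's likelihood is divided by
its inclusion probability `p*_i = 1 - prod(1 - p_id)` and abundance is
the Horvitz-Thompson sum `sum 1/p*_i`, with sex and occasion fixed
effects (occasions without captures share the baseline to avoid
separation). The two estimators answer the same question under
different conditioning and are deliberately not merged.

## Genetic-rescue assessment

For recipient r and donor s, the mean inbreeding coefficient is
`F = 1 - Ho_r / He_s` (observed heterozygosity of the recipient so
that both drift and non-random mating register; expected
heterozygosity of the donor). Donor selection is restricted to the
recipient's regional genetic cluster (cluster membership is an input
from external clustering, not computed here) under four scenarios:
nearest neighbor, largest Ne, highest He, and largest adult
abundance. When a scenario's argmax is the recipient itself the cell
is reported as not applicable. Conventions that required a decision:

* **Donor heterozygosity column.** `F` uses the nucleotide-diversity
  column (the unbiased estimator) of the diversity table by default —
  with the bundled published tables, only this choice reproduces the
  printed rescue matrix from the printed diversity values (e.g.
  1 - 0.092/0.117 = 0.21 where the plug-in He column would give 0.19).
  A switch selects the plug-in He instead.
* **Max-He ties.** Printed 3-decimal He values can tie; ties break by
  higher pi, then higher Ho, then site name.
* **Nearest neighbor.** Site metadata may carry a curated
  nearest-neighbor donor reflecting habitat connectivity; when
  present it overrides straight-line great-circle distance (the
  bundled focal-site table uses the curated pairs).
* **Erosion flags.** `small` = (Na < 100 AND Ne < 100): a population
  currently small and effectively small for multiple generations.
  `erosion` = F strictly greater than the threshold, default 0.10
  (the "F > 10%" working rule; the literature also contains a much
  more conservative 0.01 suggestion, selectable via `f_threshold`).
* **Rounding.** Reported F and Ne/Na values round half-up (0.125 ->
  0.13), not banker's rounding.

## Synthetic data

**Wright-Fisher generator.** Two modes with one interface:

* `individual` (default): each deme is a set of N diploid genotypes;
  every offspring draws two parents uniformly at random (ideal
  monoecious population, selfing allowed) and one allele per locus
  from each, loci transmitted independently. Finite parent numbers
  generate both allele-frequency drift and the composite LD among
  unlinked loci that the LD-Ne estimator measures. This mode is
  required for any LD-related validation — a frequency-only scheme
  cannot produce the signal.
* `frequency`: per generation, symmetric island-model migration mixes
  deme frequencies, then 2N gene copies are binomially resampled;
  sampled genotypes are assembled under Hardy-Weinberg (optionally
  with an excess-homozygosity knob to stress-test estimator bias).
  Fast, carries the exact drift law `E[He_t] = He_0 (1 - 1/(2N))^t`,
  and is used for temporal-method and drift-decay validation.

Initial frequencies are uniform on [0.05, 0.95]; missingness is
applied uniformly at random at a configured rate (the missingness
mechanism of real reduced-representation data — coverage-dependent
dropout — is *not* emulated). Sampling is without replacement within
a deme; a mandatory seed makes outputs bit-reproducible.

**Capture-history generator.** Individuals receive sex, SVL and
per-occasion capture probabilities from the same logit-linear model
the CMR module fits (including optional date/individual random
effects and the previous-capture response); never-captured
individuals appear only in the returned truth record. Defaults mimic
the field design the package targets: daily occasions over a few
weeks, tens-to-hundreds of true individuals, capture probabilities of
order 0.1-0.4.

What passing tests on these generators do **not** show: robustness to
physically linked loci, to overlapping generations or age structure,
to non-random missingness, to heterogeneous trap placement, or to
temporary emigration — all of which real monitoring data can contain.

## Validation scale and numerical notes

Calibration tests run at sizes chosen to keep the full suite in the
minutes range while leaving Monte-Carlo error well inside the
asserted tolerances: 50 simulated capture datasets (N = 100, 10
occasions, p = 0.2, pool 300) for interval coverage; 20 replicates
each for LD-Ne (Ne = 50, S = 30, 200 loci, 15 generations of burn-in —
long enough for LD equilibrium, short enough that the allele-frequency
spectrum is not yet drift-distorted) and temporal Ne (Ne = 100,
t = 10, S = 50, 500 loci); 200 replicates for permutation-test type-I
calibration. The enumeration oracle for the CMR sampler integrates p
and psi analytically and sums over inclusion configurations — exact
for tiny pools, independent of the sampler code path.

Degenerate inputs are handled explicitly rather than silently: loci
with no calls are dropped from means; locus pairs with zero dosage
variance are excluded from r^2; temporal loci fixed in both samples
are skipped; permutations that destroy all polymorphism count as
non-exceedances; HPDI computation requires at least 20 draws; the
jackknife requires at least 5 individuals and skips leave-one-out
subsets that lose all usable pairs, with a warning.
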