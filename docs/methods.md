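# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Ages

Integer age is an opaque-zone count agreed by two otolith readers; only
agreeing fish enter clock construction. Fractional age is
`(zones·365 + days since the most recent March 15 on or before capture)/365`.
March 15 approximates the median birth date of a January–April spawning
peak. Day counts are real calendar differences, but the divisor is a fixed
365, so a fish captured the day before its birthday in a leap cycle can
reach fractional − integer = 365/365; we accept that rather than invent a
366-day rule the fractional-age convention does not define. Reader
precision is summarized by the Beamish–Fournier index of average percent
error (per fish, mean absolute deviation from the reader mean as a
percentage, averaged over fish) and intra-observer error (disagreement rate
between original and recount, averaged over readers).

## QC filters

Four filters run in a fixed order, each configurable
(`finclock.config.PipelineConfig` carries the published defaults):

1. sites that could not be genotyped in the untreated library portion, or
   whose pooled substitution fraction (substituted reads / untreated reads,
   summed across individuals) is strictly greater than 5%, are removed as
   apparent C/T (G/A) polymorphisms — at such sites the "unmethylated"
   signal can be genotype, not methylation;
2. individuals observed at fewer than `min_sites` CpG sites are removed
   (400,000 at sequencing scale; synthetic cohorts use a scaled value,
   since the threshold is a library-quality proxy, not a biological one);
3. sites observed in fewer than 80% of the remaining individuals are
   removed;
4. sites whose exact binomial 95% interval has width ≥ 0.85 in more than
   20% of observed individuals are removed. Width < 0.85 corresponds
   roughly to ≥ 16 reads, so this is a depth filter expressed on the
   uncertainty scale. We read the published "confidence intervals < 0.85"
   rule as a *width* bound: an upper-confidence-bound reading would delete
   every highly methylated site and contradict the ~80% global methylation
   such data show.

Clopper–Pearson intervals use beta quantiles:
`low = B(α/2; x, n−x+1)`, `high = B(1−α/2; x+1, n−x)`, with the endpoints
0 and 1 at x = 0 and x = n. The test suite checks them against an
independent numerical inversion of the binomial tail tests.

## Per-site age screen

For one site, each fish contributes a single binomial count, so the fish
random intercept in

    Meth_f ~ Binomial(Total_f, p_f),  logit(p_f) = β0 + β1·Age_f + u_f,
    u_f ~ N(0, σ²_Fish)

is an observation-level over-dispersion term. We therefore integrate u out
exactly (to quadrature precision) with 16-node Gauss–Hermite quadrature —
one 1-D integral per fish — leaving a three-parameter marginal posterior in
(β0, β1, log σ). Age is centred internally; priors are weakly informative:
Normal(0, 2.5) on the centred intercept, Normal(0, 2.5/sd(age)) on the
slope, Exponential(1) on σ. These reproduce the behaviour of standard
weakly-informative GLM defaults without tying the contract to a package.

Two engines share this posterior:

- **laplace** (default): MAP by Nelder–Mead + BFGS, a central-difference
  Hessian at the mode, and Wald-style 95% intervals. ~25 ms per site, used
  for genome-scale screens.
- **mcmc** (reference): univariate stepping-out slice sampling, 4
  independent chains × 4000 iterations with the first half discarded.
  Effective sample sizes and the Gelman–Rubin diagnostic come from arviz;
  a fit converges only if n_eff > 2000 and R-hat < 1.01 for every
  parameter. Slice sampling was chosen over random-walk Metropolis because
  its near-iid draws comfortably clear the n_eff gate at this chain length.

Significance = converged fit whose 95% interval for β1 excludes zero. The
two engines agree on significance for essentially all sites at depth ≈ 30
(the acceptance suite spot-checks this); disagreement is possible for
slopes sitting exactly at the interval boundary. Complete separation
(every observed fraction 0 or 1) returns a non-converged model rather than
raising. Fits are independent across sites and seeded per site id, so
screen output does not depend on site or execution order. No
multiple-testing correction is applied across sites (none is part of the
procedure); the flagged count is logged.

Fractional age drives the GLMM; integer age keys the imputation donors.
At flagged sites, cells with interval width > 0.85 are re-set to missing,
and every missing cell is imputed as the median observed value among fish
of the same integer age, falling back to the nearest age (ties pooled).

## Environment-signal removal

Water-body structure is tested with one-way PERMANOVA on Euclidean
distances of percent methylation: pseudo-F = (SS_between/(k−1)) /
(SS_within/(n−k)) computed from squared pairwise distances, p-value from
9999 random label permutations, `p = (#{F* ≥ F} + 1)/(n_perm + 1)`. When
the number of distinct label assignments does not exceed the permutation
budget the implementation switches to exhaustive enumeration and the
p-value is exact. Euclidean distance matches the PCA geometry used to
visualize the structure; percent methylation is already on a common [0, 1]
scale, so no per-site scaling is applied.

Removal proceeds iteratively on the cohort restricted to the two focal
water bodies: PCA → DAPC with the PC count chosen by 50 stratified 10%
holdouts per candidate (up to 300 PCs, truncated to the usable rank) → the
top 50% of sites by squared, back-projected discriminant-1 loading are
removed (ties broken by site id) → PERMANOVA re-test; the loop stops when
p > 0.05 or after 10 iterations. The discriminant is fit on the water-body
labels themselves rather than on K = 2 K-means clusters: when another
gradient (age, in any age-structured cohort) dominates total variance,
K-means splits along it and the discriminant would strip age sites instead
of environment sites. With two cleanly separated water bodies the K-means
clusters coincide with the labels, so the two choices agree exactly in the
regime the procedure was designed for; `kmeans_clusters` remains available
and tested. "No longer distinguishable" is operationalized as PERMANOVA
p > alpha, the same confirmation test the procedure ends with.

## Clock

Fish are partitioned 80/20 (|train| = round(0.8·n); 176 fish give
141/35), optionally stratified by integer-age bin with largest-remainder
allocation so rare ages appear on both sides. The top 1000 sites by
|Pearson r| between percent methylation and (raw) age in the training set
enter the search; age is then natural-log transformed, reflecting the
decelerating methylation drift seen in fish clocks and guaranteeing
positive predictions.

The subset search repeatedly samples 125 sites with replacement
(duplicates collapsed — a duplicated column is degenerate under a
penalty), and cross-validates an elastic net over α ∈ {0, 0.1, …, 1.0} and
a 100-value λ path from λ_max down to 10⁻⁴·λ_max, 10 folds. Selection
minimizes cross-validated MAE on back-transformed years (the scale the
error is reported on; ln-scale MAE is a config switch). One fold
assignment, drawn once per search, is shared by all iterations: subsets
then compete on the same splits, which removes the winner's-curse
component that fold re-randomization adds to the minimum — the same reason
cross-validating α uses common folds. Coordinate descent (scikit-learn's
`enet_path`) computes the paths; the α = 0 limb is an SVD ridge path,
matching the objective `(1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²)`.
Predictors are standardized within each fold and for the final refit;
coefficients are returned on the original percent-methylation scale.
Desk-scale default is 1,000 iterations (600,000 at study scale is a
configuration value, not a default).

Evaluation reports R² (squared Pearson correlation of predicted versus
otolith age; the 1 − SS_res/SS_tot identity-line variant is also computed),
MAE, MDAE, and an OLS of relative error (|error|/age) on age, whose slope
says whether the clock degrades or improves with age.

## Synthetic cohorts

`SyntheticConfig` defaults define the reference cohort used across the
tests: 150 fish, true ages uniform on 1–13 years, two water bodies of 75,
2,400 sites — 300 age-linear (|β1| ∈ [0.05, 0.3] logit/yr, random sign),
50 environment-linear (water-body offsets up to ±1.5 logit), 50
age-by-environment (per-water-body slope deviations up to ±0.15 logit/yr),
100 SNP-confounded (Hardy–Weinberg genotype offsets and untreated
substitution fractions > 5%), 1,900 neutral — negative-binomial depth
(mean 30, dispersion 8; over-dispersed reduced-representation coverage),
5% missing cells, fish random intercepts of 0.3 logit shared across sites,
and baseline log-odds centred at logit(0.8) so global methylation sits
near 80%. Age-site intercepts are re-centred at the mid age so methylation
stays in a realistic band across the age range. Capture dates and zone
counts are constructed to round-trip through the fractional-age rule to
within 1/365 year. Effect-size distributions are chosen for testability —
no published per-site distributions exist to emulate.

What the generator does **not** emulate: linkage between neighbouring CpGs
(sites are independent), sequencing error and conversion inefficiency,
age-dependent or environment-dependent missingness, batch/lane effects,
non-linear methylation trajectories, and reader disagreement (both
simulated readers agree). Passing tests therefore demonstrate that the
procedure recovers the structure it assumes, at realistic depth and noise —
not that real data satisfy those assumptions.

## Numerical choices and limitations

- All thresholds are strict/inclusive exactly as stated above (substitution
  "> 5%", presence "≥ 80%", width "< 0.85", masking "> 0.85").
- PCA components have a fixed sign (largest-|loading| entry positive);
  zero-variance sites are dropped before unit scaling, with a warning.
- LDA falls back to a ridge-regularized solver on singular within-class
  scatter (common when PCs approach the training-set size).
- Every stage derives its seed from the master seed and a stage label, so
  any artifact is reproducible from the manifest alone; per-site MCMC
  seeds derive from the site id, making results order-independent.
- The laplace engine's intervals are asymptotic; at very low depth or
  extreme methylation they can disagree with the MCMC interval near the
  significance boundary.
- The imputation pools *all* nearest-age donors on ties; with very sparse
  age coverage this can mix ages a year apart.
- `drop_low_coverage_individuals` counts sites after SNP/genotype removal,
  following the stated filter order; the count before removal would differ
  slightly.
- Runtime scaling in tests and the acceptance script (150 fish, 2,400
  sites, 200 subset-search iterations of size 50) is the package's chosen
  desk-scale reference; every one of those values is a config knob.
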