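# Methods

`dietmwas` implements a co-twin-control metabolome-wide association scan
(MWAS): food-group intakes from a food-frequency questionnaire (FFQ) are
tested against blood metabolite levels in a twin cohort, with monozygotic
(MZ) pairs discordant for an intake serving as a genetically matched
replication sample. This note records the statistical model, the choices
made where the design was open, what the synthetic cohort generator does and
does not emulate, and the numerical details a maintainer would need.

## The regression model

For metabolite level `Y_ij` of twin `j` in family `i`:

    Y_ij = b0 + beta * X_ij + gamma * age_ij + delta * BMI_ij
           + batch fixed effects + zeta_i + eps_ij

`X_ij` is the energy-adjusted food-group intake in servings/week; `zeta_i ~
N(0, sigma_f^2)` is a family random intercept capturing shared familial
(genetic and environmental) variance; `eps_ij ~ N(0, sigma_e^2)`. A single
family-level variance component is used; the MZ/DZ difference in residual
sharing is deliberately not modelled (the co-twin information enters through
the discordance design, not the covariance structure). Batch (run day)
enters as categorical fixed effects with the lexicographically first level
as reference.

### Fitting

Because the marginal covariance is block compound-symmetric, the REML
problem profiles down to a one-dimensional search over the variance ratio
`lam = sigma_f^2 / sigma_e^2`: for each `lam`, `(I_k + lam J_k)^{-1} = I_k -
lam/(1+k lam) J_k` per family of size `k`, so the GLS normal equations and
the REML criterion reduce to per-family sums. The criterion

    sum_f log(1 + k_f lam) + log det(X' W X) + (n - p) log(r' W r)

is minimised by bounded scalar search over `log10(lam)` on [-8, 6]
(xatol 1e-10), with the `lam = 0` boundary checked explicitly — at the
boundary the fit is exactly ordinary least squares, so estimates are
continuous as the family variance estimate reaches zero. A perfect fit
(`r'Wr ~ 0` at `lam = 0`) short-circuits to OLS with zero variances. This
solver runs a fit in ~1–3 ms, which is what makes the simulation-based
calibration suites (tens of thousands of fits) affordable; it is validated
in the test suite against statsmodels `MixedLM` (betas and variance
components to ~1e-6) and against a brute-force profile-likelihood grid
search (betas to <=1e-4 relative).

### Inference

Fixed-effect standard errors are the plug-in GLS covariance
`sigma_e^2 (X'WX)^{-1}`. Wald statistics are referred to a t distribution
with `n - p` degrees of freedom rather than the normal: identical at cohort
scale (thousands of subjects), but materially better calibrated in the
extreme tails at a few hundred observations, where a Bonferroni threshold
of ~1e-6 lives. The plug-in SE still ignores variance-component estimation
noise (no Kenward–Roger correction); empirically this leaves the per-test
type-I rate at the Bonferroni tail within ~10–20% of nominal at 500
observations and shrinking with n — the calibration suites therefore run at
500 pairs per scan. Degenerate designs (constant or collinear columns) are
rejected naming the offending column. Listwise deletion is applied per fit.

## Preprocessing

Non-targeted (relative-intensity) panels: (1) run-day median normalization —
each value divided by the median of that metabolite among samples processed
the same day, removing multiplicative batch drift; (2) missingness filter —
metabolites missing in *strictly more than* 20% of samples are excluded
(exactly 20% is retained; the rule is a strict inequality); (3) run-day
minimum imputation — each missing cell takes the minimum observed value of
that metabolite on that sample's run day, consistent with missingness being
dominated by low-abundance censoring; a run day with no observed value for
a metabolite falls back to the metabolite's global minimum (a convention for
degenerate days); (4) Blom rank-based inverse-normal transform, computed per
metabolite across all samples: `Phi^{-1}((r - 0.375)/(n + 0.25))` with
average ranks for ties (the transform is undefined for a constant vector
and rejected). Applying the transform across all samples rather than within
run day is a convention; normalization has already removed the day medians.

Targeted (absolute mM) panels: natural log (the concentrations are
right-skewed), then removal of metabolites that duplicate the non-targeted
platform; the overlap list is an input, absent ids are warned about rather
than silently ignored. No run-day normalization is applied to targeted data,
and the processing-state list on each panel enforces the chain order on both
platforms.

## Diet variables

FFQ items carry 9-point frequency codes from "never or less than once per
month" to "6+ per day". The default code-to-servings/week map uses category
midpoints (0, 0.5, 1, 3, 5.5, 7, 17.5, 31.5, 45); it is configurable since
instruments differ, and it must be non-decreasing. Items are summed into
food groups via a many-to-one map, then energy-adjusted by the residual
method: each group intake is replaced by its residual from least-squares
regression on total energy (kcal/day), re-centred on the group mean so units
and location are preserved. The adjusted intake has exactly the input mean,
never larger variance, and zero sample correlation with energy. Adjustment
defaults to the food-group level (effect sizes are interpreted per group);
item-level adjustment before aggregation is available via `adjust_order`
since the convention varies between studies.

## Discordance partition and the two-stage scan

Per food group, the sample SD (ddof=1) of the adjusted intake is computed
over all subjects with an observed value. A complete MZ pair whose absolute
within-pair difference is >= 1 SD (ties discordant; multiplier configurable)
goes to replication; everyone else — DZ pairs, concordant MZ pairs,
singletons, and twins whose co-twin intake is missing — forms the discovery
sample. Discovery fits are Bonferroni-corrected over all tested (food group
x metabolite) pairs across both platforms; a fixed external denominator
(e.g. the published 71 x 601 = 42 671, giving 1.17e-6) can be substituted.
Replication refits significant pairs on the discordant-MZ sample; a pair
replicates when the sign matches discovery and — non-targeted platform only
— the replication p-value is below 5% (two-sided; the direction criterion is
separate, so the 5% level is read two-sided). Replication samples under 10
subjects are marked unreplicable with the reason, never dropped. The two
estimates are combined by inverse-variance fixed-effect meta-analysis
(weights `1/SE^2`; meta p from the normal tail of beta/SE, consistent with
the weighting), which is the reported result. Fit failures anywhere in a
scan are collected as error-carrying records; the scan continues.

## SNP follow-up

For a curated list of (SNP, food group) pairs, intake is regressed on the
additive dosage (0/1/2) with age and a family random intercept — a random
intercept is used for consistency with the main model, since "adjusted for
family relatedness" admits either a fixed or random formulation. MZ co-twins
must carry identical dosages; a violation is a data error, not a warning.
Both nominal (p < 0.05) and Bonferroni (p < 0.05 / n tests; 4.76e-4 at the
published 105 tests) flags are reported, one record per listed pair
including explicit failure markers.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth. Female twin pairs share age exactly; BMI is drawn per
subject around a pair mean (half the variance shared). FFQ item codes are
iid uniform over the 9 categories; total energy is an affine function of
total reported servings plus noise, so energy adjustment is non-trivial.
Metabolite signals are built on the *energy-adjusted* food-group matrix
produced by the package's own diet chain, so planted slopes are exactly the
coefficients the downstream model estimates (noise-free recovery is exact by
construction). Family structure: per (family, metabolite) random intercepts
with variance `var_family`, plus `var_pair_mz_extra` shared only within MZ
pairs, so MZ within-pair correlation exceeds DZ. The non-targeted panel
multiplies the linear signal by per-(run day, metabolite) log-normal batch
factors and then masks values missing with probability weighted 1.8 : 0.9 :
0.3 across intensity tertiles (expected fraction = the configured rate; the
left-censoring pattern is what makes minimum imputation sensible). The
targeted panel exponentiates its signal, giving right-skewed log-normal
concentrations for which the log transform is exact. Genotypes: per-SNP
allele frequency uniform on [0.1, 0.5]; MZ pairs share both allele draws, DZ
pairs share one. Run-day assignment is round-robin over subjects —
deterministic and seed-independent, so batch structure is balanced.

Defaults mirror the cohort the design targets: 1780 pairs (~3560 women), 71
food groups from ~131 items (2 items/group here), 456 non-targeted and 145
targeted metabolites. Values the source data leave open are fixed
conventions chosen once: MZ fraction 0.5, 20 run days, variance components
(0.3 family, 0.2 MZ-extra, 0.5 residual — MZ intraclass correlation 0.5 vs
DZ 0.3, reflecting substantial but incomplete familial control of metabolite
levels), missingness rate 0.10, batch shift SD 0.10, ages uniform on 18–75,
BMI 25 +/- 4.5. The targeted panel is generated for all subjects; a
targeted-subset design can be emulated by subsetting. Identical parameters
including the seed reproduce every table bit for bit.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: correlated food intakes (real FFQ groups are
strongly inter-correlated, a documented source of mutually confounded
associations), categorical coarseness interacting with true continuous
intake, metabolite–metabolite correlation beyond the shared family effect,
non-Gaussian residuals, sample-type (serum/plasma) differences, time lag
between questionnaire and blood draw, and any genotype→metabolite effects
(the SNP list is treated as an external input, and simulated genotypes are
independent of simulated diet, so the SNP scan is null by construction).

## Problem sizes used in the validation suites

Simulation-based checks run at deliberately reduced dimension: type-I error
of a single discovery fit over 200 null replicates at 250 pairs; family-wise
error of the full Bonferroni scan over 200 all-null scans of 10 food groups
x 20 metabolites at 500 pairs; parameter recovery (planted slope 0.1) over
100 cohorts of 500 pairs; end-to-end detection with three planted effects in
a 500-pair cohort. Calibration assertions use exact binomial bands (central
95% band for the type-I rate; one-sided binomial test for family-wise
control), since a point match to alpha over 200 Bernoulli trials is not a
meaningful requirement.

## Known limitations

- Plug-in Wald SEs without Kenward–Roger/Satterthwaite corrections: mild
  anticonservatism in extreme tails for small samples (quantified above).
- The meta-analysis treats discovery and replication as independent; they
  are disjoint subject sets, but both depend on the same per-food-group SD
  estimate.
- Discordance is assessed per food group on the adjusted intake of the full
  analysis sample; alternatives (raw intake, post-exclusion SD) are not
  implemented.
- The pipeline is single-time-point; longitudinal stability of markers is
  out of scope.
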