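# Methods

## The classical twin design

A phenotype measured on twin pairs is decomposed into additive genetic
(A), shared environmental (C) and non-shared environmental (E) variance.
The design rests on the known coefficients of relatedness: monozygotic
(MZ) co-twins share all segregating genes, dizygotic (DZ) co-twins half
on average, and both kinds of pair share their rearing environment.
Writing a, c, e for the (nonnegative) path coefficients, the expected
within-pair covariance in zygosity group *g* is

    cov_g = gamma_g * a^2 + c^2,      gamma = 1 (MZ), 0.5 (DZ)

and the phenotypic variance is `a^2 + c^2 + e^2`. All results are
reported as standardized proportions `a2 = a^2 / (a^2+c^2+e^2)` etc.,
which by construction lie in [0, 1] and sum to 1.

Two estimators are implemented:

* **Falconer's moment estimator** — `a2 = 2 (rMZ - rDZ)`,
  `c2 = rMZ - a2`, `e2 = 1 - rMZ`. Out-of-range values are returned
  unmodified with a flag rather than truncated, because silently clipped
  estimates hide model misfit (e.g. `rDZ < rMZ/2` suggests dominance or
  sibling contrast effects, which this package deliberately does not
  model).
* **Maximum likelihood** (`ace_continuous.fit_ace_ml`) — per-group
  bivariate-normal likelihood with a common mean and total variance,
  evaluated from sufficient statistics (per-group counts, sums, sums of
  squares and cross-products), so the cost of one likelihood evaluation
  is independent of cohort size. Optimization is L-BFGS-B on
  `(mu, a, c, e)` with nonnegativity bounds, from 5 deterministic starting
  points spanning the (a2, c2) simplex; ties are broken toward the
  lowest a2 for reproducibility. Opposite-sex DZ pairs pool with
  same-sex DZ pairs at gamma = 0.5 in combined-sex fits.

Confidence intervals are profile-likelihood intervals: the component of
interest is fixed at a trial value, the remaining parameters
(re-parameterized as total variance plus a split fraction of the
complement) are re-optimized, and the 95% bound is found by bisection on
`2 (ll_max - ll_profile) = 3.84`. Profile intervals respect the [0, 1]
boundary, unlike Wald intervals, which matters whenever c2 is near 0.

Likelihood-ratio tests of nested models report both the naive
chi-square p-value and a boundary-corrected one: dropping a variance
component pins it at the boundary of its parameter space, so the null
distribution of the LRT statistic is the 50:50 mixture of chi-square(df)
and chi-square(df-1), not chi-square(df). The calibration of this
mixture test is verified by simulation in the test suite.

## Binary traits: liability threshold model

A binary choice is modelled as the indicator that a standard-normal
latent liability exceeds a threshold *t* (the upper-K quantile for
prevalence K). Pair liabilities are bivariate normal with correlation
`gamma * a2 + c2`; the four concordance-cell probabilities are orthant
masses of that distribution, and the fit maximizes the joint multinomial
likelihood over all groups' 2x2 tables in `(t, a2, c2)` (SLSQP with the
simplex constraint). The threshold is equated across zygosity groups —
zygosity should not shift prevalence — and across sexes in combined
analyses; the five-group sex-limitation model frees per-sex thresholds.

Orthant probabilities use the single-integral identity

    P(X > h, Y > k) = Phi(-h) Phi(-k)
        + (1/2pi) * Int_0^{asin r} exp(-(h^2 - 2hk sin u + k^2) / (2 cos^2 u)) du

with 64-node Gauss–Legendre quadrature. The integrand is analytic on a
bounded interval, so the absolute error is far below the 1e-8 target;
the test suite cross-checks against an independent bivariate-normal CDF
implementation and against the arcsine closed form at median thresholds.

The **tetrachoric correlation** of a single table is the ML inversion of
the same machinery over `(r, t1, t2)`, optimized on the Fisher-z scale
for r so the search never leaves (-1, 1); a fit driven to |r| = 1 (no
discordant pairs) is flagged as a boundary solution. Zero cells need no
continuity correction: the likelihood stays finite while margins are
positive.

**Probandwise concordance** `2 n11 / (2 n11 + n10 + n01)` is reported
descriptively alongside the model fits.

## Five-group sex-limitation model

With MZm, MZf, DZm, DZf and DZos groups, quantitative sex differences
(same factors, different magnitudes) appear as sex-specific paths, and
qualitative differences (partially different factors) appear through the
DZos cross-twin covariance `0.5 * rg * a_m * a_f + rc * c_m * c_f`.
`rg` and `rc` cannot be freed jointly from twin data alone; by default
the model frees `rg` with `rc = 1` (shared environment assumed fully
shared across sexes), and the alternative — free `rc` with `rg = 0.5` —
is a spec option. The constrained values follow the standard
convention: the DZos genetic correlation is fixed at 0.5 and the shared
environmental correlation at 1.0.

The nested chain is

1. *full* — sex-specific means, variances and paths; one free cross-sex
   correlation;
2. *qualitative_constrained* — the cross-sex correlation fixed at its
   expected value;
3. *quantitative_equal* — male and female paths equated;
4. *homogeneous* — means (and, for liability fits, thresholds) equated
   too.

Each restriction is an interior equality constraint, so LRTs along the
chain use plain chi-square reference distributions. The same chain is
available for binary traits on the liability scale (per-sex thresholds,
proportions parameterization). Opposite-sex pairs are oriented
male-first internally; analyses orient by the sex column, not by twin
index.

## Preprocessing

Achievement scores are (1) regressed on age and sex by OLS across all
individuals — age is pair-constant and sex is pair-constant outside DZos
pairs, so uncorrected mean effects would masquerade as shared
environment — with residuals standardized to SD 1; (2) normalized by the
rank-based van der Waerden transform, rank r of n mapping to the
standard-normal quantile at r/(n+1), ties receiving their average rank;
(3) re-standardized. Standardization happens within the analysis sample
actually fitted (the chooser subset for achievement traits). Missing
values pass through every step unchanged. An exact regression fit
(zero residual variance) short-circuits to zeros rather than amplifying
numerical dust.

## Descriptive statistics

Twins are not independent observations, so descriptives use one
uniformly selected twin per pair under a caller-supplied seed. The
sex-difference test for a choice trait is the Pearson chi-square on the
2x2 sex-by-choice table without continuity correction. The grade ANOVA
is a two-factor fixed-effects model (sex, zygosity, interaction) with
sequential type-I sums of squares, reporting
`R^2 = (SS_sex + SS_zyg + SS_int) / SS_total`. Zygosity enters as MZ
versus DZ: with one twin per pair the five-group labels are
sex-determined (MZm contains only males), so the five-group-by-sex
crossing is structurally empty.

## The synthetic cohort generator

The generator is the package's test bed and stands in for restricted
individual-level data. Per pair it draws latent A, C, E components with
the cross-twin correlations the model assumes (A: 1 / 0.5 / `0.5 rg`;
C: 1 / 1 / `rc`; E: independent), combines them with per-sex path
coefficients, and thresholds the liability at the configured prevalence
for binary traits. Defaults mirror the emulated study: 6584 pairs
(2318 MZ, 2146 DZ same-sex, 2120 DZ opposite-sex; same-sex groups split
evenly by sex, which the source tables do not pin down exactly), choice
prevalence 0.5, choice liability components (0.44, 0.47, 0.09),
achievement components (0.59, 0.07, 0.34), grades centred at 3.90 with
SD 1.16 on the 1-6 scale. A single seeded generator drives each run, so
fixed seeds give bit-identical cohorts.

Selection into achievement is the choice itself: grades exist exactly
for choosers. The achievement liability shares each latent component
with the choice liability with mixing weight `choice_grade_overlap`
(default 0.5, giving corr(grade, choice liability) ~ 0.43). This keeps
the marginal ACE proportions of both traits exactly at their configured
values — the mixture of two standard-normal latents with the same
cross-twin correlation is again standard normal with that correlation —
while making the chooser subset genetically non-random, which is the
point of modelling self-selection. The induced double-truncation bias
on recovered achievement components is below 0.04 at the default
settings.

Grades default to the continuous clipped scale
(`mean + sd * liability`, clipped to [1, 6]) because the emulated
default trait is a mean-grade composite, which is fractional in real
data; `grade_discretize="integer"` rounds to whole grades for
single-subject traits. Integer rounding of a 6-level scale attenuates
within-pair correlations by roughly 6%, which is a real feature of
single-subject analyses and is therefore opt-in rather than silently
baked into the composite default.

What the generator does **not** emulate: assortative mating, dominance,
gene-environment interaction or correlation beyond the selection
mechanism, sibling contrast effects, measurement error structure
(beyond E), item-level grade construction, or cohort non-response.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to their violation in real
cohorts.

## Numerical choices

* BVN orthants: 64-node Gauss–Legendre after the arcsine substitution;
  exact limits used for |r| within 1e-15 of 1.
* Tetrachoric ML: Nelder-Mead on `(z, t1, t2)` with `r = tanh(z)`
  clamped to |z| <= 12; boundary flag at |r| >= 1 - 1e-6; three z-starts
  around Pearson's cosine approximation.
* Continuous ML: L-BFGS-B, `ftol = 1e-12`; cell probabilities floored at
  1e-300 before logs in all multinomial likelihoods.
* Profile CI bisection: 30-40 iterations or width < 5e-4.
* Degenerate inputs: tables with an all-zero margin, constant phenotype
  vectors, prevalence 0 or 1, and missing DZos groups in sex-limitation
  fits are rejected with specific exceptions before any optimization.

## Problem sizes used in validation

The test suite validates recovery at 5000+5000 pairs (continuous,
tolerance ±0.03), 3000+3000 pairs (liability, ±0.07), profile-CI
coverage over 300 cohorts of 500+500 pairs, LRT calibration over 400
replicates of the same size, and end-to-end recovery at the full
6584-pair study shape. Where a tolerance is of the same order as one
cohort's sampling SD (the ML-vs-Falconer ±0.02 band; the end-to-end
±0.07 bands), the property is asserted on the mean over 6-8 independent
replicate cohorts at the stated size, because a single draw would test
the seed rather than the estimator; determinism under a fixed seed is
asserted separately.

## Known limitations

* No dominance (ADE) or common-effects sex-limitation variants; the
  model space is ACE and its submodels.
* Complete pairs only; singleton twins are excluded rather than handled
  by marginal likelihood.
* Binary traits are strictly dichotomous; no multi-threshold ordinal
  support.
* The liability fit consumes collapsed 2x2 tables, which is fully
  efficient only under the equal-threshold assumption it makes.
* Profile CIs assume the chi-square(1) calibration of the likelihood
  ratio, which degrades for components estimated on the [0, 1] boundary;
  boundary cases are flagged but their intervals are conservative.
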