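# Methods

## Reference distributions

Each metabolite/sex stratum is modelled with the LMS approach: the
age-varying distribution of a positive concentration is parameterized by a
Box-Cox power `L(t)` (identity link), a median `M(t)` and a coefficient of
variation `S(t)` (both log link, so positivity is structural), with age `t`
in years on [0.25, 18]. Under BCCG the transformed score is referred to a
standard normal truncated to the invertible region of the transform; the
truncation constant `Φ(1/(S·|L|))` is carried exactly in the log-density so
that quadrature closes to 1 and likelihood comparisons between parameter
values are exact. The BCT family substitutes a Student-t kernel with
constant degrees of freedom `τ > 0` (log link), adding a kurtosis
adjustment; `τ` is not age-varying — tail weight is poorly identified
locally at realistic stratum sizes, and a constant keeps the four-parameter
model estimable. Below `|L| < 1e-5` all formulas switch to the exact `L = 0`
log-branch to avoid catastrophic cancellation.

`M` is the distribution median (the standard LMS convention), even though
the expansion is sometimes read as a mean; percentile curves and SDS values
are defined relative to the median.

## Curve estimation

Curves live on cubic B-spline bases over `u = √age`; the square-root axis
gives infancy, where concentrations change fastest, proportionally more
resolution. Smoothness is controlled by the basis dimension (df): df = 1 is
a constant, df = 2 linear in `u`, df ≥ 4 cubic with equally spaced interior
knots. All spline coefficients are estimated jointly by maximizing the full
log-likelihood (L-BFGS-B, numerical gradients, up to two deterministic
restarts from a jittered start on failure). There is no separate roughness
penalty: the df grid is the smoothness control, and the df combination is
chosen by BIC — BIC rather than AIC where they disagree, favouring
parsimony; both are reported. Default grids: M ∈ {2,3,4,5}, L and S ∈
{1,2,3}, τ constant. Initialization is deterministic: `log M` from a
least-squares fit to a rolling median, `S` from the residual spread of
`log y`, `L = 1`, `τ = 10`. Candidate models are visited in order of
increasing total df and warm-started by projecting the best previous curves
onto the new basis. A fit whose optimizer does not converge is flagged, not
silently returned; fits are deterministic given data and settings.

Distribution choice: BCT is adopted only when its BIC is strictly below
BCCG's (ties go to the three-parameter family).

## Clustered cohorts: resampling

Annual repeat visits and sibling pairs make the iid likelihood wrong for a
full cohort. `fit_reference_resampled` draws, per iteration, one observation
uniformly at random per *family* (which simultaneously breaks subject- and
sibling-level dependence), refits at the df combination selected once on the
full data, and evaluates L, M, S on a fixed 101-point age grid. The final
curves are the pointwise median across iterations, re-smoothed onto the
basis by least squares on the link scale — medians are robust to occasional
poor iterations. Iterations that fail to converge are dropped and counted;
more than 20% dropped fails the operation. Default 100 iterations. With one
observation per family the procedure reproduces the plain fit exactly.

## SDS scoring and diagnostics

SDS is the Cole-Green z at the visit's age; for BCT references the
t-referenced z is mapped through the probability integral transform
`Φ⁻¹(T_τ(z))`, so SDS values are standard-normal-scaled for both families
and comparable across metabolites. No extrapolation outside the fitted age
range. Residual diagnostics report mean, SD, skewness, excess kurtosis and
a QQ deviation statistic. The deviation is computed on the probability
scale — the supremum over a fixed grid of `|ECDF − p|`, i.e. a gridded
Kolmogorov-Smirnov statistic — because that is the scale on which an
n-dependent KS critical value is meaningful; summaries from fewer than 20
residuals are flagged unreliable.

## Quality control

Two rules, each applied once, per metabolite, across the whole cohort
(unstratified — the exclusion decision should not depend on sex or age
composition):

* LOD: excluded iff strictly more than 5% of values are below the detection
  limit; zeros always count as non-detects. The boundary case (exactly 5%)
  retains — equality matters and is tested explicitly.
* Outliers: nonzero values further than 5 SD from the mean of the natural
  log of the nonzero values are removed. The mask is invariant to the log
  base (mean and SD rescale together). Zeros survive this rule — they are
  non-detects, not biological outliers — and are excluded from modelling
  separately because the transform requires y > 0. The rule is not
  idempotent by construction; the pipeline applies it exactly once.

## Association analyses

All tests are Gaussian models with a subject-level random intercept
(family clustering is handled only in reference fitting; the association
layer adjusts for repeated measurements per subject). The single-random-
effect REML problem has a one-dimensional profile: with variance ratio
`λ = σ_u²/σ_e²`, the GLS solution, residual variance and REML deviance are
closed-form in group sums, and `λ` is found by bounded scalar minimization
over `log λ ∈ [−12, 12]` with the `λ = 0` boundary checked explicitly. This
is exact (it matches iterative mixed-model solvers to numerical tolerance)
and fast enough for the calibration simulations the test-suite runs.
Coefficients are standardized (response and continuous covariates z-scaled)
so that marker "correlations" are per-SD; inference is Wald with normal
reference — adequate at the cohort sizes the analyses target, with no
small-sample (Kenward-Roger-type) correction. Degenerate cases fall back
deliberately: a single group, or a numerically perfect fit (variance
decomposition unidentifiable), returns the OLS solution with a warning
flag; rank-deficient designs are rejected naming the collinear columns.

* Age-interval trends: SDS regressed on age within half-open intervals
  `[a, b)` (boundary ages join the right interval; the last interval is
  closed above). Default cuts {1, 5, 9, 13} years, motivated by where the
  canonical age profiles change direction; fully configurable. Intervals
  with fewer than 30 usable observations are reported not-estimable.
* BMI: `sds ~ bmi + sex + bmi×sex`; if the BY-adjusted interaction is
  significant at 5% the slope is re-estimated and reported per sex,
  otherwise one pooled (sex-adjusted) slope.
* Tanner stage: categorical with stage 1 (pre-pubertal) as reference,
  stratified by sex; stages with no observations are not-estimable.
* Marker matrices: each cell is the standardized coefficient of one marker
  from a random-intercept model (clipped to [−1, 1]), not a raw Pearson r,
  in `absolute` or `sds` (age/sex-adjusted) mode. Metabolite rows are
  clustered by agglomerative clustering (Euclidean distance on the
  correlation-profile rows, average linkage, k default 5); labels are
  canonicalized by first occurrence so the partition is permutation-stable.

Multiplicity: Benjamini-Yekutieli step-up (`p_adj(i) = min_{j≥i}
min(1, m·c(m)·p_(j)/j)`, `c(m) = Σ 1/h`), valid under arbitrary dependence.
Families are per analysis block — all BMI interaction tests together, all
reported BMI slopes together, all Tanner contrasts per call, all cells per
matrix; the block boundaries are a design choice, recorded here because the
adjusted values depend on them. Significance always uses adjusted p < 0.05.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, at the
emulated study's scale by default: 2191 subjects, mean 1.82 visits/subject
(~3989 visits), ages 0.25-18, ~50% female, 20% of subjects in sibling
families (pairs, one triple if odd). The 30-metabolite panel carries four
canonical age-profile shapes — (1) infancy peak, minimum at ~2-5 y, then
stable/rising; (2) monotone increase; (3) rise then plateau; (4) flat — as
log-median shapes on the transformed age axis (polynomial for types 1, 2
and 4, hence exactly representable in the fitting basis; a smoothstep for
type 3), with constant L = 0.4, S = 0.15, a +6% male median shift, and BCT
(τ = 6) for Asp, Met and Tau. Base concentrations are field-plausible
medians in µmol/L; no attempt is made to match any real cohort's exact
marginals.

Values are drawn by sampling a z-score and inverting the transform.
Within-subject dependence enters on the z-scale as a subject-level latent
with intraclass correlation 0.4 (a free parameter — the magnitude of the
within/between split is not observable from published summaries); a
z-scale shift keeps the marginal percentiles correct in expectation. BCT
marginals are produced through a Gaussian copula so they are exactly
Student-t while preserving the within-subject correlation structure.
Injected covariate effects (BMI slopes per sex, Tanner stage/sex shifts)
act additively on the z-scale. Tanner stage is a cumulative-ordinal model
in age with sex-specific onsets (girls ~1 year earlier) and a per-subject
timing latent, so stage is non-decreasing within subject; below age 8 the
stage is recorded missing (not assessed). Laboratory markers are linear
combinations of metabolite SDS values plus optional standardized-age
components and noise topped up to unit variance, so each loading is the
marker's target correlation with that metabolite's SDS; kidney markers
carry broad positive loadings and an age component (an age-confounded
marker, visible as attenuation between absolute and SDS correlation modes).
Degradation injects non-detects (below-LOD values and random censoring,
sentinel 0) and rare extreme outliers (multiplicative factor ≥ e⁶, far
beyond the 5-SD log cutoff). Everything is reproducible from a single seed.

What the generator does *not* emulate: analytical batch effects (the
emulated workflow could not adjust for them either), assay imprecision as a
separate variance component, metabolite-metabolite correlations beyond
those induced by shared marker structure, dropout/attrition patterns, and
real marginal concentration scales. Passing tests therefore demonstrate
statistical correctness of the estimators under the assumed data-generating
structure, not clinical validity of any particular reference table.

## Problem sizes and numerical choices

The test-suite and acceptance script run the calibration studies at sizes
chosen to put the asymptotic Wald inference in its valid regime while
remaining desk-scale: coverage protocols use ~4000 observations per sex
(fit) and the same held out; FDR control uses 200 replicates of 500 tests;
type-I calibration uses 300 subjects × 2 visits × 2000 replicates;
power/recovery simulations use 50 seeds. Percentile tables default to the
2.5/10/50/90/97.5 levels. Ties and degenerate inputs are resolved
explicitly: BIC ties prefer BCCG; zero log-SD drops nothing; equal-BIC df
candidates resolve to the first (smallest) visited.

## Known limitations

* Wald inference is anti-conservative for very small groups (dozens of
  subjects per stratum); no small-sample correction is provided.
* No extrapolation below 0.25 or above 18 years, by design.
* τ is constant in age; strongly age-varying kurtosis would be absorbed
  into L and S instead.
* The resampling aggregation (pointwise median, df fixed from the full-data
  fit) is one reasonable realization of cluster-aware LMS fitting; other
  schemes (per-iteration df selection, mean aggregation) would differ in
  detail.
* Marker SDS conversion without external reference tables fits references
  internally from the cohort itself, which is circular for markers whose
  age trend is of scientific interest; supply external LMS tables where
  available (the run log flags which source was used).
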