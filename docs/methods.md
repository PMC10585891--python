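# Methods

## Model and identifiability

Event counts `y` on an A×P Lexis grid (equal age/period interval width
`w`, cohorts on the C = A+P−1 diagonals, `c = p − a + A`, oldest cohort
first) are modelled as independent Poisson with rate offset
person-years. The linear predictor uses the extended APC
parameterization: intercept `μ` at the grid center, a centered age-index
slope, a centered cohort-index slope, and detrended deviation contrasts
on each axis (the period linear term is dropped). Under this choice the
age coefficient is the **longitudinal age trend** `τ_L`, the cohort
coefficient is the **net drift** `τ_D`, and the **cross-sectional age
trend** is the difference `τ_X = τ_L − τ_D`; the individual linear age,
period and cohort effects remain non-estimable and are never reported.
The free-parameter count is always `2(A+P−2)` per stratum.

Deviation contrasts are built by QR-orthonormalizing the polynomial
Vandermonde basis of the axis index and dropping the constant and linear
columns, so every reconstructed deviation curve sums to zero and has
zero least-squares linear trend. Estimable functions are invariant to
the particular basis spanning this subspace (tested by refitting under a
randomly sheared basis).

Fitting is by iteratively reweighted least squares through
`statsmodels.GLM` with a log person-years offset (deviance-change
convergence 1e-10, 100 iterations max); the covariance is the inverse
Fisher information at the MLE. Degenerate inputs (all-zero counts,
non-finite estimates from structurally empty rows) raise a convergence
error rather than returning garbage. Fits on noiseless expected-count
tables are exact to solver tolerance and are used throughout the tests
as closure checks.

## Estimable functions

With references `(a_ref, p_ref, c_ref)` defaulting to the central index
`ceil((L+1)/2)` of each axis (user-overridable):

* LongAge(a): fitted rates along the reference cohort, adjusted for
  period deviations; CrossAge(a): fitted rates in the reference period,
  adjusted for cohort deviations; FTT(p) and FCP(c): fitted rates over
  period/cohort at the reference age, adjusted for cohort/period
  deviations respectively.
* Ratio curves CRR, PRR, CARR, LARR are their parent curves minus the
  parent's reference value (log scale); the intercept cross-links
  `FTT(p_ref) = CrossAge(a_ref)` and `FCP(c_ref) = LongAge(a_ref)` hold
  exactly, which is what makes the four decompositions of the fitted
  surface — (LongAge, CRR, π̃), (FTT, CARR, γ̃), (FCP, LARR, π̃),
  (CrossAge, PRR, γ̃) — reproduce the fitted log rates cellwise.
* LongAge/CrossAge diverge log-linearly at exactly the net-drift slope;
  the curves additionally carry a common additive constant given by the
  reference-point deviation adjustments, which vanishes on fixtures with
  zero deviations and always cancels in cross-stratum ratios (the
  comparisons the constrained models interpret).
* Local drifts: for age `a`, the least-squares slope of the width-P
  window of cohort deviations observed at that age
  (`γ̃(A−a+1) … γ̃(A−a+P)`), added to the net drift and reported as
  annual percent change `100(exp(b/w) − 1)`.
* Gradient shifts: the analogous period-indexed quantity — for each
  period, the least-squares slope with respect to age of the cohort
  deviations cross-secting that period, added to the cross-sectional age
  trend and reported as percent per year of age. This definition (the
  cross-sectional mirror of the local drifts) is the one this package
  adopts; the quantity is displayed but not formally defined in parts of
  the surrounding literature.

All EF are linear in the parameter vector; covariances follow by the
delta method and intervals are Wald 95% on the log scale, exponentiated
for reporting.

## Constrained multi-stratum models

A sharing map pools chosen parameter blocks across strata in one stacked
Poisson regression (intercepts always per-stratum). The linear block can
be parameterized as (τ_L, τ_D) or, swapping the cohort column for a
period column, as (τ_X, τ_D); the spanned space is identical, but
sharing the first coefficient pools a different estimable trend — this
is how PH-X (shared cross-sectional trend) and Par-CAC are expressed.
The two classical routes to PH-T (proportional FTTs with equal cohort
deviations; proportional FCPs with equal period deviations) reduce to
the same sharing map here and are additionally verified to give
identical fits under either linear parameterization.

Model degrees of freedom follow mechanically from the map (e.g. N-PH:
`2G(A+P−2)`; PH-A: `2(A+P−2)+(G−1)`), and every map collapses to the
single-stratum model at G = 1. Constrained fits at G = 1 are permitted
for that reason rather than rejected. Fitted CH-RRs are returned in the
model's natural shape — scalar (PH-A), age curve (PH-T), period curve
(PH-X), cohort curve (PH-L), full grid otherwise — with delta-method
CIs.

Each constrained model is screened against N-PH by a single
likelihood-ratio test on the parameter-count difference; the P-values
are descriptive (no multiplicity adjustment) and selection is by AICc
with sample size `n = G·A·P` cells. The log-likelihood keeps the full
Poisson constant; it cancels in AICc differences.

## Multiplex partition search

Non-empty subsets are enumerated by size then lexicographically;
partitions by restricted-growth strings in lexicographic order, blocks
ordered by smallest member, with a B×N correspondence matrix recording
the order of occurrence of each subset in each partition. Non-singleton
subsets are fitted under {PH-L, PH-T, PH-X, PH-A, N-PH} and cached with
the subset-level AICc winner; singletons get the unconstrained
single-stratum fit (no proportionality is definable for one stratum).
Partition scores recompute AICc from the summed block log-likelihoods
and parameter counts at `n = G·A·P` — the small-sample correction is not
additive across blocks, so per-block AICc values are never summed. Ties
break to the lowest canonical partition index and are flagged.
Enumeration is capped at G = 12 (Bell(12) = 4,213,597); the search is
practical for roughly 2–8 strata. Results are cache-assembled and
independent of evaluation order.

## Synthetic data

The generator produces expected counts `exp(η)·T` from user-chosen
parameters under any regime, or a partition of strata with a regime per
block, enforcing the regime's sharing pattern at configuration time
(e.g. a PH-T scenario cannot carry stratum-specific cohort deviations).
Deviation shapes (named quadratic/sinusoid forms or explicit curves) are
projected onto the detrended subspace before use, so the truth lies
exactly in the identifiable model space and noiseless fit recovery is
exact. Noise is cellwise-independent Poisson (or gamma-Poisson with a
specified Pearson dispersion), sampled in fixed stratum-major order from
`numpy.random.default_rng(seed)` for cross-platform reproducibility.
Defaults: 13 five-year age groups from 25, 10 five-year periods from
1970, 1e5 person-years per cell — registry-scale stability.

Three presets mirror the package's vignettes qualitatively. Their effect
sizes are this package's choices, set so that the documented recovery
rates hold at the default person-years while keeping every cell's
expected count above ~2 (sparse corner cells make Wald intervals
conservative):

* `meningioma_like_PHT` — two strata, PH-T; the true female:male CH-RR
  declines monotonically in age from about 2.7 to 1.1, realized as a
  logistic log-ratio whose linear part enters the longitudinal-trend gap
  and whose curvature enters the age deviations.
* `myeloma_like_PHA` — four strata, PH-A, intercept rate ratios
  (1, 2.24, 0.95, 0.63) against the reference stratum.
* `melanoma_like_partition` — four strata in blocks {1,2} PH-L and
  {3,4} PH-X, the block-two net drifts differing by log(1.007) per year
  (0.7 %/yr). Because period deviations are stratum-specific under PH-X,
  that gap is the least-squares linear component of the FTT
  log-difference and, exactly, the constant offset between the block's
  local-drift curves.

What the generator does **not** emulate: age-varying person-years,
within-registry correlation, secular coding changes, overdispersion
beyond the explicit negative-binomial option, and unequal age/period
interval widths (rejected by the data model). Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated sampling model, not robustness to those real-data features.

## Calibration checks and problem sizes

The simulation tests use the preset grids (13×10, 1e5 person-years per
cell): 200 replicates for Wald coverage of the net drift (pooled over
both strata of the PH-T preset; accepted band 92–98%), 200 replicates
each for AICc selection of the generating regime (PH-T and PH-A presets,
≥80% required), and 100 replicates for recovery of the planted
{PH-L}{PH-X} two-block partition (≥70% required). These sizes keep the
full suite around five minutes on one CPU while leaving the binomial
noise of the estimated rates well inside the acceptance margins.

## Known limitations

* Inference is purely likelihood-based Poisson; overdispersion is
  diagnosed (deviance/df, Pearson dispersion, large standardized
  residuals) but not propagated into quasi-likelihood intervals.
* Near-tied AICc values mean genuinely ambiguous structure; the report
  exposes the full ranking and flags exact ties, but no model averaging
  is attempted.
* Wald intervals lose calibration when expected cell counts drop toward
  zero; the lack-of-fit report and the generator's defaults are designed
  to keep users aware of, and away from, that regime.
* The partition search is exhaustive; beyond G = 12 (and practically
  beyond G ≈ 8) the strata or the evaluated partitions must be
  restricted.
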