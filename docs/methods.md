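# Methods

`setgrowth` implements growth analysis by **smoothing and extraction of
traits (SET)** for non-invasive high-throughput phenotyping (HTP) data:
each plant's trajectory is smoothed individually, biologically meaningful
single-day and interval traits are extracted from the smoothed curves, and
each trait is analysed in the designed experiment with ordinary linear-model
machinery. This note records the models, the defaults and why, the numerical
choices, what the synthetic generator does and does not emulate, and known
limitations.

## Data model and growth-rate calculus

Data are long format: one row per subject (plant/cart) per integer imaging
day (DAP), with design factors (block, lane, position), treatment factors
and nonnegative trait values — canonically the projected shoot area (PSA,
kilopixels), a biomass proxy.

Between times t_j < t_k,

* AGR(t_j, t_k) = (y_k − y_j) / (t_k − t_j)   (trait units / day)
* RGR(t_j, t_k) = (ln y_k − ln y_j) / (t_k − t_j)   (1/day)

"Continuous" rates use consecutive observed times (no value exists at a
subject's first time); "interval" rates use interval endpoints. The interval
rate is exactly the time-weighted mean of the continuous rates inside the
interval (weights = the time spans); this telescoping identity is tested to
1e−10 and is why interval traits still reflect all interior observations
after smoothing. Differencing always divides by the *actual* time gap, so
missed imaging days are handled without special cases. RGR of a trait equals
AGR of its logarithm by construction.

`derive_continuous_gr(..., on_nonpositive=...)` defaults to raising on
nonpositive values (an RGR is then meaningless and silently offsetting the
data would distort every downstream rate). The `"missing"` mode exists for
smoothed direct-scale trajectories, which can legitimately dip below zero at
the extremes of heavily smoothed, orders-of-magnitude data; there the RGR is
simply left missing.

## Smoothing

### Natural cubic smoothing splines with fixed effective DF

The smoother minimizes Σ(y_i − f(t_i))² + λ∫f″(t)²dt over natural cubic
splines with knots at the observed times, via the Green–Silverman band
construction: penalty K = Q R⁻¹ Qᵀ on the knot values, fitted values
S_λ y with S_λ = (I + λK)⁻¹. At n ≈ 35 points dense linear algebra is used
throughout.

The user never sets λ. The tuning parameter is the **effective degrees of
freedom** df = trace(S_λ), which is continuous and strictly decreasing in λ
with limits n (λ→0, interpolation) and 2 (λ→∞, the least-squares straight
line). Given df ∈ (2, n), λ is found by bracketed Brent root-finding on
log₁₀λ (bracket seeded at λ ≈ (t-range)³/n and expanded until sign change),
converging far below the |trace − df| < 1e−6 contract. df = 2 and df = n are
handled by exact branches (OLS hat matrix / identity) because the dense
solve of I + λK loses accuracy beyond λ ≈ 1e12. df is real-valued; nothing
requires integers. Since trace(S_λ) does not depend on y, the (time-grid,
df) → (λ, S) pair is cached and shared across all subjects on a common grid,
which is what makes thousand-replicate simulation studies cheap.

Properties guaranteed by construction and verified by tests: S_λ is
symmetric; K annihilates constants and linear trends, so straight-line data
are reproduced exactly at every df; RSS is non-increasing in df on fixed
data. Off-knot evaluation (imputation at missed days) uses the natural cubic
interpolant of the fitted knot values — the exact closed form of the
minimizer, not an approximation.

**Direct vs log scale.** Log smoothing fits the spline to ln y and
backtransforms (`exp`), guaranteeing positive fitted values and spreading
the penalty evenly across trajectories spanning orders of magnitude. Direct
smoothing at low DF systematically under-fits the early, small-value part of
such trajectories (the penalty is dominated by the large-value end); the
median-deviations diagnostics make this visible and it is asserted as an
ordering (direct-4 deviation larger and positive early) rather than a
magnitude. The package default mirrors the standard choice for this kind of
data: **log scale, df = 6**.

Heavy smoothing (df 4–6) is deliberate: HTP transients demand it, and
automatic selectors (cross-validation, REML) under-smooth this kind of data;
DF selection is therefore an explicit, evidence-based user decision
supported by the diagnostics module, not an optimizer. That is a design
position, not an omission.

### Three-parameter logistic

y(t) = φ₁ / (1 + exp(−(t − φ₂)/φ₃)): φ₁ the upper asymptote (kpx), φ₂ the
time of half-asymptote (DAP), φ₃ a scale (days); the time from half to
three-quarters of the asymptote is exactly φ₃·ln 3 (≈ 1.1·φ₃). Fitting is
Levenberg–Marquardt least squares with self-start φ₁ = 1.05·max(y), φ₂ from
the interpolated upward crossing of max(y)/2, φ₃ from the crossing times of
max/2 and 3·max/4. Non-convergence is reported (`converged=False`) rather
than raised so a pipeline can fall back to splines per subject; genuinely
degenerate (flat) data raise a start-value error. Noiseless data are
recovered to optimizer tolerance (tested at 1e−6 relative).

### Dataset-level and segmented smoothing

Every subject is smoothed **on all of its observed data** even when interest
is a subinterval — restricting the fit invites boundary bias. Subjects with
too few points (< max(3, ⌈df⌉), or < 4 for the logistic) go into a
per-subject failure report; one bad plant never aborts a run. Optional
imputation evaluates the fitted curve on the union time grid.

Segmented smoothing splits at user breakpoints (e.g. the onset of a watering
interruption) and smooths each segment independently; a breakpoint belongs
to both neighbouring segments but its fitted value is taken from the
*earlier* one, and continuity across the break is deliberately not enforced
(an abrupt regime change is exactly what segmentation is for). GRs are
differenced across the concatenated fitted series.

## Diagnostics

* **Median deviations**: per scheme × facet × day, the median over subjects
  of observed − smoothed. Positive medians mean the smooth under-estimates
  the trend (or a positive transient occurred). Periodic patterns are
  expected — they are the removed transients.
* **Envelope**: ±10% (configurable) of the median smoothed trajectory of a
  reference scheme, giving deviations a scale.
* **Profile summaries**: per facet × day median and outer whiskers
  median ± 1.5·IQR, IQR = Q75 − Q25 with linear-interpolation ("type 7")
  quantiles — the convention is recorded in the output metadata because no
  canonical choice exists and cross-package quantile values differ at small
  n. Whisker claims in tests are therefore orderings, not exact
  cross-package matches.

The default diagnostics grid is {direct, log} × {4, 5, 6, 12} DF plus the
logistic — nine schemes. Scheme selection remains a human decision; the
module produces evidence, not a winner.

## Outlier handling

Rules: whisker exceedance (strictly outside the outer whiskers at ≥ 3
*consecutive* observed days by default — single-day excursions are usually
transients), interval thresholds (bounds may be facet-specific, since
thresholds plausibly differ between treatments), and a near-zero-GR rule
(|GR| < ε while the facet median GR > 5ε; ε defaults to 5% of the global
median |GR|). The near-zero rule is an explicit operationalization of an
informal criterion and is labelled as such in reports. Removal is never
automatic: flagging produces a report; removal requires an explicit id list
and is logged with its reason in the dataset history.

## Trait extraction

With endpoints {18, 22, 27, 33, 39, 43, 51}: 7 smoothed values, 7 + 7
endpoint AGR/RGR values and 6 + 6 interval mean AGR/RGR values = 33
potential traits; the endpoint GR traits are excluded from the default
analysis set (19 traits) because they duplicate the neighbouring interval
means. Interval means are computed from the smoothed endpoint values, which
by the telescoping identity equals the weighted mean of the continuous
smoothed GRs (asserted to 1e−10 in tests). The homogeneity report
(median AGR at interval start/end, slope sign, RGR trend, fraction of
subjects with rising AGR, coarse category) supports — never replaces — the
interval choice.

## Per-trait analysis

Model: y = μ + Block + Zn + AMF + Zn:AMF + e, e ~ N(0, σ²I), fitted by OLS;
blocks are fixed. Term tests are marginality-respecting (Type II) Wald F
with denominator df = residual df; for a fixed-effects-only iid-error model
the Kenward–Roger denominator df reduces exactly to the residual df, so this
is an equivalence, not an approximation. On the balanced complete design
Type I/II/III coincide and equal the classical mean-square ratios (verified
against an independent sums-of-squares oracle to 1e−8); the Type-II choice
only matters after outlier removal unbalances the data. Zero residual
variance (degenerate noiseless input, detected relative to ‖y‖²) reports F
as missing with a note rather than an infinite ratio.

Predictions are cell means averaging over blocks (estimable linear
functions), with SEs from σ̂²·L(XᵀX)⁻¹Lᵀ. SED per pair; LSD(α) =
t_{1−α/2,df}·SED. Balanced: all SEDs equal s√(2/r). Unbalanced: the exact
pairwise SED/LSD matrices are returned, and the single plotting ribbon uses
t·mean(SED) — a display convention, with exact inference always available.
Residual diagnostics are emitted as tables (residual-vs-fitted,
normal-quantile with Blom positions); no formal normality test is computed —
the assessment is visual, by design.

`analyze_all_traits` shares the design matrix and per-term QR factorizations
across traits when no values are missing, making a full 19-trait re-analysis
run in milliseconds.

The helper `implied_ar1_correlation(rho, lag) = rho**lag` exposes the
power-law decay of first-order autoregressive correlation between imaging
days (lag 1: 0.88 → lag 2: 0.7744).

## Synthetic experiment generator

The generator defines the study conditions for every simulation-based test:
a randomized complete-block design with 4 blocks × (4 Zn levels × 2 AMF
levels), one plant per cart, daily imaging DAP 17–51 → 1120 PSA records.
Per plant, PSA(t) = m(t)·exp(σ(t)·z(t) + A·s(t)):

* m(t): logistic with plant parameters drawn around treatment means
  (φ₁ CV 6%, φ₂ SD 0.5 d, φ₃ SD 0.15 d, multiplicative block effect
  SD 3%). Defaults: +AMF asymptotes 172–180 kpx essentially independent of
  Zn; −AMF asymptotes 95–160 kpx rising with Zn; φ₂ = 34 d, φ₃ = 3.8 d, so
  day-17 sizes sit near 2 kpx and trajectories span ≈ 2 orders of magnitude
  (≈ 0.8–195 kpx with noise).
* watering-interruption dip: the mean curve's day-to-day AGR is multiplied
  by 0.3 for DAP 39–41, recovering linearly over 2 days; rebuilding by
  cumulative summation keeps the curve continuous. The dip acts on AGR (not
  RGR) because a watering interruption throttles absolute growth.
* z(t): standardized stationary AR(1), lag-1 correlation ρ = 0.88,
  independent across plants; σ(t) ramps 0.04 → 0.08 (log scale) with
  m(t)/φ₁, widening the replicate spread over time.
* s(t): deterministic alternating sign, period 2 d, amplitude 0.015 on the
  log scale — invisible in the PSA profile but producing the characteristic
  sawtooth in raw AGR/RGR.

`null_experiment` gives every treatment the same curve, enabling exact
type-I-error studies; label permutations leave its distribution unchanged by
construction. The same seed reproduces a byte-identical CSV.

**What the generator does not emulate**: spatial lane/position trends
(columns exist, trend off), image-processing artefacts, treatment-dependent
residual variance, plant death/missingness patterns, and outliers (tests
construct those explicitly). Passing tests therefore demonstrate correctness
of the machinery under a realistic noise model, not robustness to every
pathology of real greenhouse data.

## Problem sizes used in validation

Structural checks run one default experiment (1120 records). The smoother's
DF semantics are checked on 50 random 35-point series and six DF values; the
telescoping identity on 100 random irregular trajectories; ANOVA equality on
50 balanced tables; the type-I study runs 1000 full null pipelines
(→ 19 000 pooled tests per term; per-term rejection rates land within
0.05 ± 0.01 at seed 1). The full pipeline on one experiment takes ~0.1 s on
one CPU, which is what makes these replicate counts routine.

## Known limitations

* Only differencing-based GRs are provided (spline first derivatives are
  not exposed); differencing is the only definition available for *raw*
  rates and keeps smoothed and raw rates commensurable.
* The longitudinal mixed-model route (random regression splines per plant,
  per-day variances, AR1 residual correlation, REML model selection) is out
  of scope; this package is the per-plant SET alternative to it.
* LSD-based comparison assumes comparisons at the same time point/interval;
  cross-time comparisons would need the joint covariance this model does
  not carry.
* Quantile and whisker conventions are fixed (type 7) and recorded, but
  other software using other quantile types will differ slightly at n = 4
  replicates.
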