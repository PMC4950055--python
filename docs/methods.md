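# Methods notes

## The model

Birth weight `y` at completed gestational week `t` is modelled as BCCG:
the transformed quantity `z = ((y/mu)^L - 1)/(L*S)` is standard normal,
with `L = L(t)` (Box–Cox power), `mu = M(t) * exp(delta * female)`
(median, log link) and `S = S(t)` (coefficient of variation). The log
link makes `delta` a constant percentage contrast between the sexes;
`L` and `S` are pooled across sexes. The reported sex difference is
`100*(1 - exp(delta))` ("girls this many percent below boys"), with a
normal-theory 95% CI from `delta +/- 1.96*SE`.

The BCCG density is the change-of-variables density of the Box–Cox
transform. The truncation factor `Phi(1/(L*S))` that would renormalise it
to positive support is omitted throughout: at the coefficients of
variation relevant to birth weight (S <= 0.27) it differs from 1 by less
than 1e-8, and the classical LMS formulation ignores it too. For the same
reason the simulator draws `z ~ N(0,1)` and simply redraws in the
(practically impossible) event `1 + L*S*z <= 0`, preserving the BCCG
shape rather than clamping.

Centile lines are defined by z-spacing, not by exact tail areas: the
default chart draws z = 0, ±2/3, ±4/3, ±2 and labels them with the
approximate centiles (50th, 25th/75th, 9th/91st, 2nd/98th). The labels
map to exact z values, so "2nd centile" means z = −2, not Φ⁻¹(0.02).

## Numerical choices

- `|L| < 1e-8` switches the centile/z-score/score formulas to their
  analytic log-limit branches; elsewhere `log1p`/`expm1` forms are used so
  the z ↔ centile round trip is exact to double precision even at
  L ~ 1e-7 (charts often print L rounded to two decimals, with values
  passing through zero).
- Centile tables round half-away-from-zero to integer grams, the
  convention of published charts.
- Interpolation between integer weeks is linear in (L, log M, log S):
  positivity-preserving and consistent with the log link for M.
- Tie-break for the modal gestation: the lower week wins.

## Fitting

Each curve is a clamped cubic B-spline with knots at every integer week
of the fit window and a second-difference penalty on its coefficients.
The penalized log-likelihood is maximised by cyclic backfitting: one
penalized Fisher-scoring step per curve per cycle (the median curve and
`delta` update jointly), with step-halving whenever a proposed step would
decrease the objective, iterated until the relative change in the
penalized log-likelihood falls below `tolerance` (default 1e-7). The
Fisher weights per observation are `7*S^2/4` for L, `1/S^2 + 2*L^2` for
log M and `2` for log S (the expected information of the BCCG likelihood
to second order in S). Because every accepted step is non-decreasing, the
penalized log-likelihood trace is monotone, which the test suite asserts.

Smoothness is parameterised by effective degrees of freedom,
`edf = tr[(B'WB + lambda*P)^(-1) B'WB]`. The penalty weight `lambda` per
curve is found by bisection on log-lambda against the starting-value
Fisher weights and then held fixed, so the objective is a fixed
functional across iterations; the edf recomputed at convergence is
reported alongside the target (they differ by at most a few percent as
the weights update). With a second-difference penalty the edf floor is 2
(its null space is the linear functions), so `edf = 1` is implemented as
an exact constant basis and targets strictly between 1 and 2 fall back
to a first-difference penalty (floor 1).

Defaults: `edf_L = 4`, `edf_M = 6`, `edf_S = 4` over a 28–43-week fit
window, reported over 30–42 weeks. The original chart's smoothing
settings are not published; these values are flexible enough to track the
reference chart's shapes (L rising from about −0.1 to 1.0 across the
window, S dipping around 38–40 weeks) while keeping the curves stable in
the sparse tails, and they are exposed in `FitConfig` rather than chosen
automatically. Starting values are scale-free: L ≡ 1, M from smoothed
per-week medians, S from smoothed per-week (IQR/1.349)/median, delta from
the difference of the sexes' log-medians. The fit itself is
deterministic.

`SE(delta)` comes from the inverse penalized Fisher information of the
joint (M-curve, delta) block at convergence — the usual Bayesian
covariance of penalized spline models. It accounts for the correlation
between delta and the median curve but, like any backfitting SE, not for
the (weak) correlation with L and S.

Records with gestation outside the fit window are excluded, not clamped;
at least 50 usable records are required, and both sexes when the sex
offset is on.

## The synthetic register

The simulator emulates a national cytogenetic register extract: exact
per-(sex, week) counts (defaults: the published reference counts,
totalling 8,825 across weeks 28–43 and peaking at the modal 38 weeks),
weights drawn from the reference LMS chart, birth years uniform over
1989–2011. Deterministic cell counts, rather than multinomial draws, make
selection flows and table sums exactly assertable. Optional knobs:

- `trend_g_per_year` (default 0 g/year, matching the absence of a secular
  trend in the source register): added linearly around the year-range
  midpoint.
- MCAR missingness for weight and gestation (default 0), plus a
  log-odds-per-week gradient in weight-missingness anchored at week 38
  for the missingness regression's power/type-I checks.
- Contaminating records (non-live outcomes, non-free-trisomy karyotypes,
  default 0) for selection-flow tests. The stillbirth weight deficit is
  unpublished, so the −150 g default offset is an arbitrary, documented
  knob, not a claim.

What the simulator does **not** emulate: gestational-age measurement error
(LMP-based dating), within-year seasonality, maternal covariates,
heart-anomaly status, or any real termination/stillbirth gestation
structure. Passing recovery tests therefore shows the estimator is
consistent for data generated by the model it assumes — evidence of
correct implementation, not of robustness to real-register artefacts.

## Pipeline conventions

- Selection stages are applied in the fixed order outcome → karyotype →
  completeness → gestation window, so each exclusion is charged to
  exactly one stage and the flow conserves records.
- The secular trend is a linear OLS regression of the fitted SD score on
  birth year (the SD-score scale removes the gestation mix); the
  grams-per-year conversion multiplies the slope by M·S at the modal
  week, averaged over sexes, since M·S approximates the SD in grams. A
  direct grams-on-year regression is exposed as an option because
  published analyses sometimes report on that scale.
- The missingness check is a one-covariate logistic regression of the
  missing-weight indicator on gestational week, fitted by Newton–Raphson
  (relative tolerance 1e-10) with a two-sided Wald p-value — the default
  reporting of standard GLM software.
- All 95% intervals are normal-theory.
- Chart comparison differences are computed reference-minus-study per
  (sex, week, centile) over the overlapping domain; they are exactly
  antisymmetric under swapping the charts. No published difference against
  an external chart is asserted anywhere, because external charts enter
  only as user-supplied LMS tables.

## Problem sizes used in the test suite

Recovery and calibration checks run at the scales the methodology is
meant for: single fits and 20-replicate means use the full 8,825-record
register; the 100-replicate trend-coverage check also runs at full scale;
the 200-replicate missingness type-I check uses quarter-scale registers
(~2,210 records), ample for a one-covariate logistic Wald test. One cell
of 100,000 draws checks the simulator's distributional accuracy.

## Known limitations

- Exact numerical replication of the published LMS parameter table from
  raw data is impossible from the outside: the register is not public and
  the original smoothing settings are unpublished. The package instead
  verifies that (a) the published centile tables follow from the published
  parameters to printed precision, and (b) fits of synthetic registers
  generated from those parameters recover them.
- Backfitting SEs are reported for delta only; no covariance is provided
  for the curves themselves.
- No four-parameter (BCT/BCPE) extensions; no measurements other than
  weight-for-gestation; no covariates beyond sex and gestation.
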