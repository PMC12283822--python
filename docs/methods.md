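# Methods

This note documents the statistical procedures, the generator that defines
the synthetic study conditions, the numerical choices, and the known
limitations of `kmvar`.

## 1. Reconstruction of individual records

**Inputs.** Digitized step coordinates `(t_k, S_k)` of one arm's
Kaplan–Meier curve (months, probabilities) and the published number-at-risk
table `(T_i, R_i)`, optionally the arm's total death count.

**Cleaning.** Digitization leaves jitter: survival values are clipped to
[0, 1] (a percent axis is detected when values exceed 1.5 and divided by
100), duplicate times are collapsed keeping the post-step minimum, `(0, 1)`
is prepended when absent, and monotone non-increase is enforced by
pool-adjacent-violators. Cleaning is idempotent.

**Algorithm.** The interval-by-interval procedure of Guyot et al. (2012).
Within each interval between consecutive risk-table times, a censoring count
is guessed, censoring times are placed uniformly over the interval
(deterministically), event counts at each digitized step follow from the KM
ratio against the running reconstructed estimate, and the guess is iterated
until the reconstructed at-risk count at the next published time matches.
Iteration stops on match or when a guess repeats; ties break toward fewer
censorings. Implied non-integer event counts are rounded half-up with a
running remainder so interval totals are preserved. Participants still at
risk after the last digitized time are censored there. The reconstructed
cohort size equals `R_0` by construction.

Numerical details worth knowing:

* *Parity traps.* Adding one censoring occasionally flips one rounded event,
  so the at-risk target can be unreachable by exactly one. A residual of at
  most `max(2, 1% of cohort)` is tolerated and propagated (the cited
  algorithm's stop-on-repeat behavior); larger mismatches raise an error
  naming the interval.
* *Total-events constraint.* When the death count is supplied, the censoring
  allocation of the final stretch (last inter-risk interval plus anything
  after the last risk time) is adjusted: within the boundary-satisfying
  allocations each extra censoring trades exactly one event, which is what
  makes the adjustment possible. An inconsistent count is met as closely as
  possible (logged), never silently redistributed across earlier intervals.
* *Exactness.* On exactly rendered inputs with administrative censoring
  only, reconstruction is lossless: per-interval event counts and the
  round-trip KM agree exactly. With random dropout inside intervals, event
  counts per interval remain exact but uniform censor placement can shift
  within-interval at-risk counts, leaving round-trip KM drift of the order
  of one step (1/n). Digitization noise of SD 0.005 perturbs reconstructed
  event counts by well under 5% of the cohort in the regimes tested.

## 2. Per-arm Weibull variability

Death times are modelled Weibull, `S(t) = exp(−(t/λ)^k)`. The censored
log-likelihood is maximized over `(log k, log λ)`: a one-dimensional profile
in `log k` (the scale has a closed-form profile optimum
`λ^k = Σ t_i^k / d`) is minimized by bounded Brent search, then polished by
damped Newton steps with analytic gradient and Hessian until the gradient
norm is below 1e-8. The covariance of the log-parameters is the inverse
observed information. Fits require at least two events at two distinct times
(a single event time sends the shape to infinity and is rejected).

The variability outcome is `log SD` of the **uncensored** fitted law,

    Mean = λ·Γ(1 + 1/k),  SD = λ·sqrt(Γ(1 + 2/k) − Γ(1 + 1/k)²).

Censoring enters only through the likelihood. With follow-up of 2–5 years
and fitted SDs of roughly 20 years, these are heavily extrapolated moments;
that is deliberate — it puts arms with different follow-up on a common
scale, and the meta-regression adjusts for `log Mean`.

`Var(log SD)` is computed by the delta method: the gradient of `log SD`
with respect to `(log k, log λ)` (the `log λ` component is exactly 1)
applied to the log-parameter covariance. A case-resampling bootstrap is
provided as an independent check and agrees with the delta method within a
few percent at CVOT-like arm sizes; the delta method is the production
estimator because it is deterministic and cheap.

## 3. Meta-regression

Arms are observations of

    y_ij = β0 + β1·trt_ij + β2·logMean_ij + u_i + ε_ij,
    u_i ~ N(0, τ²),  ε_ij ~ N(0, v_ij),

with `v_ij = Var(log SD)_ij` treated as **known** (inverse-variance
weighting, the meta-analytic convention; no residual scale multiplier is
estimated). τ² is profiled by REML over a nonnegative grid (0 plus 80
log-spaced points up to ten times the outcome variance) and refined by
bounded scalar minimization between the best grid neighbors; the returned
value attains the best REML criterion among all evaluated candidates, and
hitting the upper bound sets a warning flag. Fixed effects are GLS at the
selected τ² with Wald z (1.96) intervals. Estimates are invariant to arm
ordering and trial relabeling, and the implementation matches `metafor`'s
`rma.mv` on the same data to four decimals.

**Interaction screens.** One model per clinical predictor, adding the
(trial-level) predictor's main effect and its interaction with treatment.
Continuous predictors are centered at the mean over included arms (this
changes only the treatment main effect, never the interaction). Drug class
enters as indicator contrasts with the first observed class (DPP-4 in the
shipped data) as reference. Trials missing a predictor are dropped for that
model only, with the count logged and reported; fewer than three remaining
trials is an error. Per-predictor failures are recorded rows in the screen
table, not fatal.

**Subgroups.** The primary model restricted to one drug class requires at
least two trials; subgroups of six or fewer arms carry an explicit warning
that their standard errors should not be over-interpreted.

## 4. The synthetic study conditions

The generator emulates the portfolio the analysis targets: ten two-arm
placebo-controlled CVOTs. Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| trials per portfolio | 10 | the analyzed portfolio size |
| arm size | uniform 2200–8600 | published CVOT arm range |
| follow-up cutoff | uniform 24–66 months | published median follow-ups (19–65 mo) |
| dropout hazard | 0.002 / month | mild random loss on top of the administrative cutoff |
| base log(SD) | uniform 5.0–6.0 | observed arm log(SD) ranged ≈ 4.5–7.0, means ≈ 5.45 |
| β2 (log Mean coefficient) | 1.0 | roughly constant coefficient of variation across trials |
| β0 (intercept) | −0.18 | implies CV ≈ 0.84, i.e. Weibull shape ≈ 1.2 |
| β1 (treatment) | −0.036 | headline effect size used as simulation truth |
| τ (intercept SD) | 0.05 | modest between-trial heterogeneity |
| covariates | uniform within published min–max | realistic support without invented correlations |

Construction per trial: a base level and a random intercept set the placebo
target `log SD`; the verum target differs by exactly β1 (plus an optional
built-in treatment-by-predictor slope); the trial's `log Mean` is derived
from the base level through the linear predictor, so the adjustment
covariate is exogenous by construction. Shape and scale are then solved
jointly from the (mean, SD) targets — the coefficient of variation pins the
shape uniquely (CV(k) is strictly decreasing), the mean then pins the scale.
Solving both parameters, rather than holding the shape fixed and moving only
the scale, keeps the arm's mean independent of the treatment effect on the
SD; otherwise `log Mean` would be an endogenous function of the effect and
the adjusted treatment coefficient would be biased toward zero. Event
fractions come out near 8%, matching the published cohort (7.6%).

What the generator does **not** emulate: pixel-level digitization (noise is
Gaussian on the survival axis, then re-monotonized), competing risks,
non-Weibull or time-varying hazards, informative censoring, correlated
covariates, and staggered entry. Passing tests therefore validate the
reconstruction/estimation/regression chain under these idealized mechanisms,
not the fidelity of any real digitization.

## 5. Calibration findings

Validation studies shipped with the test suite (problem sizes chosen to keep
a full run in minutes on one core):

* Delta-method 95% intervals for `log SD` cover at ≈ 0.94 over 200 simulated
  arms (n = 2000, 30% censoring); the delta variance agrees with a 500-draw
  bootstrap within a few percent.
* Over 500 simulated portfolios the mean estimated treatment coefficient is
  −0.0361 (truth −0.036); the 3-trial subgroup configuration recovers −0.050
  within Monte-Carlo error; a built-in treatment-by-HbA1c slope of 0.02 per %
  is recovered within Monte-Carlo error over 200 portfolios.
* The Wald interval for β1 holds its nominal level (coverage ≈ 0.95) when
  the arm-level data are generated directly from the mixed model with known
  `v`. When the arm summaries are *estimated* from individual records, the
  interval becomes strongly conservative (observed coverage ≈ 1.0): the
  fitted `log SD` and `log Mean` of an arm are almost perfectly correlated
  (ρ ≈ 0.996) because both are extrapolated moments driven by the same
  parameter errors, so the location adjustment absorbs most measurement
  error while the weights `1/v_ij` still reflect the full marginal variance.
  The realized spread of the treatment estimate is ~3× smaller than its
  model-based SE. This conservativeness is intrinsic to inverse-variance
  weighting with moment-correlated summaries under heavy extrapolation — a
  real feature of this design, worth keeping in mind when reading the
  original CIs — and is documented rather than patched.

## 6. Known limitations

* Trial-level covariates are ecological: interaction screens cannot detect
  within-trial effect modification.
* The Weibull family is assumed adequate (it fits published CVOT mortality
  curves well); no alternative families are implemented.
* `Var(log SD)` is the delta-method estimator; other choices (normal-theory
  `1/(2(n−1))`, bootstrap) would change the weights and hence the CI width.
* The reconstruction assumes non-informative censoring within risk
  intervals and standard survival curves (no cumulative-incidence inputs).
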