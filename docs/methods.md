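# Methods

This note records the statistical procedures the package implements, the
defaults and numerical choices behind them, and what the synthetic test
conditions do and do not establish.

## Data model

A dataset is `{(U_i, x_i, δ_i)}`, one row per patient: `d` numeric
covariates, a nonnegative observed time `U_i = min(T_i, C_i)` and an event
indicator `δ_i = 1[T_i ≤ C_i]`. The latent true time `T_i` and censoring
time `C_i` are never stored — only the generator (for oracle tests) knows
them. Times are kept on the scale they were read; every computation in the
package is a ranking or a comparison, so no unit is assumed. Missing
covariates are rejected rather than imputed, and only right censoring is
representable (no left truncation, interval censoring or competing risks).

One deliberate asymmetry: the in-memory container permits a dataset with
zero events — needed to represent a degenerate late endpoint that nobody
reached — while the CSV loader and every model constructor reject it.

## Metrics

**Concordance index.** Harrell's convention: pairs `(i, j)` are comparable
when `U_i < U_j` and `δ_i = 1`, plus tied-time pairs where `i` is an event
and `j` censored. A pair is concordant when the shorter-lived patient has
the smaller survival-oriented score; tied scores earn 0.5; tied event times
are not compared to each other.

**Stratification at a time point `t`.** Positives are events with
`U ≤ t`; negatives are records observed beyond `t`; censored records with
`U ≤ t` are excluded (their class is unknowable). A record is predicted
high-risk when its score falls below a threshold. Boundary convention: an
event exactly at `t` is positive, a censored record exactly at `t` is
excluded — this keeps the three classes exhaustive and is tested. An empty
positive or negative class raises rather than silently scoring 0.

**Threshold selection.** The continuous score is dichotomized at the
midpoint of adjacent sorted unique scores that maximizes
sensitivity × specificity **on training data**, with ties broken toward the
smaller cutoff; the threshold is then frozen for validation. Products that
differ only by float rounding of mathematically equal values are treated as
ties (comparison epsilon 1e−15).

**Combined criterion.** `Criterion = CI + sensitivity × specificity`,
range [0, 2]. Both terms live on comparable scales for any useful model
(CI > 0.5), and the product term rewards a usable operating point rather
than ranking alone.

## Cox proportional hazards learner

Newton–Raphson on the log partial likelihood with Breslow tie handling
(simplest standard method; estimates match statsmodels' Breslow option to
machine precision and lifelines to its own convergence tolerance).
Features are centered internally — the partial likelihood is invariant —
for numerical range; coefficients are reported on the original scale.
Convergence: gradient norm ≤ 1e−8 within 100 iterations, with step-halving
to force ascent; otherwise a fit error with diagnostics. Standard errors
come from the inverse observed information.

Degenerate designs: a constant column is dropped with a warning and gets
coefficient 0. Monotone likelihood (perfect separation) is caught two ways:
coefficients exceeding ±500 during iteration are capped with a warning, and
a converged fit whose single-feature linear-predictor range exceeds 15 (a
hazard ratio of e^15 across the cohort) is flagged as separated. No
regularization by default — a ridge penalty exists behind an explicit flag
only as a separation fallback. The baseline hazard is never estimated: all
downstream uses need only the rank-preserving linear predictor, and scores
are its negation so that larger = longer survival.

## SVRc learner

The asymmetric censored-data SVR minimizes
`½‖W‖² + Σ_i (C_i ξ_i + C_i* ξ_i*)` subject to the two-sided tube
constraints with per-sample `(C_i, ε_i)` below and `(C_i*, ε_i*)` above the
regression function, mixed by censoring status
(`C_i* = s_i C_c* + (1−s_i) C_n*`, etc., `s_i = 1` iff censored). The
printed mixing rule covers only the upper-starred side; the unstarred side
is completed symmetrically, the convention of the original censored-SVR
formulation.

**Defaults** (all overridable, logged in the serialized model):
`C_n = C_n* = C_c = 1`, `C_c* = 0.2`, `ε_n = ε_n* = ε_c = 0.1·sd(times)`,
`ε_c* = 0.5·sd(times)` — a wide, lightly penalized upper tube for censored
records encodes "over-predicting a censored time is cheap". Inverted
relations (`ε_c* < ε_n*`, `C_c* > C_n*`) warn but are not forbidden.
Kernel: linear by default (a single weight per feature is only meaningful
then); RBF available for prediction. Features are standardized on the
training data by default (the C/ε scales are not scale-free); targets are
the raw times, with an optional log1p transform.

**Solver.** The dual — a QP in `(α, α*)` with per-sample boxes
`[0, C_i] × [0, C_i*]` and the intercept equality constraint — is solved by
a maximal-violating-pair SMO iteration (the standard working-set scheme of
SVM libraries, generalized to per-sample C and ε). Stopping: KKT violation
≤ 1e−8 × max(1, max|y|). The intercept is averaged over free support
vectors, falling back to the midpoint of the KKT interval. Every fit
reports its primal and dual objectives; a relative duality gap above 1e−6
triggers one diagonal jitter retry (1e−8 × mean kernel diagonal) and then a
fit error above 1e−3. Agreement is verified in tests against scikit-learn's
SVR in the symmetric-parameter limit (≤ 1e−4 on weights) and against a
direct primal solve by scipy's trust-constr on small asymmetric fixtures
(≤ 1e−5 relative objective).

## Transduction

For each censored record `i`, candidates are `m + 1` equally spaced times
from `U_i` to `T_max` inclusive (default `m = 10`); the first candidate is
always the unmodified `U_i`, so the search can never select something worse
than the observed data. For each candidate the learner is refit on a copy
where only record `i`'s target changed, and the criterion is computed on
the original times with a freshly selected training threshold. Ties break
toward the smallest candidate (minimal departure from observation). A
failed candidate fit is skipped with a warning; only if all candidates fail
does the instance error.

Records are searched independently against the original dataset — not
sequentially against partially transduced data — which is what makes the
cost linear in the number of censored records; the final model is fit once
on the combined targets with original indicators (so SVRc still applies its
censored-sample loss to transduced records). The sequential variant is a
possible extension, not implemented.

Two properties are guaranteed by construction and tested: the constraints
`Û_i = U_i` (events) and `U_i ≤ Û_i ≤ T_max` (censored) hold on every
output, and each instance's selected criterion is at least the criterion at
its unmodified time. The criterion of the final *combined* refit is not
guaranteed to beat the un-transduced baseline (each target was optimized in
isolation); both values are carried on the results object so the comparison
is always visible. All validation metrics are computed on original times
with the threshold frozen on training scores; transduced targets never
enter an accuracy assessment.

The exhaustive joint search over all grid assignments exists only as a test
oracle for fixtures with a single censored record, where it coincides with
the singular search.

## Synthetic cohorts

`generate_single_endpoint` draws i.i.d. standard-normal covariates and
Weibull event times with scale `λ·exp(−βᵀx/k)`, so proportional hazards
holds exactly with log-hazard `βᵀx` and Cox recovery is well-posed.
Censoring is noninformative: uniform on `(0, c*)` capped at an
administrative horizon, with `c*` found by bisection so the realized event
rate lands within ±2 percentage points of the request (the realized rate is
monotone in `c*`; unattainable targets raise a calibration error).

`generate_two_endpoint` adds a nested late endpoint: only true
early-endpoint events progress, with probability
`sigmoid(a₀ + aᵀx)` (default: logistic in the first two covariates), at the
early time plus a Weibull gap; both endpoints share the same follow-up
time, which enforces that every observed late event is an observed early
event at an earlier-or-equal time.

Defaults — `n = 340`, `d = 9`, `k = 1.5`, `λ = 180`, horizon 120,
censoring target 87%, progression intercept 0, gap Weibull(1.3, 30) — were
calibrated once so the mean realized rates over 50 seeds are ~13% (early)
and ~3.5% (late), the cohort structure this design targets; the covariate
distributions and effect sizes are illustrative, not estimates of any
clinical population. What passing tests on these cohorts show is that the
machinery is correct under a proportional-hazards world with exchangeable
Gaussian features and noninformative censoring; they do not show
robustness to the correlated, heavy-tailed, partly ordinal features or the
informative censoring of real clinical data.

## Problem sizes used in the checked runs

Oracle equivalences run on fixtures of 5–30 records; transduction
properties on a full n = 120 / 80%-censored / 10-step-grid SVRc run and
n ≈ 20–50 Cox fixtures; Cox parameter recovery on 20 cohorts of n = 2000;
generator calibration over 50 seeds at n = 340; the chance-level
concordance average over 1000 score draws at n = 200.

## Known limitations

* SVRc weights are reported in the standardized feature space when internal
  standardization is on; comparisons across models should use the
  normalized weight report.
* The weight normalization divides by the maximum absolute weight by
  default. Published weight tables are not fully consistent on this point
  (some columns divide by a reference feature that is not the largest in
  magnitude); the `max_positive` rule is available behind a flag.
* The evaluation time point for stratification is a required configuration
  parameter; no data-driven choice is attempted.
* Hyperparameter search for SVRc is out of scope; defaults are heuristics
  tied to the time scale.
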