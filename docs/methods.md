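# Methods

This note documents the statistical model behind `survfunnel`, the
numerical choices that matter, what the simulation harness does and does
not emulate, and the design decisions taken where the methodology leaves
room.

## Model and estimands

**Setting.** `n` centers, `n_i` patients in center `i`; per patient we
observe `(t_ij, d_ij, x_ij)`: the follow-up time `min(T̃, C)`, the event
indicator, and a case-mix covariate vector. Censoring is assumed
independent of the event time given case mix, and (deliberately) *not*
modeled as covariate-dependent: the center's follow-up behavior is treated
as a property of the center. All analyses run on data administratively
truncated at the horizon τ ("stopped" follow-up): any subject observed past
τ becomes `(τ, censored)`. Truncation is applied to *everything* —
benchmark fitting, censoring estimation, event counting — so the observed
counts, the expected counts, and the overall event fraction `p0` all refer
to the same window. A side benefit of the stopped fit is robustness of
fixed-time predictions to proportional-hazards violations, which the
non-PH simulation scenario confirms empirically.

**Benchmark.** A proportional-hazards model
`h_ij(t) = h0(t) exp(β'x_ij)` fitted to the pooled data of all centers,
disregarding center identity: the benchmark *is* the average performance
of participating centers. The baseline cumulative hazard is estimated by
its Breslow jumps `h0(s) = d(s) / Σ_{at risk} exp(β'x)`. Coefficients and
baseline are treated as known downstream: benchmark uncertainty is
negligible against single-center sampling noise, and conceptually the
estimated benchmark is the target, not an estimate of one. A benchmark may
also be imported from a frozen coefficients + baseline table, supporting
external targets and year-over-year comparisons.

**Censoring.** Per-center follow-up curves `G_i` by reverse Kaplan-Meier:
censoring before τ is the "event", deaths are removals. Two conventions
are fixed: administrative censoring at exactly τ is *complete* follow-up
(no hazard jump; the subject stays in the risk set through τ), and at tied
times deaths leave the risk set before censorings. Per-center curves are
always used, however small the center; a pooled-curve option exists for
users who prefer borrowing strength, and curves extend as constants beyond
the last observed time.

**Per-patient event probability.** Under the center-performs-to-benchmark
null, the observed-event indicator of patient (i,j) is Bernoulli with

    p_ij = P(T̃ < C, T̃ < τ) = Σ_{s ≤ τ} h0(s) e^{β'x_ij} S_ij(s−) G_i(s−),

summing over baseline jump times. Left limits are deliberate: the patient
must be event-free and under follow-up *just before* s, matching the KM
tie conventions. Two survival plug-ins are offered:

* `product_limit` (default): `S_ij(s−) = Π_{u<s} (1 − min(1, h0(u)e^{β'x}))`.
  The per-jump hazard is clipped at 1 so survival stays nonnegative for
  extreme linear predictors, and — the reason this is the default — the
  no-censoring case telescopes exactly to `p_ij = 1 − S_ij(τ)`, giving the
  test suite an algebraic anchor.
* `exp_cumhaz`: `S_ij(s−) = exp(−H_ij(s−))`, a sensitivity option. The two
  agree to well under 0.02 on realistic data.

**Inference.** `O_i` vs `E_i = Σ p_ij`, `V_i = Σ p_ij(1−p_ij)`,
`Z_i = (O_i − E_i)/√V_i`. Exactly, `O_i` is Poisson-binomial; the exact
distribution is computed by a dynamic-programming convolution (O(n²) time,
linear space, all intermediates probabilities) for centers up to 5000
subjects (configurable), larger centers use the normal approximation —
which is accurate there anyway, and is what the Z-classification uses
throughout. Exact two-sided p-values double the smaller tail and cap at 1;
no mid-p correction (the conservative standard). Centers with `E = 0` or
`V = 0` are reported but flagged untested.

**Funnel geometry.** The x-axis is the effective sample size
`(E²/V)(1−p0)/p0` with `p0` the overall post-truncation event fraction; a
center with homogeneous `p_ij = p0` sits exactly at its raw size, which is
why clinicians can read the axis as "number of patients, adjusted for case
mix and follow-up". Control limits `1 ± z_{1−α/2}√((1−p0)/p0)/√x` at the
nominal level, plus multiplicity-adjusted limits at α′ (default Bonferroni
α/n, configurable). Classification by |Z| threshold and position relative
to the curves are algebraically identical; the tests assert this.

**Follow-up funnel.** Swap the roles: the event is a loss to follow-up
strictly before τ, the null is a common follow-up distribution, so the
censoring hazard `hC` and curve `G` are estimated from the *pooled* data,
while the patient's event-free survival `S_ij` now must reflect genuine
between-center mortality differences — it comes from a *center-stratified*
fit (shared β, per-center Breslow baselines). Stratification was chosen
over fixed or random center effects because it needs no new estimation
machinery and tolerates non-proportional center effects; strata with fewer
than two events fall back to the pooled baseline (logged). Left limits of
both `G` and `S` are used, making the mortality and follow-up integrands
exact mirror images; on a cohort with β = 0 and stratification disabled,
swapping status codes maps one funnel onto the other exactly (tested).

**Missing case mix at benchmarking time.** Missing covariate values are
imputed by the median (numeric) or mode (indicator) among patients with
the observed *favorable* outcome — alive and under follow-up at τ. This
makes incompletely registered patients look relatively healthy, lowers the
center's expected count, and so penalizes incomplete registration rather
than rewarding it. The median uses the lower middle order statistic on
even counts and modal ties break to the smaller value (determinism);
imputation is global per covariate, not within subgroups. Model *fitting*
is expected to receive complete or properly multiply-imputed data;
benchmarking-time single imputation is the only rule implemented here.

## Numerical implementation

The Cox fit is a Newton maximization of the Breslow partial likelihood
(relative log-likelihood change < 1e-9, at most 100 iterations, step
halving), vectorized with suffix cumulative sums over subjects sorted by
time; strata contribute additively. It matches `lifelines` to ~1e-5 on
shared fixtures (test suite) but exposes the Breslow jumps directly and is
fast enough for thousands of refits.

The batch `p_ij` computation exploits an exact telescoping identity: over
any interval between consecutive jumps of `G_i`, `Σ h0(s)e^θ S(s−) =
S(a) − S(b)` under the product-limit form, so `p_ij` collapses to a sum
over the center's censoring-jump segments. The per-subject `log S` at the
segment boundaries is evaluated through the power series of
`log1p(−h0 e^θ)` truncated at order 4, whose truncation error for a
subject with maximal per-jump hazard `z` is at most `m z⁵/5`; subjects for
whom that bound exceeds 1e-8 are recomputed on the dense reference path
(direct per-subject sum over the whole grid). The fast and dense paths
agree to ~1e-10 where both apply. The follow-up probabilities use the same
telescoping with the roles of `S` and `G` exchanged, which is exact
without any series. Pseudo-values are computed by cumulative leave-one-out
corrections to the log product-limit (one pass, O(n log n)), matching
naive recomputation to 1e-10.

## Simulation harness

The generative model emulates a large multinational transplant-registry
benchmarking exercise, time in months, horizon 12:

* center sizes `NegBin(mean 200, SD 150)`, zeros redrawn (not shifted) to
  preserve the mean approximately while avoiding empty centers;
* per-center censoring `Weibull(shape a_i, rate r_i)` with
  `(log a_i, log r_i) ~ N((0.4, −4.8), SD (0.24, 1.72), ρ = −0.87)` —
  substantial, genuinely heterogeneous follow-up (~60% of subjects are
  censored before their event);
* case mix `x_ij = b_i + w_ij`, `b_i ~ N(0, 0.056)`,
  `w_ij ~ N(0, 0.224)`, true coefficient 1 — calibrated to the linear
  predictor of a real case-mix model;
* events `Weibull(shape 0.94, rate 0.032)` under proportional hazards,
  survival convention `exp(−rate·t^shape)`. An import-time self-check
  asserts this convention yields the intended ~28% one-year baseline
  mortality — under the scale-parameter convention the same numbers would
  imply essentially no events, so the check pins the parameterization;
* power scenarios multiply the event rate by a log-normal center frailty
  `exp(u_i)`, `u_i ~ N(0, σ²)`, σ² ∈ {0.15, 0.30};
* the non-PH scenario draws frailties with σ² = 0.15 on the rates and
  solves each center's Weibull shape so `rate_i·12^{shape_i}` is constant:
  centers differ over time but share the 12-month baseline survival, so
  the scenario is null at the horizon while violating proportionality;
* the common-censoring scenario uses a single Weibull follow-up law. Its
  published rate parameter `exp(0.8)` would censor ~97% of subjects within
  weeks, which contradicts the scenario's reported ~58% censoring and the
  base mean log-rate of −4.8; it is almost certainly a sign typo for
  `exp(−4.8)`. The printed value remains the scenario default with a
  `common_lograte` override, and the reproduction script runs the
  corrected value, which recovers both the reported censoring fraction and
  the reported coverage.

Each replication is analyzed by the same public pipeline a real cohort
would use (truncate, fit pooled benchmark on the single covariate,
per-center reverse-KM, `p_ij`, per-center Z), classification at ±1.96, and
results are pooled across replications. Replication seeds are spawned from
a master seed (independent streams; failed replications are logged and
re-seeded, never dropped). The censoring percentage reported is the
pre-truncation `P(C < T̃)`, which is the quantity the ~60% figure refers
to; post-truncation censoring within 12 months is lower (~28%).

What the generator does **not** emulate: real case-mix vectors (a single
Gaussian surrogate for the linear predictor), informative or
covariate-dependent censoring, reporting-lag bias (deaths reported faster
than follow-up), competing risks, and within-center correlation beyond the
frailty. Passing the simulation suite therefore demonstrates calibration
and power of the *statistical machinery* under a realistic size/censoring
regime, not robustness to data-quality pathologies — the follow-up funnel
exists precisely because those pathologies occur.

At the published sizes (50 replications × 300 centers ≈ 3M subjects for
the base-like scenarios; 500 replications for the small-center variants)
a scenario runs in 15-45 s on one CPU, so the reproduction script and the
acceptance tests run everything at full published scale.

## Pseudo-observation comparator

Implemented as a diagnostic, never a gate. Jackknife pseudo-values of the
pooled KM death probability at τ are regressed on case mix by OLS —
identity link with an independence working correlation makes the GEE
estimator coincide with OLS, and makes center aggregation of fitted values
linear, which the bootstrap aggregation requires. Raw residuals are
resampled i.i.d. (the "no center effects" null); each center's prediction
interval is the 2.5/97.5% range of its re-aggregated mean over 1000
bootstrap draws, and a Z-score is derived from the interval endpoints
under normality. The residual construction in the source procedure is not
fully specified; resampling raw rather than variance-standardized
residuals is this package's documented choice (with identity link and
homoskedastic OLS the two coincide up to a constant factor that cancels in
the interval). The known failure mode — interval width tracks pooled
rather than center-specific follow-up — reproduces clearly: pseudo
Z-scores in the top censoring quintile are several times more dispersed
than in the bottom quintile, while funnel Z-scores stay flat.

## Known limitations

* Comparison happens at a single pre-specified horizon; different horizons
  can rank centers differently.
* No overdispersion adjustment: the limits assume the per-center test has
  exact level α, and true between-center heterogeneity (the thing one
  wants to detect) is indistinguishable from case-mix model inadequacy.
* Benchmark uncertainty is ignored; defensible at registry scale, not for
  a handful of small centers.
* The exact Poisson-binomial test uses the doubled-tail convention, which
  is conservative near the center of the null distribution.
* Recurrent events and left truncation fit the counting-process notation
  but are not exercised by the current implementation or tests.
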