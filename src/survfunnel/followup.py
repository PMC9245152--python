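"""The follow-up (completeness) funnel: the mirror image of the mortality
funnel, obtained by reversing the roles of event and censoring.

Here the "event" is a loss to follow-up strictly before the horizon, and
the null hypothesis is that every center's follow-up distribution equals
the pooled one. Each patient's probability of an *observed* loss is

    p~_ij = P(C_ij < T_ij, C_ij < tau)
          = sum_{s <= tau} hC(s) G(s-) S_ij(s-),

summing over the jump times of the *pooled* reverse-KM censoring hazard hC
(under the null the follow-up law is common), while S_ij is the subject's
event-free survival from a *center-stratified* proportional-hazards model —
mortality may genuinely differ between centers, so center-specific
baselines (shared case-mix coefficients) are used, with the pooled baseline
as fallback for centers with fewer than two events. The O/E/V/Z machinery
and funnel geometry are identical to the mortality funnel; "under" now
means excess loss to follow-up.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import BenchmarkModel, fit_benchmark
from .censoring import CensoringCurve, censoring_curves
from .cohort import CENTER, Cohort
from .engine import FunnelConfig, model_linear_predictors, summarize_counts

__all__ = [
    "compute_followup_probability",
    "followup_probabilities",
    "followup_center_summary",
    "followup_analysis",
]


def compute_followup_probability(
    model: BenchmarkModel,
    pooled_censoring: CensoringCurve,
    x,
    tau: float,
    center=None,
) -> float:
    """p~_ij for a single subject (reference implementation).

    Direct sum over the pooled censoring-jump times with left limits of
    both G and the subject's center-stratified survival.
    """
    if model.strata is not None and center is not None and center not in model.strata:
        bt, bj = model.baseline_times, model.baseline_jumps  # documented fallback
    else:
        bt, bj = model.stratum_baseline(center)
    keep = bt <= tau
    bt, bj = bt[keep], bj[keep]
    risk = float(np.exp(model.linear_predictor(np.asarray(x, dtype=float))))
    ck = pooled_censoring.times <= tau
    ct, ch = pooled_censoring.times[ck], pooled_censoring.hazard_jumps[ck]
    if ct.size == 0:
        return 0.0
    g_left = np.asarray(pooled_censoring.left_limit(ct))
    # S_ij(s-): product of (1 - min(1, h0 e^theta)) over baseline jumps u < s
    factors = 1.0 - np.minimum(1.0, risk * bj)
    cum = np.concatenate([[1.0], np.cumprod(factors)])
    s_left = cum[np.searchsorted(bt, ct, side="left")]
    return float(np.clip((ch * g_left * s_left).sum(), 0.0, 1.0))


def followup_probabilities(
    model: BenchmarkModel,
    pooled_censoring: CensoringCurve,
    cohort: Cohort,
) -> np.ndarray:
    """Per-subject loss-to-follow-up probabilities p~_ij.

    Vectorized via exact telescoping of the product-limit G between the
    subject's survival-jump times: within a segment where S is constant,
    sum hC(s) G(s-) = G(a) - G(b), so
    p~ = sum_k S(e_k) [G(e_k) - G(e_{k+1})] over baseline-event segments.
    """
    tau = cohort.horizon
    probs = np.empty(cohort.n)
    centers = cohort.data[CENTER].to_numpy()
    lp_all = model_linear_predictors(model, cohort)
    for center in pd.unique(centers):
        idx = np.flatnonzero(centers == center)
        bt, bj = model.stratum_baseline(center)
        keep = bt <= tau
        bt, bj = bt[keep], bj[keep]
        risk = np.exp(lp_all[idx])
        bounds = np.concatenate([[0.0], bt, [tau]])
        g_at = np.asarray(pooled_censoring.G(bounds))
        dg = -np.diff(g_at)  # mass lost to follow-up in each segment
        z = np.minimum(1.0, risk[:, None] * bj[None, :])
        s_at = np.concatenate(
            [np.ones((idx.size, 1)), np.cumprod(1.0 - z, axis=1)], axis=1
        )
        probs[idx] = np.clip((s_at * dg[None, :]).sum(axis=1), 0.0, 1.0)
    return probs


def followup_center_summary(
    probs: np.ndarray, cohort: Cohort, config: FunnelConfig | None = None
) -> pd.DataFrame:
    """Per-center follow-up-funnel results.

    O~ counts losses strictly before the horizon (patients administratively
    censored at exactly tau completed follow-up and are not losses); p0 is
    the overall loss fraction.
    """
    config = config or FunnelConfig()
    observed = (cohort.statuses == 0) & (cohort.times < cohort.horizon)
    p0 = float(observed.mean())
    return summarize_counts(cohort, probs, observed, p0, config)


def followup_analysis(
    cohort: Cohort,
    config: FunnelConfig | None = None,
    covariates=None,
    model: BenchmarkModel | None = None,
):
    """End-to-end follow-up funnel: center-stratified event model, pooled
    reverse-KM censoring, p~_ij and the center table.

    Returns ``(results, model, pooled_curve)``.
    """
    config = config or FunnelConfig()
    if model is None:
        model = fit_benchmark(cohort, covariates, stratify_by_center=True)
    pooled = censoring_curves(cohort, pooled=True)
    probs = followup_probabilities(model, pooled, cohort)
    results = followup_center_summary(probs, cohort, config)
    return results, model, pooled
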