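"""The funnel engine: event probabilities, O/E/V/Z inference, control limits.

Under the null hypothesis that a center performs according to the
benchmark, each patient's observed-event indicator within the horizon is
Bernoulli with probability

    p_ij = P(T_ij < C_ij, T_ij < tau)
         = sum_{s <= tau} h0(s) e^{beta'x_ij} S_ij(s-) G_i(s-),

the sum running over the Breslow baseline jump times, with S_ij the
subject's event-free survival under the benchmark and G_i the center's
follow-up (reverse-KM) curve, both taken as left limits — the patient must
be event-free *and* still under follow-up just before s. The center's
observed count O_i then has a Poisson-binomial null law with mean
E_i = sum p_ij and variance V_i = sum p_ij (1 - p_ij); Z_i =
(O_i - E_i)/sqrt(V_i), and the funnel plots O_i/E_i against the effective
sample size (E_i^2/V_i)(1-p0)/p0, with control limits
1 +/- z_{1-a/2} sqrt((1-p0)/p0)/sqrt(x).

Two survival plug-ins are offered: ``product_limit`` (default)
S_ij(s-) = prod_{u<s} (1 - min(1, h0(u) e^{beta'x})), which makes the
no-censoring identity p_ij = 1 - S_ij(tau) exact by telescoping, and
``exp_cumhaz`` S_ij(s-) = exp(-H_ij(s-)) as a sensitivity option.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkModel
from .censoring import CensoringCurve
from .cohort import CENTER, STATUS, TIME, Cohort

__all__ = [
    "FunnelConfig",
    "compute_event_probability",
    "event_probabilities",
    "center_summary",
    "poisson_binomial_pvalue",
    "effective_sample_size",
    "funnel_limits",
    "funnel_analysis",
]


@dataclasses.dataclass
class FunnelConfig:
    """Analysis-level options shared across the funnel computations.

    ``alpha`` is the nominal two-sided level per center; ``alpha_adjusted``
    the multiplicity-adjusted level (default Bonferroni, alpha / n_centers,
    resolved when the number of centers is known). Exact Poisson-binomial
    p-values are computed for centers with at most ``exact_threshold``
    subjects (the dynamic program is quadratic); larger centers use the
    normal approximation, which is accurate there anyway.
    """

    alpha: float = 0.05
    alpha_adjusted: float | None = None
    survival_form: str = "product_limit"
    exact_threshold: int = 5000
    pooled_censoring: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_adjusted is not None and not 0 < self.alpha_adjusted <= self.alpha:
            raise ValueError("must have 0 < alpha_adjusted <= alpha")
        if self.survival_form not in ("product_limit", "exp_cumhaz"):
            raise ValueError(f"unknown survival_form {self.survival_form!r}")

    def resolve_adjusted(self, n_centers: int) -> float:
        if self.alpha_adjusted is not None:
            return self.alpha_adjusted
        return self.alpha / max(n_centers, 1)


# ---------------------------------------------------------------------------
# per-patient event probabilities
# ---------------------------------------------------------------------------

def _baseline_upto(model_times, model_jumps, tau):
    keep = model_times <= tau
    return model_times[keep], model_jumps[keep]


def model_linear_predictors(model: BenchmarkModel, cohort: Cohort) -> np.ndarray:
    """beta' x_ij for every subject, selecting the model's own covariates
    from the cohort (a null model yields zeros)."""
    if not model.covariate_names:
        return np.zeros(cohort.n)
    missing = [c for c in model.covariate_names if c not in cohort.data.columns]
    if missing:
        raise ValueError(f"cohort lacks model covariates {missing}")
    X = cohort.data[model.covariate_names].to_numpy(dtype=float)
    return np.atleast_1d(model.linear_predictor(X))


def _probs_dense(bt, bj, lp, curve: CensoringCurve | None, form: str) -> np.ndarray:
    """Reference path: direct per-subject sum over the baseline grid."""
    lp = np.atleast_1d(np.asarray(lp, dtype=float))
    if bt.size == 0:
        return np.zeros(lp.size)
    risk = np.exp(lp)
    z = np.minimum(1.0, risk[:, None] * bj[None, :])  # per-jump hazard, clipped
    if form == "product_limit":
        s_left = np.cumprod(1.0 - z, axis=1)
        s_left = np.concatenate([np.ones((lp.size, 1)), s_left[:, :-1]], axis=1)
    else:  # exp_cumhaz
        H = np.cumsum(risk[:, None] * bj[None, :], axis=1)
        H_left = np.concatenate([np.zeros((lp.size, 1)), H[:, :-1]], axis=1)
        s_left = np.exp(-H_left)
    g_left = np.ones(bt.size) if curve is None else np.asarray(curve.left_limit(bt))
    p = (z * s_left * g_left[None, :]).sum(axis=1)
    return np.clip(p, 0.0, 1.0)


_SERIES_ORDER = 4
_SERIES_TOL = 1e-8


def _probs_fast(bt, bj, lp, curve: CensoringCurve | None, tau: float):
    """Segment-telescoped evaluation for the product-limit form.

    Between consecutive jumps of G the integrand telescopes exactly:
    sum_{s in (a, b]} h0(s) e^theta S(s-) = S(a) - S(b), so
    p = sum_k G(c_k) [S(c_k) - S(c_{k+1})] over the censoring-jump segments.
    log S(t) = sum_{u<=t} log1p(-h0(u) e^theta) is evaluated by its power
    series in h0 e^theta truncated at order 4; for a subject whose largest
    per-jump hazard is z the truncation error is at most m * z^5 / 5.
    Subjects whose bound exceeds the tolerance come back NaN (the caller
    recomputes them on the dense path), so every returned value is exact to
    well below statistical resolution.
    """
    lp = np.atleast_1d(np.asarray(lp, dtype=float))
    if bt.size == 0:
        return np.zeros(lp.size)
    zj = bj.max() * np.exp(lp)
    bad = (zj >= 0.1) | (bt.size * zj ** (_SERIES_ORDER + 1) / 5 > _SERIES_TOL)
    if bad.all():
        return None
    if curve is None or curve.times.size == 0:
        ctimes = np.empty(0)
        gvals = np.empty(0)
    else:
        keep = curve.times < tau
        ctimes, gvals = curve.times[keep], curve.survival[keep]
    bounds = np.concatenate([[0.0], ctimes, [tau]])
    gk = np.concatenate([[1.0], gvals])  # G on each segment (post-jump value)
    # cumulants H_r(t) = sum_{u<=t} h0(u)^r at the segment boundaries
    idx = np.searchsorted(bt, bounds, side="right") - 1
    log_s = np.zeros((lp.size, bounds.size))
    expo = np.exp(lp)
    powers = np.ones_like(bj)
    for r in range(1, _SERIES_ORDER + 1):
        powers = powers * bj
        cum = np.concatenate([[0.0], np.cumsum(powers)])
        h_at = cum[idx + 1]
        log_s -= (expo[:, None] ** r) * (h_at[None, :] / r)
    s = np.exp(log_s)
    p = ((s[:, :-1] - s[:, 1:]) * gk[None, :]).sum(axis=1)
    p = np.clip(p, 0.0, 1.0)
    p[bad] = np.nan
    return p


def compute_event_probability(
    model: BenchmarkModel,
    censoring: CensoringCurve | None,
    x,
    tau: float,
    survival_form: str = "product_limit",
    center=None,
) -> float:
    """p_ij for a single subject (reference implementation, exact).

    ``censoring=None`` means G identically 1 (no censoring), in which case
    the product-limit form returns exactly 1 - S_ij(tau).
    """
    bt, bj = _baseline_upto(*model.stratum_baseline(center), tau)
    lp = model.linear_predictor(np.asarray(x, dtype=float))
    return float(_probs_dense(bt, bj, np.atleast_1d(lp), censoring, survival_form)[0])


def event_probabilities(
    model: BenchmarkModel,
    curves: Mapping | CensoringCurve | None,
    cohort: Cohort,
    config: FunnelConfig | None = None,
) -> np.ndarray:
    """Per-subject event probabilities p_ij for a whole cohort.

    ``curves`` maps center labels to their follow-up curves (or is a single
    pooled curve, or None for no censoring). Uses the telescoped fast path
    when its error bound permits, the dense reference path otherwise; the
    two agree to ~1e-10 wherever both apply.
    """
    config = config or FunnelConfig()
    tau = cohort.horizon
    bt, bj = _baseline_upto(model.baseline_times, model.baseline_jumps, tau)
    if (bj < 0).any():
        raise ValueError("negative baseline hazard jump")
    lp_all = model_linear_predictors(model, cohort)
    probs = np.empty(cohort.n)
    centers = cohort.data[CENTER].to_numpy()
    for center in pd.unique(centers):
        idx = np.flatnonzero(centers == center)
        curve = curves.get(center) if isinstance(curves, Mapping) else curves
        lp = lp_all[idx]
        p = None
        if config.survival_form == "product_limit":
            p = _probs_fast(bt, bj, lp, curve, tau)
        if p is None:
            p = _probs_dense(bt, bj, lp, curve, config.survival_form)
        else:
            redo = np.isnan(p)
            if redo.any():
                p[redo] = _probs_dense(
                    bt, bj, lp[redo], curve, config.survival_form
                )
        probs[idx] = p
    return probs


# ---------------------------------------------------------------------------
# exact Poisson-binomial inference
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(p_vector) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_k) variables.

    Dynamic-programming convolution, O(n^2) time and O(n) space; stable
    because every intermediate value is a probability in [0, 1].
    """
    p_vector = np.asarray(p_vector, dtype=float)
    if ((p_vector < 0) | (p_vector > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pk in p_vector:
        pmf = np.convolve(pmf, [1.0 - pk, pk])
    return pmf


def poisson_binomial_pvalue(p_vector, o: int) -> float:
    """Exact two-sided p-value for an observed count under the
    Poisson-binomial null: doubled smaller tail, capped at 1 (no mid-p)."""
    p_vector = np.asarray(p_vector, dtype=float)
    o = int(o)
    if not 0 <= o <= p_vector.size:
        raise ValueError(f"observed count {o} outside [0, {p_vector.size}]")
    pmf = poisson_binomial_pmf(p_vector)
    lower = float(pmf[: o + 1].sum())
    upper = float(pmf[o:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def effective_sample_size(E: float, V: float, p0: float) -> float:
    """(E^2/V) (1-p0)/p0: the precision axis rescaled so that a center with
    homogeneous p_ij = p0 sits exactly at its raw size n_i."""
    if V <= 0:
        raise ValueError("V must be positive")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1 (degenerate cohort)")
    return (E * E / V) * (1.0 - p0) / p0


def funnel_limits(
    x_grid,
    p0: float,
    alpha: float = 0.05,
    alpha_adjusted: float | None = None,
) -> pd.DataFrame:
    """Control-limit ordinates on the O/E axis over the effective-sample-size
    axis: 1 +/- z sqrt((1-p0)/p0) / sqrt(x), at the nominal and (optionally)
    multiplicity-adjusted levels."""
    x = np.asarray(x_grid, dtype=float)
    if (x <= 0).any():
        raise ValueError("x grid must be positive")
    scale = np.sqrt((1.0 - p0) / p0) / np.sqrt(x)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out = pd.DataFrame({"x": x, "lower": 1.0 - z * scale, "upper": 1.0 + z * scale})
    if alpha_adjusted is not None:
        za = stats.norm.ppf(1.0 - alpha_adjusted / 2.0)
        out["lower_adj"] = 1.0 - za * scale
        out["upper_adj"] = 1.0 + za * scale
    return out


# ---------------------------------------------------------------------------
# per-center summaries
# ---------------------------------------------------------------------------

def _classify(z: float, threshold: float) -> str:
    # excess events (mortality / losses) -> "under"(performing)
    if z > threshold:
        return "under"
    if z < -threshold:
        return "over"
    return "target"


def summarize_counts(
    cohort: Cohort,
    probs: np.ndarray,
    observed: np.ndarray,
    p0: float,
    config: FunnelConfig,
) -> pd.DataFrame:
    """Shared O/E/V/Z machinery for the mortality and follow-up funnels."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (cohort.n,):
        raise ValueError("need one probability per subject")
    if np.isnan(probs).any() or ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    centers = cohort.data[CENTER].to_numpy()
    labels = pd.unique(centers)
    alpha_adj = config.resolve_adjusted(labels.size)
    z_a = stats.norm.ppf(1.0 - config.alpha / 2.0)
    z_aa = stats.norm.ppf(1.0 - alpha_adj / 2.0)
    rows = []
    for center in labels:
        idx = np.flatnonzero(centers == center)
        p = probs[idx]
        o = int(observed[idx].sum())
        e = float(p.sum())
        v = float((p * (1.0 - p)).sum())
        row = {
            "center": center,
            "n": idx.size,
            "O": o,
            "E": e,
            "V": v,
            "oe_ratio": o / e if e > 0 else np.nan,
            "tested": e > 0 and v > 0,
        }
        if row["tested"]:
            z = (o - e) / np.sqrt(v)
            row["Z"] = z
            if idx.size <= config.exact_threshold:
                row["exact_p"] = poisson_binomial_pvalue(p, o)
            else:
                row["exact_p"] = float(2.0 * stats.norm.sf(abs(z)))
            row["ess"] = (
                effective_sample_size(e, v, p0) if 0.0 < p0 < 1.0 else np.nan
            )
            row["precision"] = e * e / v
            row["class_alpha"] = _classify(z, z_a)
            row["class_alpha_adj"] = _classify(z, z_aa)
        else:
            row.update(
                Z=np.nan, exact_p=np.nan, ess=np.nan, precision=np.nan,
                class_alpha="untested", class_alpha_adj="untested",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs.update(
        p0=p0, alpha=config.alpha, alpha_adjusted=alpha_adj, tau=cohort.horizon
    )
    return out


def center_summary(
    probs: np.ndarray, cohort: Cohort, config: FunnelConfig | None = None
) -> pd.DataFrame:
    """Per-center mortality-funnel results.

    O counts observed events within the horizon; p0 (the effective-sample-
    size scale) is the overall event fraction after truncation. Centers
    with E = 0 (or V = 0) are reported but flagged untested.
    """
    config = config or FunnelConfig()
    observed = (cohort.statuses == 1) & (cohort.times <= cohort.horizon)
    p0 = float(observed.mean())
    return summarize_counts(cohort, probs, observed, p0, config)


def funnel_analysis(
    cohort: Cohort,
    config: FunnelConfig | None = None,
    covariates=None,
    model: BenchmarkModel | None = None,
):
    """End-to-end mortality funnel: fit (or accept) the benchmark, estimate
    per-center follow-up curves, compute p_ij and the center table.

    Returns ``(results, model, curves)``.
    """
    from .benchmark import fit_benchmark
    from .censoring import censoring_curves

    config = config or FunnelConfig()
    if model is None:
        model = fit_benchmark(cohort, covariates)
    curves = censoring_curves(cohort, pooled=config.pooled_censoring)
    probs = event_probabilities(model, curves, cohort, config)
    results = center_summary(probs, cohort, config)
    return results, model, curves
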