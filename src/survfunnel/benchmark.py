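"""The benchmark proportional-hazards model.

The benchmark embodies average performance across all centers: a single Cox
model h_ij(t) = h0(t) exp(beta' x_ij) fitted to the pooled data,
disregarding center identity, with the Breslow estimate of the baseline
cumulative-hazard jumps h0(s). The fitted coefficients and baseline are
treated as *known* downstream — no benchmark uncertainty is propagated,
since it is negligible relative to single-center sampling noise and,
conceptually, the (estimated) benchmark *is* the target.

The fit is a straight Newton maximization of the Breslow partial
likelihood, vectorized over subjects; ``lifelines`` produces identical
estimates on the same data (checked in the test suite) but the in-house
routine exposes the Breslow jumps directly, supports center-stratified
baselines with a pooled fallback for tiny strata, and is fast enough to be
refit thousands of times inside the simulation harness.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CENTER, STATUS, TIME, Cohort


class FitError(RuntimeError):
    """The benchmark model could not be fitted."""


class ConvergenceError(FitError):
    """Newton iterations failed to converge."""


@dataclasses.dataclass
class BenchmarkModel:
    """A (fitted or imported) benchmark: coefficients + Breslow baseline.

    ``baseline_times`` are strictly increasing; ``baseline_jumps`` are the
    nonnegative Breslow increments h0(s) of the cumulative baseline hazard.
    When center-stratified, ``strata`` maps center labels to per-center
    ``(times, jumps)`` baselines sharing the same ``beta``, and the pooled
    baseline serves as the documented fallback for strata with fewer than
    two events.
    """

    beta: np.ndarray
    covariate_names: list[str]
    baseline_times: np.ndarray
    baseline_jumps: np.ndarray
    strata: dict | None = None
    beta_se: np.ndarray | None = None
    loglik: float | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_jumps = np.asarray(self.baseline_jumps, dtype=float)
        if self.beta.size != len(self.covariate_names):
            raise FitError("beta length does not match covariate names")
        t, h = self.baseline_times, self.baseline_jumps
        if t.shape != h.shape:
            raise FitError("baseline times and jumps differ in length")
        if t.size and (np.diff(t) <= 0).any():
            raise FitError("baseline times must be strictly increasing")
        if (h < 0).any():
            raise FitError("baseline hazard jumps must be nonnegative")

    # -- predictions -------------------------------------------------------
    def linear_predictor(self, x) -> np.ndarray | float:
        """beta' x for one covariate vector or a (n, p) matrix."""
        x = np.asarray(x, dtype=float)
        p = self.beta.size
        if x.ndim == 1 and x.size != p or x.ndim == 2 and x.shape[1] != p:
            raise FitError(
                f"covariate vector of length {x.shape[-1]} does not match p={p}"
            )
        return x @ self.beta

    def stratum_baseline(self, center) -> tuple[np.ndarray, np.ndarray]:
        """Baseline (times, jumps) for a center; pooled fallback when the
        center's stratum was too small to estimate its own baseline."""
        if self.strata is not None and center in self.strata:
            return self.strata[center]
        return self.baseline_times, self.baseline_jumps

    def cumulative_baseline_hazard(self, t, center=None) -> np.ndarray | float:
        """H0(t) = sum of jumps at times <= t (right-continuous step)."""
        times, jumps = (
            (self.baseline_times, self.baseline_jumps)
            if center is None
            else self.stratum_baseline(center)
        )
        cum = np.concatenate([[0.0], np.cumsum(jumps)])
        idx = np.searchsorted(times, np.asarray(t, dtype=float), side="right")
        return cum[idx]

    # -- serialization -----------------------------------------------------
    def to_csv(self, coef_path, baseline_path) -> None:
        pd.DataFrame({"name": self.covariate_names, "value": self.beta}).to_csv(
            coef_path, index=False
        )
        pd.DataFrame(
            {"time": self.baseline_times, "jump": self.baseline_jumps}
        ).to_csv(baseline_path, index=False)


def load_benchmark(coef_path, baseline_path) -> BenchmarkModel:
    """Load a serialized benchmark (see :meth:`BenchmarkModel.to_csv`)."""
    coef = pd.read_csv(coef_path)
    base = pd.read_csv(baseline_path)
    return import_benchmark(
        dict(zip(coef["name"].astype(str), coef["value"].astype(float))),
        base[["time", "jump"]].to_numpy(dtype=float),
    )


def import_benchmark(
    coefficients: Mapping[str, float], baseline
) -> BenchmarkModel:
    """Build a benchmark from externally supplied coefficients and a
    (time, jump) baseline table, e.g. a frozen target from a previous
    benchmarking cycle. Jump times beyond the analysis horizon are accepted;
    they simply never contribute to event probabilities."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        times = jumps = np.empty(0)
    else:
        if baseline.ndim != 2 or baseline.shape[1] != 2:
            raise FitError("baseline must be a (time, jump) table")
        times, jumps = baseline[:, 0], baseline[:, 1]
    return BenchmarkModel(
        beta=np.array(list(coefficients.values()), dtype=float),
        covariate_names=list(coefficients.keys()),
        baseline_times=times,
        baseline_jumps=jumps,
    )


# ---------------------------------------------------------------------------
# Breslow partial-likelihood machinery
# ---------------------------------------------------------------------------

def _stratum_quantities(time, status, X, beta):
    """Log partial likelihood, score and information for one stratum.

    Breslow tie handling: tied events share the full risk set.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = status[order].astype(bool)
    x = X[order]
    n, p = x.shape
    eta = x @ beta
    r = np.exp(eta)
    # suffix sums over the risk set {i : t_i >= s}
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((r[:, None, None] * x[:, :, None] * x[:, None, :])[::-1], axis=0)[
        ::-1
    ]
    et = t[d]
    if et.size == 0:
        return 0.0, np.zeros(p), np.zeros((p, p)), (np.empty(0), np.empty(0))
    ut, inv = np.unique(et, return_inverse=True)
    dcount = np.bincount(inv).astype(float)
    start = np.searchsorted(t, ut, side="left")
    m0 = s0[start]
    m1 = s1[start] / m0[:, None]
    m2 = s2[start] / m0[:, None, None]
    ll = float(eta[d].sum() - dcount @ np.log(m0))
    score = x[d].sum(axis=0) - dcount @ m1
    info = np.einsum("k,kij->ij", dcount, m2 - m1[:, :, None] * m1[:, None, :])
    baseline = (ut, dcount / m0)
    return ll, score, info, baseline


def _cox_fit(time, status, X, groups=None, tol=1e-9, max_iter=100):
    """Newton maximization of the (stratified) Breslow partial likelihood.

    Returns (beta, cov, loglik, n_iter, baselines) where ``baselines`` maps
    each stratum label to its Breslow (times, jumps) at the fitted beta.
    Convergence: relative change in log partial likelihood < ``tol``.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if status.sum() == 0:
        raise FitError("no events in the data; benchmark cannot be fitted")
    if groups is None:
        labels = [None]
        idxs = [np.arange(n)]
    else:
        groups = np.asarray(groups)
        labels, inv = np.unique(groups, return_inverse=True)
        idxs = [np.flatnonzero(inv == k) for k in range(labels.size)]
        labels = list(labels)

    def quantities(beta):
        ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
        bases = {}
        for lab, idx in zip(labels, idxs):
            l, s, i, b = _stratum_quantities(time[idx], status[idx], X[idx], beta)
            ll += l
            score += s
            info += i
            bases[lab] = b
        return ll, score, info, bases

    beta = np.zeros(p)
    ll, score, info, bases = quantities(beta)
    n_iter = 0
    if p == 0:
        cov = np.zeros((0, 0))
        return beta, cov, ll, n_iter, bases
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "singular information matrix (constant or collinear covariates)"
            ) from exc
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new, bases_new = quantities(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter} (loglik {ll:.6g})"
            )
        delta = ll_new - ll
        beta, ll, score, info, bases = cand, ll_new, score_new, info_new, bases_new
        if abs(delta) < tol * (abs(ll) + tol):
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} Newton iterations "
            f"(last loglik change {delta:.3e})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, n_iter, bases


def fit_benchmark(
    cohort: Cohort,
    covariates: Sequence[str] | None = None,
    stratify_by_center: bool = False,
    tol: float = 1e-9,
    max_iter: int = 100,
    min_stratum_events: int = 2,
) -> BenchmarkModel:
    """Fit the benchmark Cox model on a (truncated) cohort.

    With ``covariates=None`` all cohort covariates enter; an empty list fits
    the null model, whose Breslow baseline reduces to the Nelson-Aalen
    increments. With ``stratify_by_center`` a separate baseline is estimated
    per center (shared beta); centers with fewer than ``min_stratum_events``
    events fall back to the pooled baseline, computed at the same beta.
    """
    covariates = list(cohort.covariate_names if covariates is None else covariates)
    unknown = [c for c in covariates if c not in cohort.data.columns]
    if unknown:
        raise FitError(f"unknown covariates {unknown}")
    X = (
        cohort.data[covariates].to_numpy(dtype=float)
        if covariates
        else np.empty((cohort.n, 0))
    )
    if np.isnan(X).any():
        raise FitError("missing covariate values; impute before fitting")
    time, status = cohort.times, cohort.statuses
    groups = cohort.data[CENTER].to_numpy() if stratify_by_center else None
    beta, cov, ll, n_iter, bases = _cox_fit(
        time, status, X, groups=groups, tol=tol, max_iter=max_iter
    )
    se = np.sqrt(np.diag(cov)) if cov.size else np.empty(0)
    if not stratify_by_center:
        bt, bj = bases[None]
        strata = None
    else:
        # pooled fallback baseline at the stratified beta
        _, _, _, pooled = _stratum_quantities(time, status, X, beta)
        bt, bj = pooled
        strata = {
            lab: b for lab, b in bases.items() if (b[1].size and b[1].size >= 0)
        }
        # keep only strata with enough events for a stable per-center baseline
        events_per = cohort.data.groupby(CENTER)[STATUS].sum()
        strata = {
            lab: b
            for lab, b in strata.items()
            if int(events_per.get(lab, 0)) >= min_stratum_events
        }
    return BenchmarkModel(
        beta=beta,
        covariate_names=covariates,
        baseline_times=bt,
        baseline_jumps=bj,
        strata=strata,
        beta_se=se,
        loglik=ll,
        n_iter=n_iter,
    )
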