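"""Censoring (follow-up) distributions by reverse Kaplan-Meier.

The probability of still being under follow-up at time t, G(t), is the
product-limit estimator applied with the roles of event and censoring
swapped: a censoring before the horizon counts as the "event" (a loss to
follow-up), a death removes the subject from the risk set. Two conventions
matter and are fixed here:

* administrative truncation at exactly the horizon (time == tau, status 0)
  is *complete* follow-up, not a loss — such subjects stay in the risk set
  through tau and contribute no hazard jump;
* at tied times deaths are removed from the risk set before censorings
  (the standard Kaplan-Meier tie convention), so a loss at time t sees the
  risk set with same-time deaths already gone.

Curves are estimated per center (G_i) for the mortality funnel and pooled
(G) for the follow-up funnel, and extend as constants beyond the last
observed time up to the horizon.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CENTER, Cohort


class CensoringError(ValueError):
    """Invalid input to censoring estimation."""


@dataclasses.dataclass
class CensoringCurve:
    """A right-continuous, non-increasing step function G with G(0) = 1.

    ``times`` are the (strictly increasing) jump times, ``hazard_jumps``
    the discrete hazards hC(s) in [0, 1], and ``survival`` the post-jump
    values G(s) = prod_{u<=s} (1 - hC(u)).
    """

    times: np.ndarray
    hazard_jumps: np.ndarray
    survival: np.ndarray
    horizon: float
    scope: str = "center"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hazard_jumps = np.asarray(self.hazard_jumps, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if not (self.times.shape == self.hazard_jumps.shape == self.survival.shape):
            raise CensoringError("times/hazard_jumps/survival length mismatch")
        if self.times.size:
            if (np.diff(self.times) <= 0).any():
                raise CensoringError("jump times must be strictly increasing")
            if ((self.hazard_jumps < 0) | (self.hazard_jumps > 1)).any():
                raise CensoringError("hazard jumps must lie in [0, 1]")
            if ((self.survival < 0) | (self.survival > 1)).any():
                raise CensoringError("survival values must lie in [0, 1]")
            if (np.diff(self.survival) > 1e-12).any():
                raise CensoringError("G must be non-increasing")

    def G(self, t) -> np.ndarray | float:
        """G(t), right-continuous (value after any jump at t); G(0) = 1."""
        vals = np.concatenate([[1.0], self.survival])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return vals[idx]

    def left_limit(self, t) -> np.ndarray | float:
        """G(t-), the value just before t; G(0-) = 1.

        This is the evaluation the event-probability integrand requires:
        being still under follow-up *just before* an event at t.
        """
        vals = np.concatenate([[1.0], self.survival])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        return vals[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "hazard_jump": self.hazard_jumps, "G": self.survival}
        )


def reverse_km(
    time, status, horizon: float, scope: str = "center"
) -> CensoringCurve:
    """Reverse Kaplan-Meier estimate of the follow-up curve G.

    ``status`` uses the cohort convention (1 = death, 0 = censored); losses
    are censorings strictly before the horizon. Deaths at a tied time are
    removed from the risk set before the loss is counted.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if time.size == 0:
        raise CensoringError("no subjects")
    loss = (status == 0) & (time < horizon)
    ut, n_loss = np.unique(time[loss], return_counts=True)
    n_loss = n_loss.astype(float)
    if ut.size == 0:
        return CensoringCurve(
            np.empty(0), np.empty(0), np.empty(0), float(horizon), scope
        )
    srt = np.sort(time)
    at_risk = time.size - np.searchsorted(srt, ut, side="left")
    death_times = np.sort(time[status == 1])
    deaths_at = np.searchsorted(death_times, ut, side="right") - np.searchsorted(
        death_times, ut, side="left"
    )
    denom = at_risk - deaths_at
    if (denom <= 0).any():
        # every remaining subject dies at that time: no one left to lose
        keep = denom > 0
        ut, n_loss, denom = ut[keep], n_loss[keep], denom[keep]
    haz = n_loss / denom
    surv = np.cumprod(1.0 - haz)
    return CensoringCurve(ut, haz, surv, float(horizon), scope)


def censoring_curves(cohort: Cohort, pooled: bool = False):
    """Per-center follow-up curves {center: G_i}, or the single pooled G.

    Per-center curves are the default for the mortality funnel, however
    small the center; ``pooled=True`` provides the pooled-curve fallback
    (and the pooled G used by the follow-up funnel).
    """
    if pooled:
        return reverse_km(cohort.times, cohort.statuses, cohort.horizon, scope="pooled")
    out = {}
    for center, g in cohort.data.groupby(CENTER, sort=False):
        out[center] = reverse_km(
            g["time"].to_numpy(dtype=float),
            g["status"].to_numpy(),
            cohort.horizon,
            scope="center",
        )
    return out


def km_survival(time, status, at: float) -> float:
    """Plain Kaplan-Meier survival estimate S(at) (status 1 = event).

    Used by the pseudo-observation comparator; same tie convention as
    :func:`reverse_km` with roles swapped.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if time.size == 0:
        raise CensoringError("no subjects")
    if at > time.max():
        raise CensoringError(f"evaluation time {at} beyond last observed time")
    et, d = np.unique(time[(status == 1) & (time <= at)], return_counts=True)
    if et.size == 0:
        return 1.0
    srt = np.sort(time)
    at_risk = time.size - np.searchsorted(srt, et, side="left")
    return float(np.prod(1.0 - d.astype(float) / at_risk))
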