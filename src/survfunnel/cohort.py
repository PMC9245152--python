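"""Patient-level multi-center survival data.

Containers and plumbing for the benchmarking pipeline: a validated
:class:`Cohort` of subjects (one row per patient: center label, follow-up
time, event status, case-mix covariates), delimited-text I/O with a
configurable column mapping, administrative truncation at the analysis
horizon, and the benchmarking-time missing-covariate imputation rule
(median / mode among patients with the favorable outcome).

Times are in whatever unit the horizon is stated in (months throughout the
examples); status is 1 for an observed event (death) and 0 for censoring.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CENTER = "center"
TIME = "time"
STATUS = "status"


class CohortError(ValueError):
    """Invalid cohort data or schema."""


class UnimputableError(CohortError):
    """A covariate cannot be imputed because it is missing for every
    favorable-outcome patient."""


@dataclasses.dataclass
class Cohort:
    """A validated multi-center cohort.

    Parameters
    ----------
    data
        One row per subject with columns ``center``, ``time``, ``status``
        and one numeric column per covariate (categorical case mix must be
        pre-expanded to indicator columns). Missing covariate values are
        NaN.
    covariate_names
        Ordered covariate column labels (may be empty).
    horizon
        The analysis horizon tau (> 0), in the same unit as ``time``.
    """

    data: pd.DataFrame
    covariate_names: list[str]
    horizon: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise CohortError(f"horizon must be positive, got {self.horizon}")
        required = [CENTER, TIME, STATUS, *self.covariate_names]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort data lacks columns {missing}")
        if len(self.data) == 0:
            raise CohortError("cohort has no subjects")
        t = self.data[TIME].to_numpy(dtype=float)
        if np.isnan(t).any():
            row = int(np.flatnonzero(np.isnan(t))[0])
            raise CohortError(f"non-numeric follow-up time in row {row}")
        if (t < 0).any():
            row = int(np.flatnonzero(t < 0)[0])
            raise CohortError(f"negative follow-up time in row {row}")
        s = self.data[STATUS].to_numpy()
        if not np.isin(s, (0, 1)).all():
            row = int(np.flatnonzero(~np.isin(s, (0, 1)))[0])
            raise CohortError(f"status must be 0 or 1; bad value in row {row}")
        self.data = self.data.reset_index(drop=True)
        self.covariate_names = list(self.covariate_names)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def center_ids(self) -> list:
        return list(pd.unique(self.data[CENTER]))

    @property
    def n_centers(self) -> int:
        return self.data[CENTER].nunique()

    @property
    def center_sizes(self) -> pd.Series:
        return self.data[CENTER].value_counts(sort=False)

    @property
    def times(self) -> np.ndarray:
        return self.data[TIME].to_numpy(dtype=float)

    @property
    def statuses(self) -> np.ndarray:
        return self.data[STATUS].to_numpy(dtype=int)

    def covariate_matrix(self) -> np.ndarray:
        """Subjects-by-covariates design matrix (no intercept)."""
        if not self.covariate_names:
            return np.empty((self.n, 0))
        return self.data[self.covariate_names].to_numpy(dtype=float)

    def summary(self) -> pd.DataFrame:
        """Per-center counts: size, events, losses before tau, horizon survivors."""
        tau = self.horizon
        d = self.data
        out = d.groupby(CENTER, sort=False).apply(
            lambda g: pd.Series(
                {
                    "n": len(g),
                    "events": int(((g[STATUS] == 1) & (g[TIME] <= tau)).sum()),
                    "losses": int(((g[STATUS] == 0) & (g[TIME] < tau)).sum()),
                    "complete": int(((g[STATUS] == 0) & (g[TIME] >= tau)).sum()),
                }
            ),
            include_groups=False,
        )
        return out.astype(int).reset_index()


def read_cohort(
    path,
    horizon: float,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
) -> Cohort:
    """Read a cohort from a delimited-text (CSV, header required) file.

    Parameters
    ----------
    path
        CSV file, UTF-8, one row per subject.
    horizon
        Analysis horizon tau; times are administratively truncated at it.
    schema
        Optional mapping from canonical names (``center``, ``time``,
        ``status``) to the file's column headers.
    covariates
        Covariate column names *as they appear in the file*. Defaults to
        every column not mapped to center/time/status.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path)
    colmap = {
        CENTER: schema.get(CENTER, CENTER),
        TIME: schema.get(TIME, TIME),
        STATUS: schema.get(STATUS, STATUS),
    }
    for canon, col in colmap.items():
        if col not in raw.columns:
            raise CohortError(f"mapped column {col!r} (for {canon!r}) not in file")
    if covariates is None:
        covariates = [c for c in raw.columns if c not in colmap.values()]
    else:
        missing = [c for c in covariates if c not in raw.columns]
        if missing:
            raise CohortError(f"covariate columns {missing} not in file")

    df = pd.DataFrame({CENTER: raw[colmap[CENTER]]})
    time = pd.to_numeric(raw[colmap[TIME]], errors="coerce")
    if time.isna().any():
        row = int(time.index[time.isna()][0]) + 2  # 1-based, counting header
        raise CohortError(f"unparseable follow-up time in file row {row}")
    if (time < 0).any():
        row = int(time.index[time < 0][0]) + 2
        raise CohortError(f"negative follow-up time in file row {row}")
    status = pd.to_numeric(raw[colmap[STATUS]], errors="coerce")
    bad = ~status.isin([0, 1])
    if bad.any():
        row = int(status.index[bad][0]) + 2
        raise CohortError(f"unknown status code in file row {row} (must be 0/1)")
    df[TIME] = time.astype(float)
    df[STATUS] = status.astype(int)
    for c in covariates:
        df[c] = pd.to_numeric(raw[c], errors="coerce")
    cohort = Cohort(df, list(covariates), float(horizon))
    return truncate_at_horizon(cohort, float(horizon))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV (canonical column names)."""
    cols = [CENTER, TIME, STATUS, *cohort.covariate_names]
    cohort.data[cols].to_csv(path, index=False)


def truncate_at_horizon(cohort: Cohort, tau: float | None = None) -> Cohort:
    """Administrative truncation ("stopped" follow-up) at the horizon.

    Every subject still under observation past ``tau`` is set to
    ``(time=tau, status=0)``; subjects with ``time <= tau`` are unchanged.
    Idempotent. All downstream estimation (benchmark fit, censoring curves,
    event counting) operates on truncated cohorts so that observed events
    and the overall event fraction p0 refer to the same window.
    """
    tau = float(cohort.horizon if tau is None else tau)
    if tau <= 0:
        raise CohortError(f"tau must be positive, got {tau}")
    df = cohort.data.copy()
    over = df[TIME].to_numpy(dtype=float) > tau
    df.loc[over, STATUS] = 0
    df.loc[over, TIME] = tau
    return Cohort(df, cohort.covariate_names, tau)


def favorable_outcome_mask(cohort: Cohort) -> np.ndarray:
    """Subjects with the favorable outcome: followed to the horizon alive
    (after truncation this is time == tau with status 0)."""
    return (cohort.times >= cohort.horizon) & (cohort.statuses == 0)


def impute_benchmarking(
    cohort: Cohort,
    categorical: Iterable[str] = (),
    favorable: Callable[[Cohort], np.ndarray] | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Benchmarking-time single imputation of missing case-mix values.

    Each missing numeric covariate value is replaced by the median of that
    covariate among patients with the observed favorable outcome (alive and
    under follow-up at the horizon); indicator/categorical columns (listed
    in ``categorical``) are replaced by the modal value among those
    patients. This deliberately makes incompletely registered patients look
    relatively healthy, lowering the center's expected count, so centers
    are not rewarded for incomplete registration.

    On even counts the median is the lower of the two middle order
    statistics (deterministic); modal ties break toward the smaller value.

    Returns the imputed cohort and a log with one row per covariate:
    ``covariate``, ``n_imputed``, ``fill_value``.
    """
    categorical = set(categorical)
    mask = favorable(cohort) if favorable is not None else favorable_outcome_mask(cohort)
    if not mask.any():
        raise UnimputableError("no patients with observed favorable outcome")
    df = cohort.data.copy()
    log_rows = []
    for name in cohort.covariate_names:
        col = df[name].to_numpy(dtype=float)
        miss = np.isnan(col)
        n_miss = int(miss.sum())
        if n_miss == 0:
            log_rows.append({"covariate": name, "n_imputed": 0, "fill_value": np.nan})
            continue
        donors = col[mask & ~miss]
        if donors.size == 0:
            raise UnimputableError(
                f"covariate {name!r} missing for all favorable-outcome patients"
            )
        if name in categorical:
            values, counts = np.unique(donors, return_counts=True)
            fill = float(values[np.argmax(counts)])  # ties -> smallest value
        else:
            srt = np.sort(donors)
            fill = float(srt[(srt.size - 1) // 2])  # lower median
        col[miss] = fill
        df[name] = col
        log_rows.append({"covariate": name, "n_imputed": n_miss, "fill_value": fill})
    log = pd.DataFrame(log_rows, columns=["covariate", "n_imputed", "fill_value"])
    return Cohort(df, cohort.covariate_names, cohort.horizon), log
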