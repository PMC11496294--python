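"""Test-retest reliability of longitudinal at-home measures.

A random-intercept model with participant and participant-by-fortnight
effects is fit to all assessments of one measure:

    y_{i,f,k} = mu + a_i + b_{i,f} + eps_{i,f,k}

The residual SD is the standard error of measurement sigma_m; the ICC is the
share of total variance explained by the participant and
participant-by-fortnight effects,

    ICC = (var_p + var_pf) / (var_p + var_pf + var_m)

interpretable as the expected correlation between two assessments of the same
participant within a fortnight.  The minimum detectable change is
MDC = 1.96 * sqrt(2) * sigma_m, the smallest within-person change
distinguishable from measurement noise at 95% confidence.

Reliability can be computed for individual assessments or for burst medians
(all assessments within a 7-day window collapsed to their median), the latter
trading assessment frequency for lower residual noise.  Estimation uses all
longitudinal data, so it tolerates arbitrary missingness patterns.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FORTNIGHT_DAYS

__all__ = [
    "VarianceComponents",
    "ReliabilityReport",
    "NonIdentifiableError",
    "summarize_bursts",
    "fit_variance_components",
    "compute_icc",
    "compute_sem",
    "compute_mdc",
    "reliability_report",
    "model_residuals",
]

MDC_FACTOR = 1.96 * math.sqrt(2.0)


class NonIdentifiableError(ValueError):
    """Design cannot separate the requested variance components."""


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance decomposition of a longitudinal measure."""

    var_participant: float
    var_participant_fortnight: float
    var_residual: float
    grand_mean: float
    n_participants: int
    n_observations: int

    def __post_init__(self):
        for name in ("var_participant", "var_participant_fortnight", "var_residual"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.var_participant + self.var_participant_fortnight + self.var_residual


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    sem: float
    mdc: float
    mdc_percent_of_mean: float
    mode: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "icc": self.icc,
                "sem": self.sem,
                "mdc": self.mdc,
                "mdc_percent_of_mean": self.mdc_percent_of_mean,
                "mode": self.mode,
            },
            indent=2,
        )


def summarize_bursts(records: pd.DataFrame, window_days: float = 7.0) -> pd.DataFrame:
    """Collapse each participant's assessments within consecutive windows to
    their median.

    One output record per participant per non-empty window: value = median of
    the window's values, time = the window's midpoint, fortnight_index
    recomputed from that midpoint.  Empty input yields an empty table.
    """
    if window_days <= 0:
        raise ValueError(f"window_days must be > 0, got {window_days}")
    if records.empty:
        return pd.DataFrame(
            columns=["participant_id", "time_days", "fortnight_index", "value"]
        )
    df = records.copy()
    df["_window"] = np.floor(df["time_days"] / window_days).astype(int)
    out = (
        df.groupby(["participant_id", "_window"], sort=True)["value"]
        .median()
        .reset_index()
    )
    out["time_days"] = (out["_window"] + 0.5) * window_days
    out["fortnight_index"] = np.floor(out["time_days"] / FORTNIGHT_DAYS).astype(int)
    return out[["participant_id", "time_days", "fortnight_index", "value"]]


def _ensure_fortnight(records: pd.DataFrame) -> pd.DataFrame:
    if "fortnight_index" not in records.columns:
        records = records.copy()
        records["fortnight_index"] = np.floor(
            records["time_days"] / FORTNIGHT_DAYS
        ).astype(int)
    return records


def fit_variance_components(records: pd.DataFrame) -> VarianceComponents:
    """REML estimates of (participant, participant-by-fortnight, residual)
    variances via a random-intercept mixed model.

    Requires >= 2 participants and >= 2 fortnights with data for at least one
    participant; raises :class:`NonIdentifiableError` when the residual
    component cannot be separated (at most one observation per
    participant-fortnight cell everywhere).
    """
    records = _ensure_fortnight(records)
    y = records["value"].to_numpy(dtype=float)
    if records["participant_id"].nunique() < 2:
        raise NonIdentifiableError("need >= 2 participants")
    per_subj_f = records.groupby("participant_id")["fortnight_index"].nunique()
    if per_subj_f.max() < 2:
        raise NonIdentifiableError("need >= 2 fortnights with data for some participant")
    cell_sizes = records.groupby(["participant_id", "fortnight_index"]).size()
    if cell_sizes.max() < 2:
        raise NonIdentifiableError(
            "every participant-fortnight cell has a single observation; "
            "residual and fortnight variances are confounded"
        )

    mu = float(np.mean(y))
    n = int(records["participant_id"].nunique())
    nobs = int(len(records))

    # Noise-free degenerate data breaks the REML solver; handle it exactly.
    cells = records.groupby(["participant_id", "fortnight_index"])["value"]
    within_cell_var = float(cells.var(ddof=1).fillna(0.0).max())
    scale = max(1.0, float(np.max(np.abs(y))))
    if within_cell_var <= (1e-12 * scale) ** 2:
        subj_means = records.groupby("participant_id")["value"].mean()
        within_subj = float(
            records.groupby("participant_id")["value"].var(ddof=1).fillna(0.0).max()
        )
        if within_subj <= (1e-12 * scale) ** 2:
            return VarianceComponents(
                var_participant=float(subj_means.var(ddof=1)),
                var_participant_fortnight=0.0,
                var_residual=0.0,
                grand_mean=mu,
                n_participants=n,
                n_observations=nobs,
            )

    import statsmodels.formula.api as smf

    df = records[["participant_id", "fortnight_index", "value"]].copy()
    model = smf.mixedlm(
        "value ~ 1",
        data=df,
        groups="participant_id",
        re_formula="1",
        vc_formula={"fortnight": "0 + C(fortnight_index)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=500)

    var_p = max(float(result.cov_re.iloc[0, 0]), 0.0)
    var_pf = max(float(result.vcomp[0]), 0.0)
    var_m = max(float(result.scale), 0.0)
    return VarianceComponents(
        var_participant=var_p,
        var_participant_fortnight=var_pf,
        var_residual=var_m,
        grand_mean=float(result.fe_params.iloc[0]),
        n_participants=n,
        n_observations=nobs,
    )


def compute_icc(vc: VarianceComponents) -> float:
    """Share of total variance from participant and participant-by-fortnight
    effects."""
    total = vc.total
    if total <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    return (vc.var_participant + vc.var_participant_fortnight) / total


def compute_sem(vc: VarianceComponents) -> float:
    """Standard error of measurement: residual SD."""
    return math.sqrt(vc.var_residual)


def compute_mdc(sem: float) -> float:
    """Minimum detectable change at 95% confidence: 1.96 * sqrt(2) * sem."""
    if sem < 0:
        raise ValueError(f"sem must be >= 0, got {sem}")
    return MDC_FACTOR * sem


def reliability_report(
    records: pd.DataFrame, mode: str = "individual", window_days: float = 7.0
) -> ReliabilityReport:
    """End-to-end reliability analysis of one measure.

    ``mode="burst"`` first collapses each 7-day window to its median (burst
    outcome); ``mode="individual"`` analyzes raw assessments.
    """
    if mode not in ("individual", "burst"):
        raise ValueError(f"mode must be 'individual' or 'burst', got {mode!r}")
    data = summarize_bursts(records, window_days) if mode == "burst" else records
    vc = fit_variance_components(data)
    sem = compute_sem(vc)
    mdc = compute_mdc(sem)
    return ReliabilityReport(
        icc=compute_icc(vc),
        sem=sem,
        mdc=mdc,
        mdc_percent_of_mean=(
            100.0 * mdc / abs(vc.grand_mean) if vc.grand_mean != 0 else math.inf
        ),
        mode=mode,
    )


def model_residuals(records: pd.DataFrame) -> pd.DataFrame:
    """Per-observation residuals y - (mu + a_i + b_if) under cell-mean BLUPs,
    returned as a table for Q-Q-style diagnostics."""
    records = _ensure_fortnight(records)
    df = records.copy()
    df["_cell_mean"] = df.groupby(["participant_id", "fortnight_index"])[
        "value"
    ].transform("mean")
    df["residual"] = df["value"] - df["_cell_mean"]
    return df[["participant_id", "fortnight_index", "time_days", "residual"]]
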