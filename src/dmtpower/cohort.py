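"""Synthetic longitudinal at-home assessment cohorts.

Emulates smartphone-app study data: participants perform repeated at-home assessments
of one motor measure over several months.  Values decompose as

    y_{i,f,k} = mu + a_i + b_{i,f} + eps_{i,f,k}

with a stable participant effect a_i ~ N(0, sigma_participant^2), a
participant-by-fortnight deviation b_{i,f} ~ N(0, sigma_participant_fortnight^2)
capturing slow symptom drift, and per-assessment noise eps ~ N(0, sigma_m^2).
Assessments are dropped independently (missing completely at random) with a
single adherence probability, so variance-component recovery can be exercised
under missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort", "write_cohort_csv", "read_cohort_csv"]

FORTNIGHT_DAYS = 14.0
COHORT_CSV_COLUMNS = ["participant_id", "time_days", "fortnight_index", "value"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror a 44-participant, 6-month daily-assessment study of step
    length (meters) with roughly a third of scheduled assessments missed.
    """

    n_participants: int = 44
    duration_days: float = 183.0
    assessments_per_week: float = 7.0
    mu: float = 0.5
    sigma_participant: float = 0.10
    sigma_participant_fortnight: float = 0.03
    sigma_m: float = 0.06
    missing_prob: float = 0.34
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.duration_days < 14:
            raise ValueError(f"duration_days must be >= 14, got {self.duration_days}")
        if self.assessments_per_week <= 0:
            raise ValueError(
                f"assessments_per_week must be > 0, got {self.assessments_per_week}"
            )
        for name in ("sigma_participant", "sigma_participant_fortnight", "sigma_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.missing_prob < 1:
            raise ValueError(f"missing_prob must be in [0, 1), got {self.missing_prob}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort as a long-format table.

    Columns: participant_id, time_days (from each participant's enrollment),
    fortnight_index = floor(time_days / 14), value.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    step = 7.0 / spec.assessments_per_week
    times = np.arange(0.0, spec.duration_days, step)
    m = times.size
    fortnights = np.floor(times / FORTNIGHT_DAYS).astype(int)
    n_f = fortnights.max() + 1
    n = spec.n_participants

    a = spec.sigma_participant * rng.standard_normal(n)
    b = spec.sigma_participant_fortnight * rng.standard_normal((n, n_f))
    eps = spec.sigma_m * rng.standard_normal((n, m))
    values = spec.mu + a[:, None] + b[:, fortnights] + eps

    keep = rng.random((n, m)) >= spec.missing_prob
    pid = np.repeat(np.arange(n), m)[keep.ravel()]
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "time_days": np.tile(times, n)[keep.ravel()],
            "fortnight_index": np.tile(fortnights, n)[keep.ravel()],
            "value": values.ravel()[keep.ravel()],
        }
    )
    return df


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=COHORT_CSV_COLUMNS, float_format="%.15g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
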