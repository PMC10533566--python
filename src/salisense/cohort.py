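"""Synthetic participant cohorts.

Clinical markers are drawn from truncated normal distributions whose
*truncated* mean equals the reported group mean — because the reported
ranges are asymmetric around the mean, the underlying normal location has to
be solved for (a plain ``loc=mean`` parameterisation would bias diabetic FBG
by roughly +10 mg/dL).  SDs for markers reported as "mean (range)" default
to range/4.  Ages are reported as mean ± SD and are drawn directly, with a
physiological truncation to [18, 100] years.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._util import STREAM_COHORT, stream_rng
from .config import GeneratorConfig, GroupDemographics
from .panel import DIABETIC, GROUPS, NONDIABETIC

COHORT_COLUMNS = (
    "id", "group", "age", "sex", "fbg", "glucose_2hpp", "tg", "hba1c", "activity_hours",
)


@dataclass(frozen=True)
class Participant:
    """One simulated (or recorded) study subject."""

    id: str
    group: str
    age: float
    sex: str
    fbg: float
    glucose_2hpp: Optional[float]
    tg: float
    hba1c: float
    activity_hours: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.fbg <= 0:
            raise ValueError("fbg must be positive")
        if not 0 <= self.activity_hours <= 24:
            raise ValueError("activity_hours must lie in [0, 24]")


@lru_cache(maxsize=None)
def _matched_loc(target_mean: float, sd: float, low: float, high: float) -> float:
    """Location of a normal(loc, sd) whose [low, high]-truncation has the
    requested mean."""
    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return brentq(trunc_mean, low - 10 * sd, high + 10 * sd, xtol=1e-10)


def truncated_marginal(mean: float, low: float, high: float,
                       sd: Optional[float] = None, match_mean: bool = True):
    """Frozen truncnorm for one marker.

    With ``match_mean`` the distribution's mean equals ``mean`` exactly;
    otherwise ``mean`` is used as the raw location parameter.
    """
    if sd is None:
        sd = (high - low) / 4.0
    loc = _matched_loc(mean, sd, low, high) if match_mean else mean
    a, b = (low - loc) / sd, (high - loc) / sd
    return truncnorm(a, b, loc=loc, scale=sd)


def _group_frame(demo: GroupDemographics, group: str, n: int, prefix: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    fbg = truncated_marginal(demo.fbg_mean, *demo.fbg_range).rvs(n, random_state=rng)
    tg = truncated_marginal(demo.tg_mean, *demo.tg_range).rvs(n, random_state=rng)
    hba1c = truncated_marginal(demo.hba1c_mean, *demo.hba1c_range).rvs(n, random_state=rng)
    if demo.glucose_2hpp_mean is not None:
        g2 = truncated_marginal(demo.glucose_2hpp_mean, *demo.glucose_2hpp_range).rvs(
            n, random_state=rng)
    else:
        g2 = np.full(n, np.nan)
    age = truncated_marginal(demo.age_mean, 18.0, 100.0,
                             sd=demo.age_sd, match_mean=False).rvs(n, random_state=rng)
    sex = np.where(rng.random(n) < demo.p_male, "male", "female")
    activity = truncated_marginal(demo.activity_mean, 0.0, 24.0,
                                  sd=demo.activity_sd, match_mean=False).rvs(
        n, random_state=rng)
    return pd.DataFrame({
        "id": [f"{prefix}{i + 1:03d}" for i in range(n)],
        "group": group,
        "age": age,
        "sex": sex,
        "fbg": fbg,
        "glucose_2hpp": g2,
        "tg": tg,
        "hba1c": hba1c,
        "activity_hours": activity,
    })


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort of ``n_diabetic + n_nondiabetic`` participants.

    Returns a DataFrame with one row per participant (diabetic block first)
    and columns :data:`COHORT_COLUMNS`.  Identical config + seed gives an
    identical table.
    """
    if config.n_diabetic < 0 or config.n_nondiabetic < 0:
        raise ValueError("participant counts must be non-negative")
    rng = stream_rng(config.seed, STREAM_COHORT)
    frames = [
        _group_frame(config.demographics(DIABETIC), DIABETIC,
                     config.n_diabetic, "D", rng),
        _group_frame(config.demographics(NONDIABETIC), NONDIABETIC,
                     config.n_nondiabetic, "N", rng),
    ]
    cohort = pd.concat(frames, ignore_index=True)
    return cohort[list(COHORT_COLUMNS)]


def cohort_to_participants(cohort: pd.DataFrame) -> list:
    """Row-wise view of a cohort table as :class:`Participant` records."""
    out = []
    for row in cohort.itertuples(index=False):
        g2 = None if pd.isna(row.glucose_2hpp) else float(row.glucose_2hpp)
        out.append(Participant(row.id, row.group, float(row.age), row.sex,
                               float(row.fbg), g2, float(row.tg),
                               float(row.hba1c), float(row.activity_hours)))
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return cohort[list(COHORT_COLUMNS)]
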