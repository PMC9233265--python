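"""Daily and weekly outcome measures from minute records.

Turns each participant-day into a :class:`DailySummary` (sedentary minutes,
MET-based MVPA minutes, heart-rate-based MVPA minutes, step count), applies
the outlier-day exclusion (>500 MVPA minutes), assigns days to 7-day
measurement occasions and averages retained days into weekly outcomes.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd

from .config import period_label
from .core import MinuteSeries, TrialData

OUTCOME_COLUMNS = ["sedentary_minutes", "met_mvpa_minutes",
                   "hr_mvpa_minutes", "step_count"]

#: Default heart-rate cut-off for HR-based MVPA minutes: roughly 50% of
#: heart-rate reserve for a 16-year-old with resting HR 80
#: (80 + 0.5 * (204 - 80)).  The vendor's own zone algorithm is proprietary.
DEFAULT_HR_MODERATE_THRESHOLD = 142.0

MVPA_OUTLIER_THRESHOLD = 500.0


@dataclass
class DailySummary:
    """Per-day outcome measures for one participant."""

    participant_id: str
    date: dt.date
    sedentary_minutes: int
    light_minutes: int
    met_mvpa_minutes: int
    hr_mvpa_minutes: int
    step_count: int
    wear_minutes: int
    all_missing: bool = False


def summarize_day(series: MinuteSeries,
                  hr_moderate_threshold: float = DEFAULT_HR_MODERATE_THRESHOLD
                  ) -> DailySummary:
    """Collapse one participant-day of minute records into daily outcomes.

    Step count sums minute steps; sedentary and MET-MVPA minutes count
    intensity classes; HR-MVPA minutes count wear minutes at or above the
    heart-rate threshold.  A fully missing day yields zeros and is flagged.
    """
    wear = series.wear_mask()
    inten = series.intensity
    hr = series.heart_rate
    hr_mvpa = int(np.sum(wear & ~np.isnan(hr) & (hr >= hr_moderate_threshold)))
    return DailySummary(
        participant_id=series.participant_id,
        date=series.date,
        sedentary_minutes=int(sum(v == "sedentary" for v in inten)),
        light_minutes=int(sum(v == "light" for v in inten)),
        met_mvpa_minutes=int(sum(v in ("moderate", "vigorous") for v in inten)),
        hr_mvpa_minutes=hr_mvpa,
        step_count=int(series.total_steps()),
        wear_minutes=int(wear.sum()),
        all_missing=not wear.any(),
    )


def summarize_trial(trial: TrialData,
                    hr_moderate_threshold: float = DEFAULT_HR_MODERATE_THRESHOLD
                    ) -> pd.DataFrame:
    """Daily summary table (one row per participant-day)."""
    rows = [summarize_day(ms, hr_moderate_threshold) for ms in trial.days()]
    return pd.DataFrame([r.__dict__ for r in rows])


def exclude_outlier_days(days: pd.DataFrame,
                         threshold: float = MVPA_OUTLIER_THRESHOLD
                         ) -> Tuple[pd.DataFrame, List[dict]]:
    """Drop days with more than ``threshold`` MET-MVPA minutes (strict
    inequality) and log each exclusion."""
    if days.empty:
        return days.copy(), []
    mask = days["met_mvpa_minutes"] > threshold
    log = [{"participant_id": r.participant_id, "date": str(r.date),
            "reason": f"met_mvpa_minutes {r.met_mvpa_minutes} > {threshold:g}"}
           for r in days[mask].itertuples()]
    return days[~mask].reset_index(drop=True), log


def assign_periods(days: pd.DataFrame, trial_start_date: dt.date,
                   n_periods: int = 4) -> Tuple[pd.DataFrame, List[dict]]:
    """Tag each day with its 7-day measurement occasion
    (baseline/week1/...); days outside the trial range go to a log."""
    if days.empty:
        out = days.copy()
        out["period"] = pd.Series(dtype=object)
        return out, []
    offsets = days["date"].map(lambda d: (d - trial_start_date).days)
    idx = offsets // 7
    in_range = (offsets >= 0) & (idx < n_periods)
    rejected = [{"participant_id": r.participant_id, "date": str(r.date),
                 "reason": "outside trial window"}
                for r in days[~in_range].itertuples()]
    out = days[in_range].copy()
    out["period"] = [period_label(int(i)) for i in idx[in_range]]
    return out.reset_index(drop=True), rejected


def aggregate_weekly(tagged_days: pd.DataFrame) -> pd.DataFrame:
    """Mean daily outcome per participant-period over retained days.

    Participant-periods with no retained days are simply absent; downstream
    paired tests treat the absence as missing (listwise deletion), which is
    what makes degrees of freedom shrink when a participant drops out of
    one comparison.
    """
    if tagged_days.empty:
        return pd.DataFrame(columns=["participant_id", "period", "n_days",
                                     *OUTCOME_COLUMNS])
    grp = tagged_days.groupby(["participant_id", "period"], sort=True)
    out = grp[OUTCOME_COLUMNS].mean().reset_index()
    out.insert(2, "n_days", grp.size().to_numpy())
    return out


def missingness_report(trial: TrialData) -> dict:
    """Wear-gap report: per-day missing-minute totals and participants with
    any contiguous gap longer than 24 hours across consecutive days."""
    per_day = {}
    flagged = []
    for pid in trial.participants():
        days = sorted(d for p, d in trial.series if p == pid)
        wear = np.concatenate([trial.series[(pid, d)].wear_mask() for d in days])
        longest = run = 0
        for w in wear:
            run = 0 if w else run + 1
            longest = max(longest, run)
        if longest > 1440:
            flagged.append({"participant_id": pid,
                            "longest_gap_minutes": int(longest)})
        for d in days:
            per_day[(pid, str(d))] = trial.series[(pid, d)].missing_minutes()
    return {
        "participants_with_gap_over_24h": flagged,
        "missing_minutes_per_day": [
            {"participant_id": pid, "date": date, "missing_minutes": v}
            for (pid, date), v in sorted(per_day.items())],
    }
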