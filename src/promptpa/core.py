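"""Core in-memory containers for minute-level wearable trial data.

A trial is a collection of participant-days.  Each participant-day is a
:class:`MinuteSeries`: 1440 minute records of steps, heart rate and an
intensity class.  Non-wear minutes carry NaN steps/heart-rate and a missing
intensity — steps are NaN exactly when the minute is non-wear.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .config import MINUTES_PER_DAY, SimulationConfig

INTENSITIES = ("sedentary", "light", "moderate", "vigorous")


@dataclass
class MinuteSeries:
    """One participant-day of minute records.

    Attributes
    ----------
    steps : float ndarray (1440,)
        Steps per minute; NaN marks a non-wear minute.
    heart_rate : float ndarray (1440,)
        Heart rate in bpm; NaN marks a non-wear minute.
    intensity : object ndarray (1440,)
        One of ``sedentary/light/moderate/vigorous`` or ``None`` (non-wear).
    """

    participant_id: str
    date: dt.date
    steps: np.ndarray
    heart_rate: np.ndarray
    intensity: np.ndarray

    def wear_mask(self) -> np.ndarray:
        return ~np.isnan(self.steps)

    def missing_minutes(self) -> int:
        return int(np.isnan(self.steps).sum())

    def total_steps(self) -> float:
        return float(np.nansum(self.steps))

    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        for name, arr in (("steps", self.steps), ("heart_rate", self.heart_rate),
                          ("intensity", self.intensity)):
            if len(arr) != MINUTES_PER_DAY:
                raise ValueError(f"{name}: expected {MINUTES_PER_DAY} records, got {len(arr)}")
        wear = self.wear_mask()
        if np.any(self.steps[wear] < 0):
            raise ValueError("steps must be non-negative")
        hr = self.heart_rate[wear]
        hr = hr[~np.isnan(hr)]
        if hr.size and (hr.min() < 30 or hr.max() > 220):
            raise ValueError("heart_rate out of [30, 220]")
        miss_int = np.array([v is None for v in self.intensity])
        if not np.array_equal(miss_int, ~wear):
            raise ValueError("intensity must be missing exactly on non-wear minutes")
        bad = {v for v in self.intensity if v is not None} - set(INTENSITIES)
        if bad:
            raise ValueError(f"unknown intensity classes: {sorted(bad)}")

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.participant_id, self.date, self.steps.copy(),
                            self.heart_rate.copy(), self.intensity.copy())

    def equals(self, other: "MinuteSeries") -> bool:
        return (self.participant_id == other.participant_id
                and self.date == other.date
                and np.array_equal(self.steps, other.steps, equal_nan=True)
                and np.array_equal(self.heart_rate, other.heart_rate, equal_nan=True)
                and all(a == b for a, b in zip(self.intensity, other.intensity)))


@dataclass(frozen=True)
class PromptEvent:
    """A delivered activity prompt (at most one per participant-day)."""

    participant_id: str
    date: dt.date
    delivery_minute: int  # minute-of-day within the prompt window


@dataclass
class TrialData:
    """A full trial: minute series keyed by (participant, date), the prompt
    log, and the ground-truth record of injected effects."""

    series: Dict[Tuple[str, dt.date], MinuteSeries]
    prompts: List[PromptEvent] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)
    config: Optional[SimulationConfig] = None

    def participants(self) -> List[str]:
        return sorted({pid for pid, _ in self.series})

    def dates(self) -> List[dt.date]:
        return sorted({d for _, d in self.series})

    def days(self) -> Iterator[MinuteSeries]:
        for key in sorted(self.series, key=lambda k: (k[0], k[1])):
            yield self.series[key]

    def prompt_for(self, pid: str, date: dt.date) -> Optional[PromptEvent]:
        for ev in self.prompts:
            if ev.participant_id == pid and ev.date == date:
                return ev
        return None

    def equals(self, other: "TrialData") -> bool:
        if set(self.series) != set(other.series):
            return False
        if any(not self.series[k].equals(other.series[k]) for k in self.series):
            return False
        return sorted(self.prompts, key=lambda e: (e.participant_id, e.date)) == \
            sorted(other.prompts, key=lambda e: (e.participant_id, e.date))


def classify_intensity(steps: np.ndarray, heart_rate: np.ndarray,
                       moderate_steps: int = 60, vigorous_steps: int = 110,
                       hr_elevated: float = 100.0) -> np.ndarray:
    """Derive the per-minute intensity class from steps and heart rate.

    Fixed cut-offs stand in for the device vendor's proprietary MET logic:
    zero steps with no elevated heart rate is sedentary; elevated heart rate
    alone promotes a zero-step minute to light.
    """
    out = np.empty(len(steps), dtype=object)
    out[:] = None
    wear = ~np.isnan(steps)
    s = np.where(wear, steps, 0.0)
    hr = np.where(np.isnan(heart_rate), 0.0, heart_rate)
    sed = wear & (s == 0) & (hr < hr_elevated)
    light = wear & ~sed & (s < moderate_steps)
    mod = wear & (s >= moderate_steps) & (s < vigorous_steps)
    vig = wear & (s >= vigorous_steps)
    out[sed] = "sedentary"
    out[light] = "light"
    out[mod] = "moderate"
    out[vig] = "vigorous"
    return out
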