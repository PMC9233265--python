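"""Configuration models for trial simulation and analysis runs.

All knobs of the synthetic trial generator and of the analysis pipeline live
in two pydantic models, :class:`SimulationConfig` and :class:`RunConfig`, so
that a run is fully reproducible from its serialized configuration plus a
seed.
"""
from __future__ import annotations

import datetime as dt
from typing import Optional, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

#: Relative share of a day's activity attributed to each clock hour
#: (local time, hour 0-23).  Sums to 1; night hours carry no activity.
DEFAULT_DIURNAL_PROFILE: Tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0,           # 00-05  sleep
    0.01, 0.04, 0.06, 0.05, 0.05, 0.05,     # 06-11  morning commute / school
    0.07, 0.06, 0.05, 0.06, 0.07, 0.08,     # 12-17  lunch, afternoon rise
    0.08, 0.07, 0.06, 0.05, 0.05, 0.04,     # 18-23  evening taper
)

MINUTES_PER_DAY = 1440


def period_label(index: int) -> str:
    """Name of the 7-day measurement occasion with the given 0-based index."""
    return "baseline" if index == 0 else f"week{index}"


class EffectSpec(BaseModel):
    """Injected response to a prompt: an additive mean shift on heart rate
    (bpm, deterministic) and on steps (steps/min, Poisson-distributed around
    ``delta_steps``) starting ``onset_lag`` minutes after delivery and
    lasting ``duration`` minutes."""

    delta_hr: float = 0.0
    delta_steps: float = Field(0.0, ge=0)
    onset_lag: int = Field(0, ge=0)
    duration: int = Field(30, ge=1)

    def is_null(self) -> bool:
        return self.delta_hr == 0.0 and self.delta_steps == 0.0


class SimulationConfig(BaseModel):
    """Parameters of the synthetic wearable trial.

    Defaults emulate a 4-week within-subject trial of 18 adolescents with a
    baseline week followed by three intervention weeks, minute-resolution
    steps and heart rate, daily prompts delivered between 17:00 and 19:00 on
    intervention days, and occasional non-wear gaps.
    """

    n_participants: int = Field(18, ge=1)
    n_periods: int = Field(4, ge=2, description="number of 7-day periods")
    seed: int = 0
    start_date: dt.date = dt.date(2021, 6, 7)

    # step process
    mean_daily_steps: float = Field(14_000.0, gt=0)
    between_participant_sd: float = Field(3_500.0, ge=0)
    within_participant_cv: float = Field(0.25, ge=0)
    diurnal_profile: Tuple[float, ...] = DEFAULT_DIURNAL_PROFILE
    sedentary_base: float = Field(790.0, ge=0, lt=MINUTES_PER_DAY,
                                  description="expected zero-step minutes/day")
    sedentary_between_sd: float = Field(170.0, ge=0)
    sedentary_within_cv: float = Field(0.15, ge=0,
                                       description="day-to-day CV of the active-minute budget")
    step_shape: float = Field(1.2, gt=0, description="gamma shape of active-minute steps")
    exercise_prob: float = Field(0.08, ge=0, le=1)
    exercise_steps_mean: float = Field(85.0, gt=0)
    exercise_steps_sd: float = Field(20.0, ge=0)

    # heart-rate process
    resting_hr: float = Field(80.0, gt=0)
    resting_hr_sd: float = Field(6.0, ge=0)
    hr_noise_sd: float = Field(3.0, ge=0)
    hr_step_coupling: float = Field(0.4, ge=0, description="bpm per step/min")
    exercise_hr_boost: float = Field(30.0, ge=0)

    # missingness (non-wear)
    gap_rate_per_day: float = Field(0.4, ge=0, description="expected gaps/day")
    mean_gap_minutes: float = Field(4.0, ge=1)

    # prompts
    prompt_window: Tuple[int, int] = (1020, 1140)  # [17:00, 19:00)
    prompt_effect_by_period: Optional[list[EffectSpec]] = None

    # intensity classification cut-offs (stand-in for the device's MET logic)
    moderate_steps_per_min: int = Field(60, gt=0)
    vigorous_steps_per_min: int = Field(110, gt=0)
    hr_elevated_bpm: float = Field(100.0, gt=0)

    @field_validator("diurnal_profile")
    @classmethod
    def _check_profile(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if len(v) != 24:
            raise ValueError("diurnal_profile must have 24 hourly weights")
        if any(w < 0 for w in v):
            raise ValueError("diurnal_profile weights must be non-negative")
        if abs(sum(v) - 1.0) > 1e-6:
            raise ValueError("diurnal_profile weights must sum to 1")
        return v

    @field_validator("prompt_window")
    @classmethod
    def _check_window(cls, v: Tuple[int, int]) -> Tuple[int, int]:
        lo, hi = v
        if not (0 <= lo < hi <= MINUTES_PER_DAY):
            raise ValueError("prompt_window must be a half-open interval within the day")
        return v

    @model_validator(mode="after")
    def _check_effects(self) -> "SimulationConfig":
        if self.vigorous_steps_per_min <= self.moderate_steps_per_min:
            raise ValueError("vigorous_steps_per_min must exceed moderate_steps_per_min")
        if self.prompt_effect_by_period is not None:
            if len(self.prompt_effect_by_period) != self.n_periods:
                raise ValueError(
                    "prompt_effect_by_period must have one entry per period")
            if not self.prompt_effect_by_period[0].is_null():
                raise ValueError(
                    "prompt_effect_by_period: baseline entry must be a zero effect")
        return self

    def effects(self) -> list[EffectSpec]:
        """Per-period effect list with the all-zero default resolved."""
        if self.prompt_effect_by_period is None:
            return [EffectSpec() for _ in range(self.n_periods)]
        return list(self.prompt_effect_by_period)

    @property
    def n_days(self) -> int:
        return 7 * self.n_periods


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (simulate -> intervene ->
    preprocess -> analyze -> report)."""

    simulation: SimulationConfig = SimulationConfig()
    input_dir: Optional[str] = None      # read a canonical CSV dataset instead of simulating
    out_dir: str = "promptpa_out"
    seed: int = 0
    n_boot: int = Field(10_000, ge=1000)

    hr_moderate_threshold: float = Field(142.0, gt=0)
    outlier_mvpa_threshold: float = Field(500.0, gt=0)
    max_missing_minutes: int = Field(5, ge=0)
    detection_window: Tuple[int, int] = (900, 1140)   # [15:00, 19:00)
    selection_cutoff: int = Field(1020, ge=0)          # 17:00
    effect_windows: Tuple[int, ...] = (30, 60)
    penalty_beta: float = Field(2.0, gt=0)

    @field_validator("effect_windows")
    @classmethod
    def _check_windows(cls, v: Tuple[int, ...]) -> Tuple[int, ...]:
        if not v or any(w <= 0 for w in v):
            raise ValueError("effect_windows must be positive lengths")
        return v
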