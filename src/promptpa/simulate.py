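"""Synthetic minute-level wearable trial generator.

The generator emulates the structure a prompt-based activity intervention
trial assumes: a baseline week followed by intervention weeks, minute
resolution steps and heart rate with a diurnal profile, daily prompt
deliveries in a fixed evening window, contiguous non-wear gaps, and an
injectable, fully recorded prompt-response effect per period.

Generative model
----------------
Steps are an inhomogeneous burst process: each minute is *active* with an
hour-dependent probability derived from the 24-hour activity-share profile
(scaled so the expected number of zero-step minutes matches
``sedentary_base``).  An active minute draws steps from a gamma
distribution, or — with probability ``exercise_prob`` — from a normal
"exercise burst" distribution.  Heart rate is resting level plus a linear
step coupling, an exercise boost, and white noise; values are rounded and
clipped to [30, 220].  Prompt responses add ``delta_hr`` deterministically
and Poisson(``delta_steps``) per affected minute.
"""
from __future__ import annotations

import datetime as dt
from typing import Optional, Tuple

import numpy as np

from .config import MINUTES_PER_DAY, EffectSpec, SimulationConfig, period_label
from .core import MinuteSeries, PromptEvent, TrialData, classify_intensity

__all__ = ["simulate_trial", "inject_prompt_response", "apply_missingness"]


def _simulate_day_arrays(rng: np.random.Generator, cfg: SimulationConfig,
                         day_total_steps: float, resting_hr: float,
                         active_budget: float) -> Tuple[np.ndarray, np.ndarray]:
    """Raw (steps, heart_rate) arrays for one fully worn day."""
    w = np.asarray(cfg.diurnal_profile, dtype=float)
    p_active = np.clip(np.repeat(active_budget * w / 60.0, 60), 0.0, 0.98)
    active = rng.random(MINUTES_PER_DAY) < p_active

    expected_active = p_active.sum()
    mean_active_steps = day_total_steps / max(expected_active, 1.0)
    p_ex = cfg.exercise_prob
    base_mean = max((mean_active_steps - p_ex * cfg.exercise_steps_mean)
                    / max(1.0 - p_ex, 1e-9), 1.0)

    n_active = int(active.sum())
    is_ex = np.zeros(MINUTES_PER_DAY, dtype=bool)
    steps = np.zeros(MINUTES_PER_DAY, dtype=float)
    if n_active:
        ex_draw = rng.random(n_active) < p_ex
        ordinary = rng.gamma(cfg.step_shape, base_mean / cfg.step_shape, n_active)
        bursts = rng.normal(cfg.exercise_steps_mean, cfg.exercise_steps_sd, n_active)
        vals = np.where(ex_draw, bursts, ordinary)
        steps[active] = np.clip(np.rint(vals), 1, None)
        is_ex[active] = ex_draw

    hr = (resting_hr + cfg.hr_step_coupling * steps
          + cfg.exercise_hr_boost * is_ex
          + (rng.normal(0.0, cfg.hr_noise_sd, MINUTES_PER_DAY)
             if cfg.hr_noise_sd > 0 else 0.0))
    hr = np.clip(np.rint(hr), 30, 220)
    return steps, hr


def inject_prompt_response(series: MinuteSeries, event: PromptEvent,
                           effect: EffectSpec,
                           rng: Optional[np.random.Generator] = None,
                           cfg: Optional[SimulationConfig] = None) -> MinuteSeries:
    """Superimpose a prompt response on a participant-day.

    Minutes in ``[delivery + onset_lag, delivery + onset_lag + duration)``
    get heart rate raised by exactly ``delta_hr`` and steps raised by a
    Poisson draw with mean ``delta_steps``; every other minute is untouched.
    A window extending past the end of the day is truncated.  Heart rate is
    re-clipped to [30, 220] and the intensity classes of affected minutes
    are re-derived.
    """
    if not (0 <= event.delivery_minute < MINUTES_PER_DAY):
        raise ValueError("delivery_minute must lie within the day")
    if effect.duration < 1:
        raise ValueError("duration must be >= 1")
    out = series.copy()
    start = event.delivery_minute + effect.onset_lag
    stop = min(start + effect.duration, MINUTES_PER_DAY)
    if start >= MINUTES_PER_DAY or effect.is_null():
        return out
    rng = rng if rng is not None else np.random.default_rng(0)
    cfg = cfg if cfg is not None else SimulationConfig()
    sl = slice(start, stop)
    wear = out.wear_mask()[sl]
    if effect.delta_steps > 0:
        extra = rng.poisson(effect.delta_steps, stop - start).astype(float)
        out.steps[sl] = np.where(wear, out.steps[sl] + extra, out.steps[sl])
    if effect.delta_hr != 0.0:
        out.heart_rate[sl] = np.where(
            wear, np.clip(out.heart_rate[sl] + effect.delta_hr, 30, 220),
            out.heart_rate[sl])
    out.intensity[sl] = classify_intensity(
        out.steps[sl], out.heart_rate[sl], cfg.moderate_steps_per_min,
        cfg.vigorous_steps_per_min, cfg.hr_elevated_bpm)
    return out


def apply_missingness(series: MinuteSeries, cfg: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> MinuteSeries:
    """Insert contiguous non-wear gaps.

    The number of gaps per day is Poisson(``gap_rate_per_day``); each gap
    length is ``1 + Poisson(mean_gap_minutes - 1)`` and its start is uniform
    over the day.  Gap minutes lose steps, heart rate and intensity.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = series.copy()
    if cfg.gap_rate_per_day <= 0:
        return out
    n_gaps = rng.poisson(cfg.gap_rate_per_day)
    for _ in range(n_gaps):
        length = 1 + rng.poisson(max(cfg.mean_gap_minutes - 1.0, 0.0))
        start = int(rng.integers(0, MINUTES_PER_DAY))
        sl = slice(start, min(start + length, MINUTES_PER_DAY))
        out.steps[sl] = np.nan
        out.heart_rate[sl] = np.nan
        out.intensity[sl] = None
    return out


def simulate_trial(config: SimulationConfig) -> TrialData:
    """Generate a full trial dataset.

    Returns a :class:`~promptpa.core.TrialData` with one
    :class:`~promptpa.core.MinuteSeries` per participant-day, a prompt event
    on every non-baseline day, and a ground-truth record of every injected
    effect so that recovery can be scored.  Identical configs (including
    seed) produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    effects = config.effects()
    series: dict = {}
    prompts: list[PromptEvent] = []
    truth_days: list[dict] = []

    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        personal_mean = max(rng.normal(config.mean_daily_steps,
                                       config.between_participant_sd), 2000.0)
        resting = rng.normal(config.resting_hr, config.resting_hr_sd)
        personal_sedentary = float(np.clip(
            rng.normal(config.sedentary_base, config.sedentary_between_sd),
            200.0, 1350.0))
        for d in range(config.n_days):
            date = config.start_date + dt.timedelta(days=d)
            period = d // 7
            day_total = personal_mean * max(
                rng.normal(1.0, config.within_participant_cv), 0.1)
            budget = (MINUTES_PER_DAY - personal_sedentary) * max(
                rng.normal(1.0, config.sedentary_within_cv), 0.05)
            steps, hr = _simulate_day_arrays(rng, config, day_total, resting,
                                             budget)
            intensity = classify_intensity(
                steps, hr, config.moderate_steps_per_min,
                config.vigorous_steps_per_min, config.hr_elevated_bpm)
            ms = MinuteSeries(pid, date, steps, hr, intensity)

            if period > 0:
                minute = int(rng.integers(*config.prompt_window))
                event = PromptEvent(pid, date, minute)
                prompts.append(event)
                eff = effects[period]
                ms = inject_prompt_response(ms, event, eff, rng, config)
                truth_days.append({
                    "participant_id": pid, "date": date.isoformat(),
                    "period": period_label(period), "delivery_minute": minute,
                    "effect": eff.model_dump()})
            ms = apply_missingness(ms, config, rng)
            series[(pid, date)] = ms

    ground_truth = {
        "prompt_effect_by_period": [e.model_dump() for e in effects],
        "period_labels": [period_label(p) for p in range(config.n_periods)],
        "days": truth_days,
    }
    return TrialData(series=series, prompts=prompts,
                     ground_truth=ground_truth, config=config)
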