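"""Decision rules of the activity intervention.

Weekly goal adaptation, prompt-message tiering and rendering, hourly
reminders to move, consecutive-day voucher rewards, the WHO activity
sufficiency screen and the trial eligibility screen.  Each rule is a pure
function of its inputs so the engine can be replayed deterministically.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GoalState", "PromptTier", "PromptMessage", "ReminderDecision",
    "REWARD_RULE", "TIERS", "adapt_goal", "update_weekly_goal",
    "classify_prompt_tier", "render_prompt", "should_remind",
    "compute_reward", "who_sufficient", "screen_participant",
    "load_template_pool",
]

#: Voucher euros by minimum length of the longest run of consecutive
#: goal-met days in a week; runs shorter than 3 days pay nothing.
REWARD_RULE = {3: 15, 5: 30, 7: 40}

#: WHO daily sufficiency: 60 moderate-to-vigorous minutes, or the step-count
#: equivalent of 11,700 steps.
WHO_MVPA_MINUTES = 60
WHO_DAILY_STEPS = 11_700

REMINDER_HOURS = range(16, 21)   # [4 PM, 9 PM)
REMINDER_STEP_TARGET = 250

GOAL_RAISE_FACTOR = 1.05


@dataclass(frozen=True)
class PromptTier:
    """Message-framing tier: the half-open percent-of-goal band the
    participant's progress falls into."""

    label: str
    lower_bound_pct: int


#: The five framing tiers; bands are half-open at the next bound and the
#: top tier is unbounded above.
TIERS = (
    PromptTier("LT40", 0),
    PromptTier("GE40", 40),
    PromptTier("GE60", 60),
    PromptTier("GE80", 80),
    PromptTier("GE100", 100),
)


@dataclass(frozen=True)
class GoalState:
    """Daily goals in force during one intervention week."""

    step_goal: int
    azm_goal: int
    week_index: int

    def __post_init__(self):
        if self.step_goal <= 0 or self.azm_goal <= 0:
            raise ValueError("goals must be strictly positive")


@dataclass(frozen=True)
class PromptMessage:
    name: str
    steps_so_far: int
    pct_of_goal: int
    health_benefit: str
    framing: str          # tier label the template was drawn from
    text: str


@dataclass(frozen=True)
class ReminderDecision:
    remind: bool
    step_target: int = REMINDER_STEP_TARGET


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def adapt_goal(prev_goal: int, avg_daily_achieved: float) -> int:
    """One goal's weekly update: a 5% raise on the achieved average, or a
    hold at the previous goal if the participant underperformed it."""
    if avg_daily_achieved < 0:
        raise ValueError("avg_daily_achieved must be non-negative")
    if prev_goal <= 0:
        raise ValueError("prev_goal must be strictly positive")
    if avg_daily_achieved >= prev_goal:
        return _round_half_up(GOAL_RAISE_FACTOR * avg_daily_achieved)
    return prev_goal


def update_weekly_goal(prev: GoalState, avg_daily_steps: float,
                       avg_daily_azm: Optional[float] = None) -> GoalState:
    """Advance the goal state by one week (both goals adapt independently;
    the Active-Zone-Minutes goal holds if no average is supplied)."""
    azm = prev.azm_goal if avg_daily_azm is None else adapt_goal(
        prev.azm_goal, avg_daily_azm)
    return GoalState(step_goal=adapt_goal(prev.step_goal, avg_daily_steps),
                     azm_goal=azm, week_index=prev.week_index + 1)


def classify_prompt_tier(steps_so_far: float, goal: float) -> PromptTier:
    """Framing tier for a progress level, lower bounds inclusive."""
    if goal <= 0:
        raise ValueError("goal must be strictly positive")
    if steps_so_far < 0:
        raise ValueError("steps_so_far must be non-negative")
    pct = 100.0 * steps_so_far / goal
    chosen = TIERS[0]
    for tier in TIERS:
        if pct >= tier.lower_bound_pct:
            chosen = tier
    return chosen


def load_template_pool() -> dict:
    """The packaged prompt-template pool: >=25 templates keyed by tier plus
    a pool of health-benefit statements."""
    with resources.files("promptpa.data").joinpath(
            "prompt_templates.json").open() as fh:
        return json.load(fh)


def render_prompt(name: str, steps_so_far: int, goal: int,
                  benefit_pool: Optional[Sequence[str]] = None,
                  seed: int = 0,
                  template_pool: Optional[dict] = None) -> PromptMessage:
    """Render a personalized prompt message.

    The message substitutes five variables — name, steps so far, percent of
    goal, a health benefit drawn from the pool, and the tier-keyed framing
    template.  Draws are reproducible under the seed.
    """
    if not name:
        raise ValueError("name must be non-empty")
    pool = template_pool if template_pool is not None else load_template_pool()
    benefits = list(benefit_pool) if benefit_pool is not None \
        else list(pool.get("benefits", []))
    if not benefits:
        raise ValueError("benefit pool must be non-empty")
    tier = classify_prompt_tier(steps_so_far, goal)
    templates = pool["templates"][tier.label]
    if not templates:
        raise ValueError(f"no templates for tier {tier.label}")
    rng = np.random.default_rng(seed)
    template = templates[int(rng.integers(len(templates)))]
    benefit = benefits[int(rng.integers(len(benefits)))]
    pct = _round_half_up(100.0 * steps_so_far / goal)
    text = template.format(name=name, steps=f"{steps_so_far:,}", pct=pct,
                           benefit=benefit)
    return PromptMessage(name=name, steps_so_far=steps_so_far,
                         pct_of_goal=pct, health_benefit=benefit,
                         framing=tier.label, text=text)


def should_remind(hour_of_day: int, steps_this_hour: int,
                  elevated_hr_this_hour: bool) -> ReminderDecision:
    """Hourly reminder-to-move rule: remind during 4-9 PM when the hour had
    no steps and no other heart-rate-raising activity."""
    if not 0 <= hour_of_day <= 23:
        raise ValueError("hour_of_day must be in [0, 23]")
    remind = (hour_of_day in REMINDER_HOURS and steps_this_hour == 0
              and not elevated_hr_this_hour)
    return ReminderDecision(remind=remind)


def compute_reward(goal_met: Sequence[bool]) -> int:
    """Voucher euros for a week of daily goal-met flags.

    The payout is keyed to the longest run of consecutive goal-met days:
    >=7 days pay 40, >=5 pay 30, >=3 pay 15, shorter runs pay nothing.
    """
    if len(goal_met) != 7:
        raise ValueError("goal_met must contain exactly 7 daily flags")
    longest = run = 0
    for flag in goal_met:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    for days in sorted(REWARD_RULE, reverse=True):
        if longest >= days:
            return REWARD_RULE[days]
    return 0


def who_sufficient(day) -> bool:
    """Whether a daily summary meets the WHO activity recommendation:
    >=60 MET-based moderate-to-vigorous minutes or >=11,700 steps."""
    return (day.met_mvpa_minutes >= WHO_MVPA_MINUTES
            or day.step_count >= WHO_DAILY_STEPS)


def screen_participant(paq_a_score: float, age: float,
                       owns_active_tracker: bool = False,
                       pa_constraint: bool = False) -> bool:
    """Trial eligibility: low-to-moderate self-reported activity
    (questionnaire score <=3 of 5), age 16-18, no active tracker in use and
    no constraint against physical activity."""
    if not 1 <= paq_a_score <= 5:
        raise ValueError("paq_a_score must be in [1, 5]")
    return (paq_a_score <= 3 and 16 <= age <= 18
            and not owns_active_tracker and not pa_constraint)
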