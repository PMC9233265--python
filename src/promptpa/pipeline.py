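"""End-to-end orchestration: simulate -> intervene -> preprocess ->
analyze -> report.

`run_pipeline` executes the whole study pipeline from a single declarative
:class:`~promptpa.config.RunConfig`, writing weekly-outcome and
change-point effect tables (as CSV and human-readable text), the paired
test results, engine decision logs, exclusion logs and a machine-readable
run manifest.  A partial-stage failure aborts with the failing stage named;
outputs from completed stages are retained.
"""
from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, period_label
from .core import TrialData
from . import changepoint as cp
from . import engine
from . import preprocess as pp
from . import stats
from .io import read_canonical_csv, write_canonical_csv
from .simulate import simulate_trial

OUTCOME_UNITS = {
    "sedentary_minutes": "min/day",
    "met_mvpa_minutes": "min/day",
    "hr_mvpa_minutes": "min/day",
    "step_count": "steps/day",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _period_order(periods) -> list:
    known = [period_label(i) for i in range(52)]
    return sorted(periods, key=lambda p: known.index(p) if p in known else 99)


def apply_intervention(trial: TrialData, daily: pd.DataFrame,
                       seed: int = 0) -> list:
    """Replay the intervention's decision rules over the trial and return
    the JSON-lines event log (weekly goals, daily prompt messages with
    tiers, weekly rewards).

    Initial goals come from a 5% raise on the baseline-week averages; a
    goal-met day is a day at or above the step goal (the step goal alone
    decides, by default).
    """
    cfg = trial.config
    start = cfg.start_date
    tagged, _ = pp.assign_periods(daily, start, cfg.n_periods)
    events = []
    pool = engine.load_template_pool()
    for pid in trial.participants():
        sub = tagged[tagged["participant_id"] == pid]
        base = sub[sub["period"] == "baseline"]
        if base.empty:
            continue
        goal = engine.GoalState(
            step_goal=max(engine.adapt_goal(1, base["step_count"].mean()), 1),
            azm_goal=max(engine.adapt_goal(1, max(base["hr_mvpa_minutes"].mean(),
                                                  1.0)), 1),
            week_index=1)
        for p_idx in range(1, cfg.n_periods):
            label = period_label(p_idx)
            events.append({"event": "goal_set", "participant_id": pid,
                           "period": label, "step_goal": goal.step_goal,
                           "azm_goal": goal.azm_goal})
            week = sub[sub["period"] == label].sort_values("date")
            met_flags = []
            for _, day in week.iterrows():
                met_flags.append(bool(day["step_count"] >= goal.step_goal))
                ev = trial.prompt_for(pid, day["date"])
                if ev is None:
                    continue
                ms = trial.series[(pid, day["date"])]
                so_far = int(np.nansum(ms.steps[:ev.delivery_minute]))
                msg = engine.render_prompt(
                    pid, so_far, goal.step_goal, seed=seed + ev.delivery_minute
                    + 1440 * (day["date"] - start).days, template_pool=pool)
                events.append({"event": "prompt", "participant_id": pid,
                               "date": str(day["date"]),
                               "minute": ev.delivery_minute,
                               "tier": msg.framing, "pct": msg.pct_of_goal,
                               "text": msg.text})
            while len(met_flags) < 7:
                met_flags.append(False)
            reward = engine.compute_reward(met_flags[:7])
            events.append({"event": "reward", "participant_id": pid,
                           "period": label, "euros": reward,
                           "goal_met_days": met_flags[:7]})
            if not week.empty:
                goal = engine.update_weekly_goal(
                    goal, week["step_count"].mean(),
                    week["hr_mvpa_minutes"].mean())
    return events


def render_tables(weekly: pd.DataFrame, weekly_effects: pd.DataFrame
                  ) -> Tuple[str, str]:
    """Human-readable outcome and change-point tables, means with SDs in
    parentheses, one row per measurement occasion."""
    lines2 = ["Outcome measures during the baseline and intervention periods",
              "Outcome / occasion: value per day, mean (SD)", ""]
    if not weekly.empty:
        for outcome in pp.OUTCOME_COLUMNS:
            lines2.append(f"{outcome} ({OUTCOME_UNITS.get(outcome, '')})")
            for period in _period_order(weekly["period"].unique()):
                vals = weekly.loc[weekly["period"] == period, outcome]
                lines2.append(f"  {period:<10s} {vals.mean():10.2f}"
                              f" ({vals.std(ddof=1):.2f})")
    lines3 = ["Change-point analysis results",
              "Signal x window / occasion: minutes before, minutes after, "
              "increase per minute mean (SD)", ""]
    if not weekly_effects.empty:
        for (signal, window), sub in weekly_effects.groupby(["signal", "window"]):
            lines3.append(f"{signal} at {window} minutes")
            for period in _period_order(sub["period"].unique()):
                s = sub[sub["period"] == period]
                lines3.append(
                    f"  {period:<10s} {s['pre_mean'].mean():8.3f}"
                    f" {s['post_mean'].mean():8.3f}"
                    f"   {s['delta'].mean():6.2f} ({s['delta'].std(ddof=1):.2f})")
    return "\n".join(lines2) + "\n", "\n".join(lines3) + "\n"


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline and write the report bundle to
    ``config.out_dir``.  Returns the in-memory results keyed by artifact
    name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    def load() -> TrialData:
        if config.input_dir is not None:
            path = Path(config.input_dir)
            if not (path / "minutes.csv").exists():
                raise FileNotFoundError(f"input dataset not found: {path}/minutes.csv")
            return read_canonical_csv(path)
        sim_cfg = config.simulation.model_copy(update={"seed": config.seed})
        t = simulate_trial(sim_cfg)
        write_canonical_csv(t, out / "dataset")
        return t

    trial = run_stage("load", load)

    def preprocess_stage():
        daily = pp.summarize_trial(trial, config.hr_moderate_threshold)
        retained, excl_log = pp.exclude_outlier_days(
            daily, config.outlier_mvpa_threshold)
        start = trial.config.start_date if trial.config else min(trial.dates())
        n_periods = trial.config.n_periods if trial.config else 4
        tagged, rejected = pp.assign_periods(retained, start, n_periods)
        weekly = pp.aggregate_weekly(tagged)
        return daily, tagged, weekly, excl_log + rejected

    daily, tagged, weekly, exclusions = run_stage("preprocess", preprocess_stage)
    results["daily"] = daily
    results["weekly"] = weekly

    events = run_stage("intervene", lambda: apply_intervention(
        trial, daily, seed=config.seed) if trial.prompts else [])
    results["engine_events"] = events

    outcome_tests = run_stage("outcome_tests", lambda: stats.week_vs_baseline_suite(
        weekly, n_boot=config.n_boot, seed=config.seed))
    results["outcome_tests"] = outcome_tests

    def changepoint_stage():
        day_df, log = cp.analyze_prompt_effects(
            trial, detection_window=config.detection_window,
            cutoff=config.selection_cutoff,
            effect_windows=config.effect_windows,
            max_missing=config.max_missing_minutes,
            penalty_beta=config.penalty_beta)
        weekly_eff = cp.weekly_prompt_effect(day_df)
        tests = cp.prompt_effect_tests(weekly_eff, n_boot=config.n_boot,
                                       seed=config.seed)
        return day_df, weekly_eff, tests, log

    cp_days, cp_weekly, cp_tests, cp_log = run_stage("changepoint",
                                                     changepoint_stage)
    results["changepoint_days"] = cp_days
    results["changepoint_weekly"] = cp_weekly
    results["prompt_effect_tests"] = cp_tests

    def report():
        daily.to_csv(out / "daily_summaries.csv", index=False)
        weekly.to_csv(out / "weekly_outcomes.csv", index=False)
        outcome_tests.to_csv(out / "outcome_tests.csv", index=False)
        cp_days.to_csv(out / "changepoint_days.csv", index=False)
        cp_weekly.to_csv(out / "changepoint_weekly.csv", index=False)
        cp_tests.to_csv(out / "prompt_effect_tests.csv", index=False)
        with open(out / "exclusions.jsonl", "w") as fh:
            for rec in exclusions + cp_log:
                fh.write(json.dumps(rec) + "\n")
        with open(out / "engine_events.jsonl", "w") as fh:
            for rec in events:
                fh.write(json.dumps(rec) + "\n")
        t2, t3 = render_tables(weekly, cp_weekly)
        (out / "table_outcomes.txt").write_text(t2)
        (out / "table_changepoints.txt").write_text(t3)
        report_miss = pp.missingness_report(trial)
        (out / "missingness.json").write_text(json.dumps(report_miss, indent=1))
        manifest = {
            "config": json.loads(config.model_dump_json()),
            "seed": config.seed,
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__, "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return manifest

    results["manifest"] = run_stage("report", report)
    return results
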