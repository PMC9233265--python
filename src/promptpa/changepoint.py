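"""Prompt-effect analysis via change-point detection in the mean.

Pipeline per participant-day and signal (steps or heart rate):

1. repair small wear gaps by linear interpolation (days with more than
   5 missing minutes are excluded);
2. detect mean-shift change points on the 3 PM - 7 PM window by binary
   segmentation over a sum-of-squared-errors cost;
3. keep the best-fitting change point at or after 5 PM (largest SSE
   reduction, earliest minute on ties);
4. compute the effect magnitude: the mean of the 30- (and 60-) minute
   window after the change point minus the mean of the window before;
5. average magnitudes per participant and 7-day period, the baseline week
   included as a no-prompt control for random evening variation;
6. test each intervention week against baseline with paired one-tailed
   (increase) classic and bootstrap t-tests.

The first binary-segmentation split is by construction the exhaustive
single-split scan minimizing total within-segment SSE, which is what the
test-suite oracle checks.  Candidates must strictly exceed an SIC-style
penalty (``beta * sigma^2 * log T``, sigma estimated robustly from first
differences), so a constant window yields no candidates and a no-change day
contributes nothing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import MINUTES_PER_DAY, period_label
from .core import MinuteSeries, TrialData
from .stats import (InsufficientDataError, PairedSample, ZeroVarianceError,
                    bootstrap_paired_t)

MAX_INTERPOLATED_MINUTES = 5
DETECTION_WINDOW = (900, 1140)   # [15:00, 19:00)
SELECTION_CUTOFF = 1020          # 17:00
EFFECT_WINDOWS = (30, 60)
PENALTY_BETA = 2.0

SIGNALS = ("steps", "heart_rate")


class DayExcludedError(ValueError):
    """The day cannot enter the change-point analysis (too many missing
    minutes, or no observed data)."""


@dataclass(frozen=True)
class Candidate:
    """A mean-shift change point candidate: first index of the right
    segment, scored by the SSE reduction its split contributed."""

    index: int
    gain: float


@dataclass
class ChangePointResult:
    cp_minute: int
    sse_reduction: float
    window_length: int
    pre_mean: float
    post_mean: float

    @property
    def delta(self) -> float:
        return self.post_mean - self.pre_mean


def repair_gaps(values: np.ndarray,
                max_missing: int = MAX_INTERPOLATED_MINUTES) -> np.ndarray:
    """Linearly interpolate up to ``max_missing`` missing minutes.

    Gaps are interpolated between flanking observed values; a gap touching
    the series boundary carries the nearest observed value.  More than
    ``max_missing`` missing minutes excludes the day
    (:class:`DayExcludedError`).
    """
    values = np.asarray(values, dtype=float)
    miss = np.isnan(values)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return values.copy()
    if n_miss > max_missing:
        raise DayExcludedError(
            f"{n_miss} missing minutes exceed the {max_missing}-minute limit")
    idx = np.arange(values.size)
    out = values.copy()
    out[miss] = np.interp(idx[miss], idx[~miss], values[~miss])
    return out


def _best_split(x: np.ndarray, min_size: int) -> Optional[Tuple[int, float]]:
    """Exhaustive single-split scan: the split index (first index of the
    right segment) minimizing total SSE, with the SSE reduction it yields.
    Ties break toward the earliest index."""
    n = x.size
    if n < 2 * min_size:
        return None
    c1 = np.cumsum(x)
    total_sse = float(np.sum((x - x.mean()) ** 2))
    k = np.arange(min_size, n - min_size + 1)     # candidate split points
    left_sum = c1[k - 1]
    right_sum = c1[-1] - left_sum
    # SSE(seg) - SSE(left) - SSE(right) reduces to a between-means term
    gain = (left_sum ** 2 / k + right_sum ** 2 / (n - k)
            - c1[-1] ** 2 / n)
    best = int(np.argmax(gain))                   # first max -> earliest
    return int(k[best]), float(min(gain[best], total_sse))


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise scale from first differences
    (MAD * 1.4826 / sqrt(2)); immune to a small number of mean shifts."""
    d = np.diff(np.asarray(x, dtype=float))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def default_penalty(x: np.ndarray, beta: float = PENALTY_BETA) -> float:
    """SIC-style penalty for one additional mean parameter:
    ``beta * sigma^2 * log T``."""
    sigma = estimate_noise_sd(x)
    return beta * sigma ** 2 * np.log(max(x.size, 2))


def detect_change_points(values: np.ndarray, penalty: Optional[float] = None,
                         min_size: int = 2, min_gain: float = 1e-6
                         ) -> List[Candidate]:
    """Binary segmentation over the SSE cost.

    Returns candidates sorted by index, each scored by the SSE reduction of
    its split within the segment it divided.  Splitting stops when the best
    reduction no longer strictly exceeds the penalty.  A constant series
    yields an empty list.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("detection window contains missing values; repair first")
    pen = default_penalty(x) if penalty is None else float(penalty)
    found: List[Candidate] = []
    stack = [(0, x.size)]
    while stack:
        a, b = stack.pop()
        res = _best_split(x[a:b], min_size)
        if res is None:
            continue
        k, gain = res
        if gain <= pen or gain < min_gain:
            continue
        found.append(Candidate(index=a + k, gain=gain))
        stack.append((a, a + k))
        stack.append((a + k, b))
    return sorted(found, key=lambda c: c.index)


def select_best_after_cutoff(candidates: Sequence[Candidate],
                             window_start: int = DETECTION_WINDOW[0],
                             cutoff: int = SELECTION_CUTOFF
                             ) -> Optional[Tuple[int, float]]:
    """Best-fitting change point at or after the cutoff clock minute.

    Candidates carry window-relative indices; the winner is the one with
    the largest SSE reduction (earliest minute on exact ties).  Returns
    ``(cp_minute_of_day, gain)`` or ``None`` if no candidate qualifies.
    """
    eligible = [(window_start + c.index, c.gain) for c in candidates
                if window_start + c.index >= cutoff]
    if not eligible:
        return None
    best_gain = max(g for _, g in eligible)
    return min((m, g) for m, g in eligible if g == best_gain)


def effect_magnitude(day_values: np.ndarray, cp_minute: int,
                     window_length: int, sse_reduction: float = np.nan,
                     min_fraction: float = 0.5) -> Optional[ChangePointResult]:
    """Pre/post means around the change point on the full (repaired) day.

    ``pre = mean over [cp - L, cp)``, ``post = mean over [cp, cp + L)``;
    windows are truncated at the day's edges and each must retain at least
    ``min_fraction * L`` observed minutes, else the day is dropped for this
    window length.
    """
    x = np.asarray(day_values, dtype=float)
    lo = max(cp_minute - window_length, 0)
    hi = min(cp_minute + window_length, x.size)
    pre = x[lo:cp_minute]
    post = x[cp_minute:hi]
    pre = pre[~np.isnan(pre)]
    post = post[~np.isnan(post)]
    need = min_fraction * window_length
    if pre.size < need or post.size < need:
        return None
    return ChangePointResult(cp_minute=cp_minute, sse_reduction=sse_reduction,
                             window_length=window_length,
                             pre_mean=float(pre.mean()),
                             post_mean=float(post.mean()))


def analyze_day(series: MinuteSeries, signal: str,
                detection_window: Tuple[int, int] = DETECTION_WINDOW,
                cutoff: int = SELECTION_CUTOFF,
                effect_windows: Sequence[int] = EFFECT_WINDOWS,
                max_missing: int = MAX_INTERPOLATED_MINUTES,
                penalty_beta: float = PENALTY_BETA
                ) -> List[ChangePointResult]:
    """Run repair -> detect -> select -> magnitudes for one day and signal.

    Returns one result per effect-window length (possibly empty when no
    change point qualifies).  Raises :class:`DayExcludedError` when the day
    has too many missing minutes.
    """
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}")
    raw = series.steps if signal == "steps" else series.heart_rate
    repaired = repair_gaps(raw, max_missing)
    a, b = detection_window
    window = repaired[a:b]
    cands = detect_change_points(window, penalty=default_penalty(
        window, penalty_beta))
    sel = select_best_after_cutoff(cands, window_start=a, cutoff=cutoff)
    if sel is None:
        return []
    cp_minute, gain = sel
    out = []
    for length in effect_windows:
        res = effect_magnitude(repaired, cp_minute, length, sse_reduction=gain)
        if res is not None:
            out.append(res)
    return out


def analyze_prompt_effects(trial: TrialData,
                           signals: Sequence[str] = SIGNALS,
                           detection_window: Tuple[int, int] = DETECTION_WINDOW,
                           cutoff: int = SELECTION_CUTOFF,
                           effect_windows: Sequence[int] = EFFECT_WINDOWS,
                           max_missing: int = MAX_INTERPOLATED_MINUTES,
                           penalty_beta: float = PENALTY_BETA
                           ) -> Tuple[pd.DataFrame, List[dict]]:
    """Per-day change-point effect table for a whole trial.

    Baseline days run through the identical procedure, supplying the
    no-prompt control.  Returns the long-form day table (participant, date,
    period, signal, window, cp_minute, pre/post means, delta) and a log of
    days that contributed nothing, with reasons.
    """
    if trial.config is None:
        raise ValueError("trial has no configuration; cannot assign periods")
    start = trial.config.start_date
    rows, log = [], []
    for ms in trial.days():
        period = period_label((ms.date - start).days // 7)
        for signal in signals:
            try:
                results = analyze_day(ms, signal, detection_window, cutoff,
                                      effect_windows, max_missing, penalty_beta)
            except DayExcludedError as exc:
                log.append({"participant_id": ms.participant_id,
                            "date": str(ms.date), "signal": signal,
                            "reason": str(exc)})
                continue
            if not results:
                log.append({"participant_id": ms.participant_id,
                            "date": str(ms.date), "signal": signal,
                            "reason": "no change point at or after cutoff"})
                continue
            for r in results:
                rows.append({"participant_id": ms.participant_id,
                             "date": ms.date, "period": period,
                             "signal": signal, "window": r.window_length,
                             "cp_minute": r.cp_minute,
                             "sse_reduction": r.sse_reduction,
                             "pre_mean": r.pre_mean, "post_mean": r.post_mean,
                             "delta": r.delta})
    columns = ["participant_id", "date", "period", "signal", "window",
               "cp_minute", "sse_reduction", "pre_mean", "post_mean", "delta"]
    return pd.DataFrame(rows, columns=columns), log


def weekly_prompt_effect(day_results: pd.DataFrame) -> pd.DataFrame:
    """Mean effect magnitude per participant, period, signal and window
    length, over that participant's valid days in the period."""
    cols = ["participant_id", "period", "signal", "window"]
    if day_results.empty:
        return pd.DataFrame(columns=[*cols, "n_days", "pre_mean",
                                     "post_mean", "delta"])
    grp = day_results.groupby(cols, sort=True)
    out = grp[["pre_mean", "post_mean", "delta"]].mean().reset_index()
    out.insert(4, "n_days", grp.size().to_numpy())
    return out


def baseline_control(trial: TrialData, **kwargs) -> pd.DataFrame:
    """The identical detect/select/magnitude/aggregate procedure run on the
    baseline week only — the comparison value for the treatment weeks."""
    if trial.config is None:
        raise ValueError("trial has no configuration; cannot assign periods")
    start = trial.config.start_date
    baseline_keys = {k for k in trial.series
                     if 0 <= (k[1] - start).days < 7}
    if not baseline_keys:
        raise ValueError("no baseline days present")
    sub = TrialData(series={k: trial.series[k] for k in baseline_keys},
                    prompts=[], ground_truth={}, config=trial.config)
    day_df, _ = analyze_prompt_effects(sub, **kwargs)
    return weekly_prompt_effect(day_df)


def prompt_effect_tests(weekly_effects: pd.DataFrame, n_boot: int = 10_000,
                        seed: int = 0) -> pd.DataFrame:
    """Paired one-tailed (increase) tests of each week's effect magnitude
    against the baseline control, per signal and window length."""
    combos = weekly_effects[["signal", "window"]].drop_duplicates() \
        .sort_values(["signal", "window"]) if not weekly_effects.empty else \
        pd.DataFrame(columns=["signal", "window"])
    weeks = sorted(p for p in weekly_effects.get("period", pd.Series(dtype=object))
                   .unique() if p != "baseline") if not weekly_effects.empty else []
    seeds = np.random.SeedSequence(seed).generate_state(
        max(len(combos) * max(len(weeks), 1), 1))
    rows = []
    k = 0
    for _, combo in combos.iterrows():
        sub = weekly_effects[(weekly_effects["signal"] == combo["signal"])
                             & (weekly_effects["window"] == combo["window"])]
        pivot = sub.pivot(index="participant_id", columns="period",
                          values="delta")
        for week in weeks:
            comp_seed = int(seeds[k] % (2 ** 31)); k += 1
            row = {"signal": combo["signal"], "window": int(combo["window"]),
                   "period": week}
            if "baseline" not in pivot.columns or week not in pivot.columns:
                rows.append({**row, "note": "missing period"})
                continue
            sample = PairedSample(ids=list(pivot.index),
                                  baseline=pivot["baseline"].to_numpy(),
                                  week=pivot[week].to_numpy(),
                                  direction="increase")
            try:
                res = bootstrap_paired_t(sample, n_boot=n_boot, seed=comp_seed)
            except (InsufficientDataError, ZeroVarianceError) as exc:
                rows.append({**row, "note": f"not computable: {exc}"})
                continue
            rows.append({**row, "n": res.n, "t": res.t, "df": res.df,
                         "p_classic": res.p_classic,
                         "p_bootstrap": res.p_bootstrap,
                         "mean_diff": res.mean_diff,
                         "significant": res.significant, "note": ""})
    return pd.DataFrame(rows)
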