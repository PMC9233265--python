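"""Paired one-tailed t-tests, classic and bootstrapped.

Every intervention week is compared with the baseline week within
participants.  The classic test is Student's paired t with the alternative
fixed per outcome (sedentary time decreases; activity outcomes increase).
Because trial samples are small, a bootstrap version resamples the
null-centered paired differences and recomputes the t statistic; the
reported bootstrap p uses the add-one rule so it can never be exactly zero.

Reported ``t`` follows the week-minus-baseline orientation regardless of
the alternative's direction, matching the usual reporting convention
(a significant decrease shows a negative t with a small one-tailed p).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import OUTCOME_COLUMNS

ALPHA = 0.05

#: One-tailed alternatives fixed a priori per outcome.
DEFAULT_DIRECTIONS: Dict[str, str] = {
    "sedentary_minutes": "decrease",
    "met_mvpa_minutes": "increase",
    "hr_mvpa_minutes": "increase",
    "step_count": "increase",
}


class ZeroVarianceError(ValueError):
    """All paired differences are identical; the t statistic is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than two complete pairs after listwise deletion."""


@dataclass
class PairedSample:
    """Within-subject paired values with a fixed one-tailed alternative
    (``increase`` means week > baseline)."""

    ids: Sequence[str]
    baseline: Sequence[float]
    week: Sequence[float]
    direction: str = "increase"

    def __post_init__(self):
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if not (len(self.ids) == len(self.baseline) == len(self.week)):
            raise ValueError("ids, baseline and week must have equal lengths")

    def complete_differences(self) -> np.ndarray:
        """Week-minus-baseline differences after listwise deletion."""
        b = np.asarray(self.baseline, dtype=float)
        w = np.asarray(self.week, dtype=float)
        keep = ~np.isnan(b) & ~np.isnan(w)
        return (w - b)[keep]


@dataclass
class TestResult:
    n: int
    t: float                       # week-minus-baseline orientation
    df: int
    p_classic: float
    mean_diff: float               # mean(week - baseline)
    direction: str
    p_bootstrap: Optional[float] = None
    n_boot: int = 0
    seed: Optional[int] = None

    @property
    def significant(self) -> bool:
        return self.p_classic < ALPHA


def _oriented_differences(sample: PairedSample) -> np.ndarray:
    d = sample.complete_differences()
    if d.size < 2:
        raise InsufficientDataError(
            f"need >=2 complete pairs, have {d.size}")
    oriented = d if sample.direction == "increase" else -d
    if np.std(oriented, ddof=1) == 0:
        raise ZeroVarianceError("paired differences have zero variance")
    return oriented


def paired_t_one_tailed(sample: PairedSample) -> TestResult:
    """Classic paired one-tailed t-test.

    t = mean(d) / (sd(d)/sqrt(n)) with d oriented so the alternative is
    positive; p is the upper-tail Student-t probability on n-1 df.
    """
    oriented = _oriented_differences(sample)
    n = oriented.size
    t_or = oriented.mean() / (oriented.std(ddof=1) / np.sqrt(n))
    p = float(sps.t.sf(t_or, df=n - 1))
    sign = 1.0 if sample.direction == "increase" else -1.0
    return TestResult(n=n, t=float(sign * t_or), df=n - 1, p_classic=p,
                      mean_diff=float(sign * oriented.mean()),
                      direction=sample.direction)


def bootstrap_paired_t(sample: PairedSample, n_boot: int = 10_000,
                       seed: int = 0) -> TestResult:
    """Classic test plus a bootstrap p-value.

    The oriented differences are centered to the null (d - mean(d)) and
    resampled with replacement ``n_boot`` times; the bootstrap p is
    ``(1 + #{t* >= t_obs}) / (n_boot + 1)``.  Deterministic under the seed
    and invariant to participant order.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    result = paired_t_one_tailed(sample)
    oriented = _oriented_differences(sample)
    n = oriented.size
    t_obs = oriented.mean() / (oriented.std(ddof=1) / np.sqrt(n))
    centered = np.sort(oriented - oriented.mean())  # order-invariant draws
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    res = centered[idx]
    m = res.mean(axis=1)
    s = res.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(s > 0, m / (s / np.sqrt(n)),
                          np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)))
    p_boot = (1.0 + np.sum(t_star >= t_obs)) / (n_boot + 1.0)
    result.p_bootstrap = float(p_boot)
    result.n_boot = n_boot
    result.seed = seed
    return result


def week_vs_baseline_suite(weekly: pd.DataFrame,
                           directions: Optional[Dict[str, str]] = None,
                           n_boot: int = 10_000, seed: int = 0,
                           outcomes: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """One paired comparison per outcome and intervention week.

    ``weekly`` is the weekly-outcome table (participant_id, period, one
    column per outcome).  Missing participant-periods are listwise-deleted
    per comparison; a comparison left with fewer than two pairs (or with
    degenerate differences) is reported as not computable rather than
    failing the suite.  Significance is flagged at alpha = .05, uncorrected.
    """
    directions = directions or DEFAULT_DIRECTIONS
    outcomes = list(outcomes or [c for c in OUTCOME_COLUMNS
                                 if c in weekly.columns])
    weeks = sorted(p for p in weekly["period"].unique() if p != "baseline")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(outcomes) * max(len(weeks), 1))
    rows = []
    k = 0
    for outcome in outcomes:
        pivot = weekly.pivot(index="participant_id", columns="period",
                             values=outcome)
        for week in weeks:
            comp_seed = int(seeds[k] % (2 ** 31)); k += 1
            row = {"outcome": outcome, "period": week,
                   "direction": directions.get(outcome, "increase")}
            if "baseline" not in pivot.columns or week not in pivot.columns:
                rows.append({**row, "note": "missing period"})
                continue
            sample = PairedSample(ids=list(pivot.index),
                                  baseline=pivot["baseline"].to_numpy(),
                                  week=pivot[week].to_numpy(),
                                  direction=row["direction"])
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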