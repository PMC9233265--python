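"""Change-point detection, selection, effect magnitudes and the
prompt-effect test chain."""
import numpy as np
import pandas as pd
import pytest

from promptpa import (EffectSpec, SimulationConfig, analyze_prompt_effects,
                      baseline_control, detect_change_points,
                      effect_magnitude, prompt_effect_tests, repair_gaps,
                      select_best_after_cutoff, simulate_trial,
                      weekly_prompt_effect)
from promptpa.changepoint import Candidate, DayExcludedError, analyze_day

from conftest import make_series


def brute_force_best_split(x, lo=None, hi=None, min_size=2):
    """Independent exhaustive scan: split point minimizing total SSE."""
    n = len(x)
    lo = min_size if lo is None else max(lo, min_size)
    hi = n - min_size + 1 if hi is None else min(hi, n - min_size + 1)
    best_k, best_sse = None, np.inf
    for k in range(lo, hi):
        left, right = x[:k], x[k:]
        sse = ((left - left.mean()) ** 2).sum() + \
            ((right - right.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    return best_k


class TestRepairGaps:
    def test_complete_series_unchanged(self):
        x = np.arange(100, dtype=float)
        assert np.array_equal(repair_gaps(x), x)

    def test_single_gap_linear_midpoint(self):
        x = np.array([10.0, np.nan, 20.0])
        assert repair_gaps(x)[1] == 15.0

    def test_five_missing_repaired_six_excluded(self):
        x = np.full(1440, 50.0)
        x[100:105] = np.nan
        assert not np.isnan(repair_gaps(x)).any()
        x[105] = np.nan
        with pytest.raises(DayExcludedError):
            repair_gaps(x)

    def test_boundary_gap_carries_nearest_value(self):
        x = np.array([np.nan, np.nan, 7.0, 8.0])
        out = repair_gaps(x)
        assert out[0] == 7.0 and out[1] == 7.0


class TestDetection:
    def test_constant_series_has_no_candidates(self):
        assert detect_change_points(np.full(240, 80.0)) == []

    def test_noiseless_step_found_exactly(self):
        x = np.zeros(240)
        x[150:] = 10.0
        cands = detect_change_points(x)
        assert [c.index for c in cands] == [150]
        res = effect_magnitude(x, 150, 30, cands[0].gain)
        assert res.delta == pytest.approx(10.0)

    def test_top_candidate_matches_exhaustive_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            m = int(rng.integers(20, 220))
            x = rng.normal(0, 1, 240)
            x[m:] += 3.0
            cands = detect_change_points(x)
            top = max(cands, key=lambda c: c.gain)
            assert top.index == brute_force_best_split(x)

    def test_missing_values_rejected(self):
        x = np.zeros(240)
        x[5] = np.nan
        with pytest.raises(ValueError, match="repair"):
            detect_change_points(x)

    def test_penalty_suppresses_pure_noise_sometimes(self):
        rng = np.random.default_rng(8)
        empties = sum(not detect_change_points(rng.normal(0, 1, 240))
                      for _ in range(200))
        assert empties > 100  # most pure-noise windows yield nothing


class TestSelection:
    def test_post_cutoff_restriction_beats_stronger_earlier_candidate(self):
        cands = [Candidate(70, 500.0), Candidate(150, 80.0)]  # 16:10, 17:30
        sel = select_best_after_cutoff(cands, window_start=900, cutoff=1020)
        assert sel == (1050, 80.0)

    def test_none_when_no_candidate_qualifies(self):
        assert select_best_after_cutoff([Candidate(50, 900.0)],
                                        window_start=900) is None
        assert select_best_after_cutoff([], window_start=900) is None

    def test_equal_scores_tie_break_to_earlier_minute(self):
        cands = [Candidate(180, 64.0), Candidate(130, 64.0)]
        sel = select_best_after_cutoff(cands, window_start=900, cutoff=1020)
        assert sel == (1030, 64.0)


class TestEffectMagnitude:
    def test_constant_series_zero_delta(self):
        x = np.full(1440, 80.0)
        assert effect_magnitude(x, 1050, 30).delta == 0.0

    @pytest.mark.parametrize("length", [30, 60])
    def test_sustained_shift_recovered_exactly(self, length):
        x = np.full(1440, 80.0)
        x[1050:1050 + 60] = 90.0
        assert effect_magnitude(x, 1050, length).delta == pytest.approx(10.0)

    def test_half_window_dilution(self):
        # a 30-minute effect averaged over a 60-minute window halves
        x = np.zeros(1440)
        x[1050:1080] = 10.0
        assert effect_magnitude(x, 1050, 60).delta == pytest.approx(5.0)

    def test_insufficient_window_dropped(self):
        x = np.full(1440, 5.0)
        assert effect_magnitude(x, 1435, 30) is None  # 5 post minutes < 15


class TestLocalizationAndRecovery:
    def test_noisy_localization_within_two_minutes(self):
        # mean shift of twice the noise SD: the selected change point should
        # land within +/-2 minutes of the truth in at least 90% of windows
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            m = int(rng.integers(130, 220))
            x = rng.normal(0, 1, 240)
            x[m:] += 2.0
            sel = select_best_after_cutoff(detect_change_points(x),
                                           window_start=0, cutoff=120)
            hits += sel is not None and abs(sel[0] - m) <= 2
        assert hits / n_sim >= 0.90

    def test_injected_magnitude_recovered_without_bias(self):
        # +10 bpm for 60 minutes on a flat day at the generator's default
        # heart-rate noise level: mean recovered delta within 0.5 bpm
        rng = np.random.default_rng(21)
        deltas = []
        for _ in range(1000):
            hr = 80.0 + rng.normal(0, 3.0, 1440)
            # onset late enough that the return to baseline happens outside
            # the detection frame, so the shift is sustained within it
            m = int(rng.integers(1080, 1120))
            hr[m:m + 60] += 10.0
            ms = make_series(heart_rate=hr)
            results = analyze_day(ms, "heart_rate", effect_windows=(60,))
            deltas.extend(r.delta for r in results)
        assert len(deltas) > 900
        assert abs(np.mean(deltas) - 10.0) < 0.5


class TestWeeklyAggregationAndBaseline:
    def test_toy_deltas_average(self):
        df = pd.DataFrame([
            {"participant_id": "P01", "period": "week1", "signal": "heart_rate",
             "window": 30, "pre_mean": 80, "post_mean": 84, "delta": 4},
            {"participant_id": "P01", "period": "week1", "signal": "heart_rate",
             "window": 30, "pre_mean": 80, "post_mean": 88, "delta": 8}])
        weekly = weekly_prompt_effect(df)
        assert weekly.loc[0, "delta"] == 6.0 and weekly.loc[0, "n_days"] == 2

    def test_single_valid_day_passes_through(self):
        df = pd.DataFrame([{"participant_id": "P01", "period": "week2",
                            "signal": "steps", "window": 60, "pre_mean": 10,
                            "post_mean": 17, "delta": 7}])
        assert weekly_prompt_effect(df).loc[0, "delta"] == 7.0

    def test_baseline_control_null_mean_near_zero(self):
        trial = simulate_trial(SimulationConfig(n_participants=10,
                                                n_periods=2, seed=40))
        ctrl = baseline_control(trial, signals=("heart_rate",),
                                effect_windows=(60,))
        assert set(ctrl["period"]) == {"baseline"}
        vals = ctrl["delta"].to_numpy()
        assert abs(vals.mean()) < 4 * vals.std(ddof=1) / np.sqrt(len(vals)) + 1.0

    def test_baseline_captures_incidental_burst(self):
        cfg = SimulationConfig(n_participants=1, n_periods=2, seed=1,
                               gap_rate_per_day=0)
        trial = simulate_trial(cfg)
        date = trial.dates()[2]
        ms = trial.series[("P01", date)]
        ms.heart_rate[1060:1120] = np.clip(ms.heart_rate[1060:1120] + 25, 30, 220)
        ctrl = baseline_control(trial, signals=("heart_rate",),
                                effect_windows=(60,))
        day_val = ctrl[ctrl["participant_id"] == "P01"]
        assert (day_val["delta"] > 0).any()

    def test_empty_baseline_is_an_error(self):
        trial = simulate_trial(SimulationConfig(n_participants=1,
                                                n_periods=2, seed=3))
        trial.series = {k: v for k, v in trial.series.items()
                        if (k[1] - trial.config.start_date).days >= 7}
        with pytest.raises(ValueError, match="baseline"):
            baseline_control(trial)


class TestPromptEffectTests:
    def test_two_participant_toy_matches_hand_computation(self):
        rows = []
        for pid, base, wk in (("P01", 0.0, 4.0), ("P02", 1.0, 9.0)):
            rows.append({"participant_id": pid, "period": "baseline",
                         "signal": "heart_rate", "window": 60,
                         "pre_mean": 80, "post_mean": 80 + base, "delta": base})
            rows.append({"participant_id": pid, "period": "week1",
                         "signal": "heart_rate", "window": 60,
                         "pre_mean": 80, "post_mean": 80 + wk, "delta": wk})
        res = prompt_effect_tests(weekly_prompt_effect(pd.DataFrame(rows)),
                                  n_boot=1000, seed=0)
        row = res.iloc[0]
        # d = {4, 8}: mean 6, sd 2*sqrt(2), t = 6 / (2*sqrt(2)/sqrt(2)) = 3
        assert row["t"] == pytest.approx(3.0)
        assert row["df"] == 1
        assert row["p_classic"] == pytest.approx(0.10242, abs=1e-4)

    def test_day_with_no_post_cutoff_candidate_contributes_nothing(self):
        ms = make_series(heart_rate=80.0, steps=0.0)
        assert analyze_day(ms, "heart_rate") == []

    def test_excluded_days_are_logged_with_reason(self):
        cfg = SimulationConfig(n_participants=1, n_periods=2, seed=5,
                               gap_rate_per_day=0)
        trial = simulate_trial(cfg)
        date = trial.dates()[0]
        ms = trial.series[("P01", date)]
        ms.steps[100:110] = np.nan
        ms.heart_rate[100:110] = np.nan
        ms.intensity[100:110] = None
        _, log = analyze_prompt_effects(trial, signals=("heart_rate",))
        assert any("missing" in rec["reason"] and rec["date"] == str(date)
                   for rec in log)

    def test_pipeline_determinism(self):
        cfg = SimulationConfig(n_participants=3, n_periods=2, seed=17)
        frames = []
        for _ in range(2):
            day_df, _ = analyze_prompt_effects(simulate_trial(cfg))
            frames.append(day_df)
        pd.testing.assert_frame_equal(frames[0], frames[1])
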