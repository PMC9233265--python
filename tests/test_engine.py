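"""Decision-rule unit and property tests for the intervention engine."""
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from promptpa import engine
from promptpa.engine import (GoalState, REWARD_RULE, TIERS, adapt_goal,
                             classify_prompt_tier, compute_reward,
                             render_prompt, screen_participant, should_remind,
                             update_weekly_goal, who_sufficient)
from promptpa.preprocess import DailySummary


def _day(met_mvpa, steps):
    return DailySummary("P01", None, 0, 0, met_mvpa, 0, steps, 1440)


class TestGoalAdaptation:
    @pytest.mark.parametrize("prev,achieved,expected", [
        (9_000, 10_000, 10_500),   # 5% raise on the achieved average
        (9_000, 8_000, 9_000),     # underperformance holds the goal
        (10_000, 10_000, 10_500),  # meeting the goal exactly still raises
        (10_000, 10_001, 10_501),  # half-up rounding of 10501.05
    ])
    def test_weekly_update(self, prev, achieved, expected):
        assert adapt_goal(prev, achieved) == expected

    def test_negative_achievement_rejected(self):
        with pytest.raises(ValueError):
            adapt_goal(9_000, -1)

    def test_state_update_advances_week(self):
        g = update_weekly_goal(GoalState(9_000, 20, 1), 10_000, 25)
        assert (g.step_goal, g.azm_goal, g.week_index) == (10_500, 26, 2)

    @given(st.lists(st.floats(0, 40_000), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=50)
    def test_goals_never_decrease(self, achieved_seq):
        goal = GoalState(8_000, 10, 0)
        for a in achieved_seq:
            nxt = update_weekly_goal(goal, a, a / 100 + 1)
            assert nxt.step_goal >= goal.step_goal
            assert nxt.azm_goal >= goal.azm_goal
            goal = nxt


class TestPromptTiers:
    @pytest.mark.parametrize("steps,goal,label,lower", [
        (3_900, 10_000, "LT40", 0),
        (4_000, 10_000, "GE40", 40),    # lower bound inclusive
        (5_999, 10_000, "GE40", 40),
        (6_000, 10_000, "GE60", 60),
        (8_000, 10_000, "GE80", 80),
        (10_000, 10_000, "GE100", 100),
        (13_000, 10_000, "GE100", 100),
        (0, 10_000, "LT40", 0),
    ])
    def test_band_assignment(self, steps, goal, label, lower):
        tier = classify_prompt_tier(steps, goal)
        assert (tier.label, tier.lower_bound_pct) == (label, lower)

    def test_nonpositive_goal_rejected(self):
        with pytest.raises(ValueError):
            classify_prompt_tier(100, 0)

    @given(st.floats(0, 1e6), st.floats(1, 1e6))
    @settings(derandomize=True, max_examples=200)
    def test_exactly_one_tier(self, steps, goal):
        pct = 100 * steps / goal
        tier = classify_prompt_tier(steps, goal)
        bounds = [t.lower_bound_pct for t in TIERS] + [float("inf")]
        i = [t.label for t in TIERS].index(tier.label)
        assert bounds[i] <= pct < bounds[i + 1]

    @given(st.floats(0, 1e5), st.floats(0, 1e5), st.floats(1, 1e5))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_steps(self, s1, s2, goal):
        lo, hi = sorted([s1, s2])
        assert classify_prompt_tier(lo, goal).lower_bound_pct \
            <= classify_prompt_tier(hi, goal).lower_bound_pct


class TestPromptRendering:
    def test_worked_example(self):
        msg = render_prompt("Bob", 8_000, 10_000, seed=4)
        assert "Bob" in msg.text and "80%" in msg.text and "8,000" in msg.text
        assert msg.framing == "GE80" and msg.pct_of_goal == 80
        assert msg.health_benefit in msg.text

    def test_zero_steps_is_lowest_tier(self):
        msg = render_prompt("Ana", 0, 10_000, seed=1)
        assert msg.framing == "LT40" and "0" in msg.text

    def test_deterministic_under_seed(self):
        a = render_prompt("Bob", 5_000, 9_000, seed=7)
        b = render_prompt("Bob", 5_000, 9_000, seed=7)
        assert a == b

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            render_prompt("", 100, 1_000)
        with pytest.raises(ValueError):
            render_prompt("Bob", 100, 1_000, benefit_pool=[])

    def test_pool_has_at_least_25_templates(self):
        pool = engine.load_template_pool()
        assert sum(len(v) for v in pool["templates"].values()) >= 25
        assert set(pool["templates"]) == {t.label for t in TIERS}


class TestReminders:
    @pytest.mark.parametrize("hour,steps,elevated,expected", [
        (17, 0, False, True),    # sedentary hour in the window
        (14, 0, False, False),   # before 4 PM
        (21, 0, False, False),   # window is half-open at 9 PM
        (16, 0, False, True),
        (18, 0, True, False),    # HR-raising activity suppresses it
        (17, 120, False, False),  # steps were taken
    ])
    def test_trigger(self, hour, steps, elevated, expected):
        decision = should_remind(hour, steps, elevated)
        assert decision.remind is expected
        assert decision.step_target == 250

    def test_invalid_hour(self):
        with pytest.raises(ValueError):
            should_remind(24, 0, False)


class TestRewards:
    @pytest.mark.parametrize("flags,euros", [
        ([1, 1, 1, 1, 1, 0, 0], 30),
        ([1, 1, 1, 1, 1, 1, 1], 40),
        ([1, 1, 1, 0, 0, 0, 0], 15),
        ([0, 0, 0, 0, 0, 0, 0], 0),
        ([1, 1, 0, 1, 1, 1, 1], 15),   # longest run is 4 -> lower tier
        ([1, 0, 1, 0, 1, 0, 1], 0),
    ])
    def test_examples(self, flags, euros):
        assert compute_reward([bool(f) for f in flags]) == euros

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            compute_reward([True] * 6)

    def test_agrees_with_longest_run_oracle_on_all_128_weeks(self):
        def oracle(flags):
            runs = [len(list(g)) for v, g in itertools.groupby(flags) if v]
            longest = max(runs, default=0)
            return next((REWARD_RULE[d] for d in (7, 5, 3) if longest >= d), 0)

        for flags in itertools.product([False, True], repeat=7):
            assert compute_reward(flags) == oracle(flags)

    def test_flipping_a_day_to_met_never_lowers_the_payout(self):
        for flags in itertools.product([False, True], repeat=7):
            base = compute_reward(flags)
            for i in range(7):
                if not flags[i]:
                    flipped = list(flags)
                    flipped[i] = True
                    assert compute_reward(flipped) >= base


class TestScreens:
    @pytest.mark.parametrize("mvpa,steps,expected", [
        (60, 0, True),        # MVPA threshold alone
        (59, 11_700, True),   # step equivalence alone
        (0, 11_699, False),   # just below both
        (61, 20_000, True),
    ])
    def test_who_sufficiency(self, mvpa, steps, expected):
        assert who_sufficient(_day(mvpa, steps)) is expected

    @pytest.mark.parametrize("score,age,tracker,constraint,expected", [
        (2.7, 16, False, False, True),
        (3.5, 17, False, False, False),   # above the questionnaire cut-off
        (3.0, 18, False, False, True),    # boundary inclusive
        (2.0, 19, False, False, False),   # outside the age band
        (2.0, 17, True, False, False),    # already uses a tracker
        (2.0, 17, False, True, False),    # constraint against activity
    ])
    def test_eligibility(self, score, age, tracker, constraint, expected):
        assert screen_participant(score, age, tracker, constraint) is expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            screen_participant(0.5, 17)
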