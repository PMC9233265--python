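# Methods

This note documents the models, rules and numerical choices behind
`promptpa`, and what the synthetic generator does and does not emulate.

## Trial structure

A within-subject wearable trial: `n_periods` consecutive 7-day measurement
occasions (default 4 — one baseline week, three intervention weeks) for
`n_participants` (default 18). Days are indexed by local clock time,
minute-of-day 0–1439; all intervals are half-open `[start, end)`. On every
non-baseline day one activity prompt is delivered at a minute drawn
uniformly from the 17:00–19:00 window (the delivery time is recorded in the
prompt log; whether real deliveries varied within the window is unknown, so
the uniform draw is an explicit assumption).

## Synthetic data generator

**Steps.** An inhomogeneous burst process. Each minute is *active* with
probability `(1440 − sedentary_base) · w(hour) / 60`, where `w` is a
24-hour activity-share profile summing to 1 (zero overnight, peaks at
lunchtime and late afternoon) and the participant's sedentary budget fixes
the expected number of zero-step minutes. That budget has a population
mean of `sedentary_base` (790 min/day) with between-participant SD 170
min/day and a day-to-day coefficient of variation of 0.15 on the active
remainder — dispersion chosen to match the scale of published
between-participant SDs for sedentary time in this trial design. Active
minutes draw steps
from a gamma distribution (shape 1.2) whose mean is set so the day's
expected total matches the participant-day target; with probability
`exercise_prob` (0.08) the minute is instead an "exercise burst",
normal(85, 20) steps/min. Participant-day targets combine a
between-participant level, normal(14,000, 3,500) steps/day, with a
within-participant day factor, normal(1, 0.25). Step counts are integers.

**Heart rate.** `HR = resting + 0.4 · steps/min + 30 · 1{exercise} +
noise`, with participant resting level normal(80, 6) bpm and white noise
SD 3 bpm; values are rounded to integer bpm and clipped to [30, 220]. There
is no physiological recovery kinetics, HRV or sleep architecture — minute
values are conditionally independent given activity.

**Intensity class.** Fixed cut-offs stand in for the device vendor's
proprietary MET logic (which is not published): 0 steps with HR < 100 bpm →
sedentary; < 60 steps/min → light; 60–109 → moderate; ≥ 110 → vigorous.
Under the defaults a simulated cohort averages ≈ 765 sedentary min/day
(SD ≈ 150 across participants), ≈ 67 MET-MVPA min/day, ≈ 36 HR-MVPA
min/day at the default heart-rate threshold and ≈ 14,000 steps/day — the
same order as published outcome tables for this trial design.

**Non-wear.** Poisson(0.4) contiguous gaps per day, each of length
1 + Poisson(3) minutes, uniform start; gap minutes lose steps, heart rate
and intensity. This emulates forgotten wear/charging but not systematic
(e.g. sleep-linked) non-wear.

**Prompt response.** An injectable per-period effect: from
`onset_lag` minutes after delivery, for `duration` minutes, heart rate is
raised by exactly `delta_hr` and steps by Poisson(`delta_steps`) per
minute. The baseline period's effect is structurally zero. Every injection
is recorded in a ground-truth sidecar so recovery can be scored. The
default is zero effect in every period: injections are experiment inputs,
not defaults.

**What passing tests show.** The generator reproduces the *structure* the
analysis assumes (diurnal profile, evening prompts, non-wear, additive
responses), not real adolescent behavior: there are no activity bouts
longer than one minute beyond chance runs, no weekday/weekend or holiday
effects, and no engagement decay. Validation on this generator therefore
demonstrates correctness and calibration of the inference machinery, not
field effectiveness.

## Decision rules

* **Goals.** New weekly goal = round-half-up of 1.05 × previous week's
  achieved daily average, but held unchanged if the average fell below the
  previous goal ("underperformance"). Since the raise only applies when
  achieved ≥ previous goal, goals never decrease. Step and
  active-zone-minute goals adapt independently. Initial goals are a 5%
  raise on the baseline-week averages.
* **Prompt tiers.** Percent of goal partitioned at 0/40/60/80/100 with
  inclusive lower bounds; the top tier is unbounded. Messages substitute
  five variables (name, steps so far, percent of goal, a health-benefit
  fact, tier framing) into a pool of ≥25 templates; draws are seeded.
* **Reminders.** During [16:00, 21:00), an hour with zero steps and no
  elevated-heart-rate activity triggers a reminder targeting ≥250 steps.
* **Rewards.** Longest run of consecutive goal-met days in the week maps
  3→€15, 5→€30, 7→€40; runs of 4 or 6 pay the next lower tier, runs under
  3 pay nothing. A "goal-met day" is a day at or above the step goal
  (whether both goals must be met is unspecified in this design; the step
  goal alone is the default and this is configurable at the call site).
* **Screens.** WHO sufficiency: ≥60 MET-MVPA min/day or ≥11,700 steps/day.
  Eligibility: activity questionnaire score ≤3 of 5, age 16–18, no actively
  used tracker, no constraint against physical activity.

## Preprocessing

Daily summaries count intensity classes and threshold heart-rate minutes
(HR-MVPA default 142 bpm ≈ 50% heart-rate reserve for a 16-year-old with
resting HR 80; configurable). Days with **more than 500** MET-MVPA minutes
are excluded as device artifacts (strict inequality, applied day-wise).
Days are assigned to periods by `floor((date − start)/7)`. Weekly outcomes
are means over the period's retained days — 7/7 wear is not required,
since real trials report despite missingness; a participant-period with no
retained days is missing and is listwise-deleted per comparison downstream
(this is what makes degrees of freedom vary between comparisons).

## Inference

**Classic test.** Paired one-tailed t: differences oriented so the
alternative is positive (sedentary: decrease; MVPA and steps: increase;
prompt effects: increase), p from the upper tail of Student's t with n−1
df. The reported `t` keeps the natural week-minus-baseline orientation.
Zero-variance differences and n < 2 raise explicit degenerate errors; the
suite reports such comparisons as not computable rather than failing.

**Bootstrap.** The literature for this design names no scheme, so the
choice is documented here: oriented differences are centered to the null
(d − mean d), resampled with replacement `n_boot` (default 10,000) times,
the t statistic recomputed per resample, and
p = (1 + #{t* ≥ t_obs})/(n_boot + 1) — the add-one form avoids p = 0.
Resamples are drawn from the sorted differences, making the p-value
invariant to participant order under a fixed seed. α = .05 throughout, with
no multiplicity correction (deliberate for a pilot-scale design; every p is
reported).

## Change-point analysis

* **Gap repair.** Up to 5 total missing minutes per day are linearly
  interpolated between flanking values (nearest-value carry at the day's
  edges); more than 5 excludes the day, with the reason logged.
* **Detection.** Binary segmentation on the 3 PM–7 PM window (240 minutes)
  with the within-segment SSE cost. The first split is exactly the
  exhaustive single-split scan; recursion continues while the best split's
  SSE reduction strictly exceeds an SIC-style penalty
  `2 · σ̂² · log T`, with σ̂ estimated robustly from first differences
  (MAD × 1.4826/√2) so that isolated mean shifts do not inflate it. A
  constant window yields no candidates; many pure-noise windows yield none,
  which is intended — those days contribute nothing and are logged, never
  imputed.
* **Selection.** Among candidates at or after 17:00, the largest SSE
  reduction wins; exact ties break to the earliest minute. "Best-fitting"
  is not defined in the source design; largest SSE reduction is this
  package's operationalization.
* **Magnitude.** `delta = mean[cp, cp+L) − mean[cp−L, cp)` for L ∈
  {30, 60}. Effect windows may extend past 19:00 into the day's repaired
  data (a 60-minute post-window from a 6:30 PM change point must leave the
  detection frame); each window must retain at least L/2 observed minutes.
* **Aggregation and control.** Day deltas are averaged per participant,
  period, signal and window length. The baseline week runs through the
  identical procedure, controlling for random evening variation, and each
  week is tested against it (paired, one-tailed increase). Steps and heart
  rate are analyzed as separate signals with separately selected change
  points.

**Known attenuation.** When an injected (or real) response *ends inside*
the detection frame, the procedure may select the response's end — a
downward mean shift — as the best-fitting change point, so recovered
weekly magnitudes are attenuated toward zero relative to the injected
per-minute effect (the worked example recovers ≈5.3 of +10 bpm but remains
clearly significant). For responses sustained past the frame, recovery is
essentially unbiased (mean absolute bias < 0.5 bpm at the default noise
level in the test suite). This mirrors a real limitation of
change-point-based prompt evaluation, not an implementation artifact.

## Validation scales

The test suite exercises: exhaustive 128-case reward-rule checks against a
brute-force longest-run oracle; detector equivalence with an exhaustive
SSE scan on 1,000 random shifted windows; localization within ±2 minutes
in ≥90% of 1,000 windows at a 2σ shift; null calibration of the bootstrap
test (500 replications, n = 18) and of the full pipeline (500 simulated
null trials of 12 participants, binomial 99% bounds around α = .05); and
effect recovery (100 simulated 18-participant trials with a +10 bpm,
60-minute response injected only in period 2). Simulation sizes were
chosen as the smallest that give the binomial/Monte-Carlo checks useful
resolution.

## Limitations

Beyond the generator's simplifications listed above: the HR-MVPA threshold
is a single configurable cut-off, not the vendor's zone algorithm; the
pipeline handles at most one prompt per day; and the change-point model is
piecewise-constant in the mean (no trends, no variance changes).
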