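# Methods

This note documents the models, rules and numerical choices behind
`steptailor`, the assumptions they rest on, and what the synthetic-data
experiments can and cannot show.

## Tailored advice engine

**Staging.** Participants are assigned one of the five
transtheoretical-model stages from two ingredients: the pedometer-measured
average daily steps and two intention questions (step more within 6
months? within 1 month?):

| condition | stage |
| --- | --- |
| < 10,000 steps/day, 6-month intention "no" | precontemplation |
| < 10,000, 6-month "yes", 1-month "no" | contemplation |
| < 10,000, 1-month "yes" | preparation |
| ≥ 10,000, goal met < 6 months or unknown | action |
| ≥ 10,000, goal met ≥ 6 months | maintenance |

Two conventions are deliberate. The 1-month intention dominates: a
participant answering "yes" to the 1-month horizon is a preparer whatever
the 6-month answer says, because the more proximal intention is the more
informative one. And the action/maintenance boundary is the conventional
six months of sustained behavior; when the duration is unknown the
participant is staged conservatively as *action*, which yields the more
supportive (rather than minimal) advice. Participants already at goal are
never an error case — they receive action/maintenance advice with an empty
schedule.

**Goal schedule.** Week $k$ (1-based) has the daily goal
$\min(b + k \cdot i,\ 10{,}000)$ for baseline $b$ and chosen increment
$i \in \{500, 1000\}$ steps/week. The first scheduled week already sits one
increment above baseline (the schedule is an *increase* plan, not a
restatement of the status quo), and the ladder is cut exactly at 10,000.

**Message bank.** All advice text lives in
`src/steptailor/data/message_bank.json` as (determinant, answer pattern,
stage) rules, so wording is configurable without code change. The bank is
*total*: every legal answer of every questionnaire item has a matching
rule, which the test suite enumerates exhaustively (all 45 barrier pairs ×
7 benefits × 2 familiarity levels under all five stages, with the
attitude/self-efficacy/social-support answer sets cycled through). Two
behaviors are rule-governed rather than free text: the pedometer primer
appears exactly when the participant is unfamiliar with a pedometer, and
barrier feedback returns exactly one message per chosen barrier (the
questionnaire asks for exactly two). Composition is deterministic;
repeat requests with a previous step level add a progress note keyed by
the sign of the change, with deltas rounded half-away-from-zero.

## Pedometer data reduction

A day is valid when the device recorded **more than** 100 steps (strict)
and was worn **at least** 8 hours. Daily counts above 20,000 are truncated
to 20,000 *before* averaging. The average requires at least 5 valid days
on *consecutive calendar dates* — one invalid or missing day breaks the
run — and, by default, at least one weekend day inside the run; the
weekend condition is a flag because it originates in the wearing protocol
rather than in an explicit validity rule. When several runs qualify, the
longest (earliest on ties) is used. Invalid waves return a typed marker
with a reason code (`empty`, `too_few_consecutive`, `no_weekend_day`)
instead of raising, since invalid waves are expected data, not errors.

Wear hours are reconstructed, not measured: the device is worn from rising
to bed, so wear = 24 h − sleep window (default 8 h, configurable) − logged
non-wear hours, floored at 0. Logged non-walking activities (swimming,
cycling) become annotations on the day, never step counts.

## IPAQ scoring

Domain minutes/day = days/week × min/day ÷ 7. Cleaning follows the public
IPAQ short-form protocol: per-domain episodes under 10 min/day are zeroed,
per-domain minutes capped at 180/day, and respondents totalling more than
960 min/day of activity are *flagged* excluded (the flag is evaluated on
the reported, pre-truncation minutes; truncation is still applied so the
record remains usable). All three constants are configuration defaults,
not hard-coded behavior. Total activity is the sum of the walking,
moderate and vigorous min/day values.

The positive skew typical of self-reported activity is handled by a
screen-then-transform step: a Kolmogorov–Smirnov normality test in its
Lilliefors form (mean and SD estimated from the sample — the population
moments are never known here) at α = .05 triggers a log(x+1) transform;
the +1 admits the many legitimate zeros. Constant vectors pass through
untransformed (zero-variance guard); fewer than 8 observations is an
error because the screen is meaningless there.

## Synthetic cohorts

The simulator emulates a trial of 8 white-collar worksites (3 schools, 3
commercial, 2 nonprofit, each arm containing every type) randomized by
worksite to intervention (IG) or waiting-list control (CG), measured at
baseline, 1 month and 3 months.

*Steps.* Each participant's three wave values are multivariate normal with
the configured arm × wave means and SDs, equicorrelated across waves with
test-retest correlation ρ (default 0.6 — a typical week-long pedometer
stability value; the trial tables publish only marginal SDs, so some
within-person correlation must be assumed to make repeated-measures power
realistic). An optional worksite random intercept with SD `cluster_sd`
(default 0, matching the trial's non-significant worksite variance) is
subtracted from the within-person wave variances so the *marginal* wave
SDs always equal the configured ones; configurations where a wave SD does
not exceed the cluster SD are rejected. Only the 20,000-step truncation is
applied to the draws — a zero floor is deliberately *not* applied, because
clipping would bias the wave means/SDs the generator is calibrated to
reproduce (negative draws are rare, ≈0.8% in the most dispersed wave, and
are documented artifacts rather than silently repaired data).

*Self-report.* Walking/moderate/vigorous minutes are drawn lognormal with
the configured mean × `selfreport_bias` and SD, giving the heavy right
tail that makes the log-transform path fire on realistic data; the bias
factor defaults to 1.0 since the default means are themselves self-reported
values. Sitting is normal per arm.

*Dropout.* Monotone (no re-entry): a participant retained at T1 is
retained at T2 with probability $r_2/r_1$, so the *marginal* retention at
each wave equals the configured $r_1, r_2$ (defaults are the trial's flow
fractions, 101/137 and 91/137 for IG, 112/137 and 107/137 for CG).
Missingness is completely at random within arm, consistent with the
trial's finding of no completer/dropout differences on measured variables.
A commercial-worksite hazard multiplier (default 1.0) can concentrate
dropout in commercial sites; the default keeps the arm-level marginals
exactly at the flow fractions.

*Seeding.* Every participant (and every cluster effect and dropout draw)
has its own stream spawned from the master seed, so enlarging a cohort or
adding dropout never perturbs existing draws.

The default configurations carry the published arm × wave moments for the
full randomized sample (n = 137 + 137) and for the at-risk subsample
(n = 65 + 74); T0/T1 moments come from the baseline-to-one-month effect
table and T2 from the baseline-to-three-month table. The published flow
narrative elsewhere quotes slightly higher attrition percentages than the
flow counts imply; the simulator follows the counts.

## Analysis pipeline

*Baseline comparison* uses two-sided independent t tests (quantitative)
and uncorrected Pearson chi-square (categorical); characteristics at
p ≤ .05 become the default ANCOVA covariate set. In the trial this
pipeline mirrors, baseline sitting time is that covariate, and it is the
package default; place of residence was only borderline (.05 < p ≤ .10)
and is excluded unless requested. Borderline results are flagged as such
in all outputs.

*Worksite variance check.* Before treating participants as independent,
the worksite variance component is tested by a likelihood-ratio comparison
(ML, df = 1) of a participant-random-intercept model of the outcome across
waves against the same model with participants nested in worksites. The
statistic is clamped at 0 (boundary convention); the p-value uses the
plain χ²₁ reference, which is conservative at the boundary.

*Repeated-measures ANCOVA.* For each outcome and wave pair, available-case
(participants observed at both waves — matching the varying ns of the
trial's tables, not complete-case). The time × condition interaction is
the condition effect on within-person change, adjusted for baseline
covariates, F(1, n − 2 − #covariates); without covariates this equals the
mixed-ANOVA interaction F exactly, an equivalence the suite verifies
against an independent implementation (`pingouin.mixed_anova`). The
transform screen runs on the pooled two-wave values; when it fires the
test uses log(x+1) values while descriptive means/SDs stay raw, keeping
test scale and table scale decoupled. The baseline of the analyzed outcome
itself is never entered as a covariate (it is already differenced out).

*Summaries.* At-risk subsetting is strict (< 10,000 at baseline);
guideline attainment is the percentage of *observed* participants at
≥ 10,000 steps/day, rounded half-away-from-zero to whole percent;
per-arm mean changes are rounded to whole steps for the pedometer outcome
and to 0.01 min/day otherwise. Dropout analysis defines completion as
observed data at the final wave and tests it against arm (2×2, df 1) and
worksite type (2×3, df 2) plus t tests on continuous baselines.

## Problem sizes and calibration experiments

The simulation experiments shipped with the package use the trial-sized
cohorts (139 or 274 participants): 200 replicates for the
intervention-effect round trip (the Monte-Carlo SE of the mean IG
baseline→1-month change is then ≈28 steps/day, against an expected change
of ≈1056), 1000 replicates for the type-I calibration of the ANCOVA
(99% binomial band 0.036–0.064 around α = .05), and 20–60 replicates for
power-style majority checks. These choices keep the full suite in the
low minutes on a single CPU.

## Limitations

* The generator reproduces first and second moments, the between-wave
  correlation and the missingness pattern of a real cohort, but not
  questionnaire psychometrics, seasonal recruitment effects, floor effects
  at zero steps, or outcome-dependent dropout; passing round-trip tests
  therefore validates the pipeline's statistics, not any claim about new
  field data.
* Self-report outcomes are drawn independently across waves (no
  within-person tracking in the minutes outcomes).
* The message bank ships one substantive rule per answer; a production
  deployment would localize and expand the texts (the engine is agnostic
  to wording).
* The worksite-variance LRT uses the conservative plain χ²₁ reference;
  with very few clusters (8 here) its power is limited, which is exactly
  why the downstream analysis treats the cluster check as a gate rather
  than modeling worksites throughout.
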