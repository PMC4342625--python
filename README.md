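# steptailor

Tools for building and evaluating a web-based, computer-tailored,
pedometer-based physical-activity intervention for working adults.

Sedentary employees rarely reach the widely used guideline of **10,000
steps a day**. One effective intervention format hands each participant a
pedometer, measures their actual average daily steps for a week, and then
generates individualized written advice from their step level and a short
psychosocial questionnaire (intentions, attitudes, self-efficacy, social
support, knowledge, perceived benefits and barriers). `steptailor`
implements that advice engine together with everything needed to evaluate
such an intervention in a cluster-randomized trial: pedometer data
reduction, IPAQ short-form scoring, a synthetic-cohort simulator, and the
trial's statistical pipeline.

## What is inside

| Module | Purpose |
| --- | --- |
| `steptailor.advice_engine` | Stage-of-change classification (transtheoretical model), weekly 500/1000-step goal schedules toward 10,000 steps/day, rule-matched advice text from an external message bank, progress feedback on repeat requests |
| `steptailor.pedometer_processing` | Wear-time validity (>100 steps **and** ≥8 h worn), truncation at 20,000 steps/day, averaging over ≥5 consecutive valid days (≥1 weekend day) |
| `steptailor.ipaq_scoring` | IPAQ short-form cleaning (10-min floor, 180-min cap, 960-min exclusion flag), min/day scoring, skewness-triggered log(x+1) transform |
| `steptailor.trial_simulator` | 8-worksite, 2-arm, 3-wave synthetic cohorts with configurable between-wave correlation, worksite variance, and monotone differential dropout |
| `steptailor.trial_analysis` | Baseline t/chi-square comparisons, dropout analysis, worksite variance LRT, 2×2 repeated-measures ANCOVA per outcome, at-risk subsetting, guideline-attainment percentages |

The core inferential statistic is the **time × condition interaction** of a
two-wave repeated-measures ANCOVA. For waves $t_1, t_2$ and outcome
$Y_{it}$, the interaction is tested as the condition effect in

$$Y_{i t_2} - Y_{i t_1} = \beta_0 + \beta_1\,\mathrm{IG}_i + \gamma^\top z_i + \varepsilon_i,$$

with baseline covariates $z_i$ (sitting time by default) and
$F(1,\,n-2-\lvert z\rvert) = t_{\beta_1}^2$ — algebraically identical to
the classical mixed-ANOVA interaction F when no covariates are used (this
equivalence is tested against `pingouin.mixed_anova`). Outcomes are
log(x+1)-transformed before testing whenever a Kolmogorov–Smirnov
(Lilliefors) screen rejects normality; descriptive means stay on the raw
scale.

## Worked example

```python
from steptailor import TailoringResponse, compose_advice

response = TailoringResponse(
    avg_daily_steps=6700, intent_6mo="yes", intent_1mo="yes",
    pedometer_familiarity="no",
    barriers=("lack_of_time", "external_factors"),
    previous_avg_daily_steps=6000,
)
doc = compose_advice(response, increment=500)
print(doc.stage.value)
print(doc.schedule.weekly_goals)
print(doc.progress_note)
```

prints

```
preparation
(7200, 7700, 8200, 8700, 9200, 9700, 10000)
Since your previous advice your average rose from 6000 to 6700 steps a day, an increase of 700 steps. Keep it up!
```

The participant walks 6,700 steps/day and intends to do more within a
month, so they are staged as a *preparer* and receive a directive
introduction plus a 7-week schedule that adds 500 steps/week until the
10,000 goal. And a full synthetic trial:

```python
from steptailor import (default_config_from_paper, simulate_cohort,
                        apply_dropout, effect_table)

cfg = default_config_from_paper("at_risk")
cohort = apply_dropout(simulate_cohort(cfg, seed=1), cfg, seed=2)
table = effect_table(cohort, sample="at_risk", contrast="t0t1")
print(table.loc[table.outcome == "steps",
                ["n_IG", "n_CG", "mean_IG_1", "mean_IG_2", "F", "p"]])
```

```
   n_IG  n_CG    mean_IG_1    mean_IG_2          F         p
0    46    55  6662.663496  7971.177275  20.415732  0.000017
```

— the intervention arm rises by roughly a thousand steps/day while the
control arm does not, and the interaction F is significant, mirroring the
design the defaults encode.

Each stage is also available from the shell:

```bash
steptailor simulate --sample at_risk --seed 1 --out cohort.csv
steptailor analyze --cohort cohort.csv --sample at_risk --out tables/
steptailor advise response.json --increment 500 --out advice.md
steptailor qc-steps steps.csv --out summary.csv
steptailor score-ipaq ipaq.csv --out scored.csv
```

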