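"""Trial statistics for 2-arm, 3-wave physical-activity cohorts.

Reproduces the analysis pipeline of a cluster-randomized pedometer trial
on real or simulated cohorts:

* baseline comparisons (t tests for quantitative, chi-square for
  qualitative characteristics), returning the significant characteristics
  as the downstream covariate set;
* dropout analysis (completion vs arm and worksite type, t tests on
  continuous baselines);
* a likelihood-ratio check of the worksite-level variance component, which
  justified collapsing the three-level model into repeated-measures ANCOVA;
* per-outcome 2x2 repeated-measures ANCOVA (time within, condition
  between), run on log(x+1)-transformed values whenever the skewness
  screen fires, with descriptives always reported on the raw scale;
* the at-risk subset (below 10,000 steps/day at baseline), guideline
  attainment percentages, and per-arm mean-change summaries.

The time x condition interaction is tested as the condition effect on
change scores adjusted for baseline covariates, which for two waves is the
classical repeated-measures interaction F with F(1, n - 2 - #covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from steptailor.ipaq_scoring import log_transform_if_skewed

STEP_GOAL = 10_000.0
ALPHA = 0.05
BORDERLINE = 0.10
OUTCOMES = ("steps", "sitting", "walking", "moderate", "vigorous", "total_pa")
CONTRASTS = {"t0t1": ("T0", "T1"), "t1t2": ("T1", "T2"), "t0t2": ("T0", "T2")}


def _with_total_pa(cohort: pd.DataFrame) -> pd.DataFrame:
    if "total_pa" in cohort.columns:
        return cohort
    out = cohort.copy()
    out["total_pa"] = out["walking"] + out["moderate"] + out["vigorous"]
    return out


def _baseline_steps(cohort: pd.DataFrame) -> pd.Series:
    t0 = cohort[(cohort["wave"] == "T0") & cohort["observed"]]
    return t0.set_index("participant_id")["steps"]


def at_risk_filter(cohort: pd.DataFrame) -> pd.DataFrame:
    """Retain participants strictly below 10,000 steps/day at baseline."""
    base = _baseline_steps(cohort)
    keep = base.index[base < STEP_GOAL]
    return cohort[cohort["participant_id"].isin(keep)].copy()


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA

    @property
    def borderline(self) -> bool:
        return ALPHA < self.p_value <= BORDERLINE


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, df=1, two-tailed."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(res.statistic), df=1,
                      p_value=float(res.pvalue))


def chi_square_table(table: np.ndarray) -> TestResult:
    """Uncorrected Pearson chi-square for a general r x c count table."""
    res = stats.chi2_contingency(np.asarray(table, dtype=float),
                                 correction=False)
    return TestResult(statistic=float(res.statistic), df=float(res.dof),
                      p_value=float(res.pvalue))


@dataclass(frozen=True)
class BaselineRow:
    characteristic: str
    kind: str  # "quantitative" / "categorical"
    summary_ig: str
    summary_cg: str
    test: str  # "t" / "chi2"
    result: Optional[TestResult]


def baseline_comparison(
    cohort: pd.DataFrame,
    quantitative: Sequence[str] = ("steps", "sitting", "walking", "moderate",
                                   "vigorous", "total_pa"),
    categorical: Sequence[str] = (),
) -> tuple[list[BaselineRow], list[str]]:
    """Compare arms at baseline; return the rows and the covariate set.

    Quantitative characteristics are compared by two-sided independent
    t tests, categorical ones by uncorrected chi-square.  Characteristics
    differing at p <= .05 form the covariate set for the downstream ANCOVA.
    """
    data = _with_total_pa(cohort)
    t0 = data[(data["wave"] == "T0") & data["observed"]]
    ig = t0[t0["arm"] == "IG"]
    cg = t0[t0["arm"] == "CG"]
    rows: list[BaselineRow] = []
    covariates: list[str] = []
    for col in quantitative:
        x, y = ig[col].dropna(), cg[col].dropna()
        if x.empty or y.empty or (x.nunique() == 1 and y.nunique() == 1):
            warnings.warn(f"baseline characteristic {col!r} skipped "
                          "(constant or missing)")
            rows.append(BaselineRow(col, "quantitative", "-", "-", "t", None))
            continue
        t, p = stats.ttest_ind(x, y)
        res = TestResult(statistic=float(t), df=len(x) + len(y) - 2,
                         p_value=float(p))
        rows.append(BaselineRow(
            col, "quantitative",
            f"{x.mean():.1f} ({x.std(ddof=1):.1f})",
            f"{y.mean():.1f} ({y.std(ddof=1):.1f})",
            "t", res,
        ))
        if res.significant:
            covariates.append(col)
    for col in categorical:
        tab = pd.crosstab(t0["arm"], t0[col])
        if tab.shape[1] < 2:
            warnings.warn(f"baseline characteristic {col!r} skipped "
                          "(single level)")
            rows.append(BaselineRow(col, "categorical", "-", "-", "chi2",
                                    None))
            continue
        res = chi_square_table(tab.to_numpy())
        rows.append(BaselineRow(
            col, "categorical",
            "/".join(str(v) for v in tab.loc["IG"]),
            "/".join(str(v) for v in tab.loc["CG"]),
            "chi2", res,
        ))
        if res.significant:
            covariates.append(col)
    return rows, covariates


def cluster_variance_test(cohort: pd.DataFrame,
                          outcome: str = "steps") -> TestResult:
    """Likelihood-ratio test of the worksite-level variance component.

    Compares, by maximum likelihood, a participant-random-intercept model
    of the outcome across waves against the same model with an additional
    worksite random intercept (participants nested in worksites); df=1.
    A statistic below the 3.84 criterion is what licenses analyzing the
    trial with ordinary repeated-measures ANCOVA instead of a three-level
    model.
    """
    data = _with_total_pa(cohort)
    data = data[data["observed"]][
        ["participant_id", "cluster", "wave", outcome]
    ].dropna()
    if data["cluster"].nunique() < 2:
        raise ValueError("at least two worksites are required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = smf.mixedlm(f"{outcome} ~ C(wave)", data,
                         groups=data["participant_id"]).fit(reml=False)
        m1 = smf.mixedlm(
            f"{outcome} ~ C(wave)", data, groups=data["cluster"],
            re_formula="1",
            vc_formula={"participant": "0 + C(participant_id)"},
        ).fit(reml=False)
    lrt = max(0.0, 2.0 * (m1.llf - m0.llf))
    return TestResult(statistic=float(lrt), df=1,
                      p_value=float(stats.chi2.sf(lrt, 1)))


@dataclass(frozen=True)
class EffectRow:
    """One outcome x contrast row of the effect table."""

    sample: str
    outcome: str
    contrast: tuple[str, str]
    n: dict[str, int]
    means: dict[str, tuple[float, float]]  # arm -> (wave1, wave2), raw scale
    sds: dict[str, tuple[float, float]]
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    transformed: bool
    covariates: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA

    @property
    def borderline(self) -> bool:
        return ALPHA < self.p_value <= BORDERLINE


def _available_case(data: pd.DataFrame, outcome: str,
                    waves: tuple[str, str]) -> pd.DataFrame:
    obs = data[data["observed"] & data["wave"].isin(waves)]
    wide = obs.pivot(index="participant_id", columns="wave",
                     values=outcome).dropna()
    arms = data[data["wave"] == "T0"].set_index("participant_id")["arm"]
    wide = wide.join(arms).dropna()
    covs = data[data["wave"] == "T0"].set_index("participant_id")
    return wide, covs


def rm_ancova(cohort: pd.DataFrame, outcome: str,
              wave_pair: tuple[str, str] = ("T0", "T1"),
              covariates: Sequence[str] = (),
              transform: str = "auto") -> EffectRow:
    """2x2 repeated-measures ANCOVA for one outcome and wave pair.

    Available-case: participants with the outcome observed at both waves.
    The time x condition interaction is the condition effect on the
    within-person change, adjusted for the baseline values of the supplied
    covariates; the reported F has df (1, n - 2 - #covariates).  When
    ``transform="auto"`` the pooled outcome values are screened for
    non-normality and, if the screen fires, the test runs on log(x+1)
    values; descriptive means/SDs stay on the raw scale.
    """
    data = _with_total_pa(cohort)
    w1, w2 = wave_pair
    wide, baseline = _available_case(data, outcome, (w1, w2))
    ns = {arm: int((wide["arm"] == arm).sum()) for arm in ("IG", "CG")}
    if min(ns.values()) < 2:
        raise ValueError("each arm needs at least 2 analyzable participants")

    means = {arm: (float(wide.loc[wide["arm"] == arm, w1].mean()),
                   float(wide.loc[wide["arm"] == arm, w2].mean()))
             for arm in ("IG", "CG")}
    sds = {arm: (float(wide.loc[wide["arm"] == arm, w1].std(ddof=1)),
                 float(wide.loc[wide["arm"] == arm, w2].std(ddof=1)))
           for arm in ("IG", "CG")}

    pooled = np.concatenate([wide[w1].to_numpy(), wide[w2].to_numpy()])
    if transform == "auto":
        do_log = (np.all(pooled >= 0)
                  and log_transform_if_skewed(pooled).transformed)
    elif transform == "log":
        do_log = True
    elif transform == "none":
        do_log = False
    else:
        raise ValueError("transform must be 'auto', 'log' or 'none'")

    y1 = np.log1p(wide[w1]) if do_log else wide[w1]
    y2 = np.log1p(wide[w2]) if do_log else wide[w2]
    model_df = pd.DataFrame({
        "change": (y2 - y1).to_numpy(),
        "arm": (wide["arm"] == "IG").astype(float).to_numpy(),
    }, index=wide.index)
    used_covs = []
    for cov in covariates:
        if cov == outcome:
            continue  # the baseline of the outcome is already differenced out
        vals = baseline[cov].reindex(wide.index)
        if vals.isna().any() or vals.nunique() <= 1:
            warnings.warn(f"covariate {cov!r} dropped (missing or constant)")
            continue
        model_df[cov] = vals.to_numpy()
        used_covs.append(cov)

    X = sm.add_constant(model_df[["arm"] + used_covs])
    fit = sm.OLS(model_df["change"], X).fit()
    f_stat = float(fit.tvalues["arm"] ** 2)
    dfd = int(fit.df_resid)
    p = float(fit.pvalues["arm"])
    return EffectRow(
        sample="", outcome=outcome, contrast=wave_pair, n=ns,
        means=means, sds=sds, f_statistic=f_stat, df=(1, dfd), p_value=p,
        transformed=do_log, covariates=tuple(used_covs),
    )


def effect_table(cohort: pd.DataFrame, sample: str = "total",
                 contrast: str = "t0t1",
                 covariates: Sequence[str] = ("sitting",),
                 transform: str = "auto") -> pd.DataFrame:
    """All-outcome effect table for one sample and wave contrast.

    ``sample`` is "total" or "at_risk"; covariates default to baseline
    sitting time (the characteristic that differed between arms at
    baseline in the trial this pipeline mirrors).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}")
    data = cohort if sample == "total" else at_risk_filter(cohort)
    wave_pair = CONTRASTS[contrast]
    rows = []
    for outcome in OUTCOMES:
        row = rm_ancova(data, outcome, wave_pair, covariates=covariates,
                        transform=transform)
        rows.append({
            "sample": sample,
            "outcome": outcome,
            "contrast": f"{wave_pair[0]}->{wave_pair[1]}",
            "n_IG": row.n["IG"], "n_CG": row.n["CG"],
            "mean_IG_1": row.means["IG"][0], "sd_IG_1": row.sds["IG"][0],
            "mean_IG_2": row.means["IG"][1], "sd_IG_2": row.sds["IG"][1],
            "mean_CG_1": row.means["CG"][0], "sd_CG_1": row.sds["CG"][0],
            "mean_CG_2": row.means["CG"][1], "sd_CG_2": row.sds["CG"][1],
            "F": row.f_statistic, "df1": row.df[0], "df2": row.df[1],
            "p": row.p_value, "transformed": row.transformed,
            "significant": row.significant, "borderline": row.borderline,
        })
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class Attainment:
    percent: int
    numerator: int
    denominator: int


def guideline_attainment(cohort: pd.DataFrame, wave: str,
                         arm: str) -> Attainment:
    """Percent of observed participants at >= 10,000 steps/day at a wave."""
    sub = cohort[(cohort["wave"] == wave) & (cohort["arm"] == arm)
                 & cohort["observed"]]["steps"].dropna()
    if sub.empty:
        raise ValueError(f"no observed step data at {wave} in arm {arm}")
    num = int((sub >= STEP_GOAL).sum())
    den = int(len(sub))
    return Attainment(percent=_round_half_away(100.0 * num / den),
                      numerator=num, denominator=den)


def attainment_fraction(numerator: int, denominator: int) -> Attainment:
    """Attainment percentage straight from a printed fraction."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return Attainment(percent=_round_half_away(100.0 * numerator / denominator),
                      numerator=numerator, denominator=denominator)


def change_summary(row: EffectRow) -> dict[str, float]:
    """Per-arm mean change between the row's two waves, raw scale.

    Step changes are rounded to whole steps (half away from zero);
    minutes/day changes are kept to two decimals.
    """
    out = {}
    for arm, (m1, m2) in row.means.items():
        delta = m2 - m1
        out[arm] = (_round_half_away(delta) if row.outcome == "steps"
                    else round(delta, 2))
    return out


def dropout_analysis(cohort: pd.DataFrame) -> pd.DataFrame:
    """Completer-vs-dropout tests; completion = observed data at T2.

    Arm and worksite type are tested against completion by uncorrected
    chi-square (df 1 and k-1); continuous baselines by t tests.  With no
    dropout at all the tests are degenerate and are skipped with a warning.
    """
    data = _with_total_pa(cohort)
    t2 = data[data["wave"] == "T2"].set_index("participant_id")
    completed = t2["observed"]
    base = data[data["wave"] == "T0"].set_index("participant_id")
    base = base.assign(completed=completed)
    rows = []
    if completed.all() or (~completed).all():
        warnings.warn("no variation in completion; dropout tests skipped")
        return pd.DataFrame(rows)
    for col, name in (("arm", "arm"), ("cluster_type", "cluster_type")):
        tab = pd.crosstab(base[col], base["completed"])
        if tab.shape == (2, 2):
            res = chi_square_2x2(*tab.to_numpy().ravel())
        else:
            res = chi_square_table(tab.to_numpy())
        rows.append({"characteristic": name, "test": "chi2",
                     "statistic": res.statistic, "df": res.df,
                     "p": res.p_value})
    for col in ("steps", "sitting", "walking", "moderate", "vigorous",
                "total_pa"):
        x = base.loc[base["completed"], col].dropna()
        y = base.loc[~base["completed"], col].dropna()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"dropout t test for {col!r} skipped (too few)")
            continue
        t, p = stats.ttest_ind(x, y)
        rows.append({"characteristic": col, "test": "t",
                     "statistic": float(t), "df": len(x) + len(y) - 2,
                     "p": float(p)})
    return pd.DataFrame(rows)
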