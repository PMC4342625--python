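"""Statistical pipeline: subsetting, tests, ANCOVA, and summaries."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from steptailor.trial_analysis import (
    at_risk_filter,
    attainment_fraction,
    baseline_comparison,
    change_summary,
    chi_square_2x2,
    chi_square_table,
    cluster_variance_test,
    dropout_analysis,
    effect_table,
    guideline_attainment,
    rm_ancova,
)
from steptailor.trial_simulator import (
    SimConfig,
    _default_clusters,
    apply_dropout,
    default_config_from_paper,
    simulate_cohort,
)


def null_config(n_ig=65, n_cg=74):
    """Both arms share the IG at-risk parameters: no time x group effect."""
    cfg = default_config_from_paper("at_risk")
    ig = replace(cfg.arms["IG"], n=n_ig)
    return SimConfig(arms={"IG": ig, "CG": replace(ig, n=n_cg)},
                     clusters=_default_clusters(n_ig, n_cg))


def chi2_closed_form(a, b, c, d):
    """Independent oracle: sum over cells of (O - E)^2 / E."""
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    from scipy.stats import chi2

    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, 1))


def test_at_risk_threshold_is_strict(small_cohort):
    cohort = small_cohort.copy()
    t0 = cohort["wave"] == "T0"
    pids = cohort.loc[t0, "participant_id"].iloc[:2].tolist()
    cohort.loc[t0 & (cohort["participant_id"] == pids[0]), "steps"] = 9999.0
    cohort.loc[t0 & (cohort["participant_id"] == pids[1]), "steps"] = 10000.0
    sub = at_risk_filter(cohort)
    assert pids[0] in set(sub["participant_id"])
    assert pids[1] not in set(sub["participant_id"])


def test_at_risk_partitions_cohort(small_cohort):
    sub = at_risk_filter(small_cohort)
    all_pids = set(small_cohort["participant_id"])
    sub_pids = set(sub["participant_id"])
    base = small_cohort[small_cohort["wave"] == "T0"].set_index(
        "participant_id")["steps"]
    comp_pids = {p for p in all_pids if base[p] >= 10000}
    assert sub_pids | comp_pids == all_pids
    assert sub_pids & comp_pids == set()


def test_at_risk_fraction_under_total_defaults():
    cfg = default_config_from_paper("total")
    fracs = []
    for i in range(20):
        cohort = simulate_cohort(cfg, seed=300 + i)
        sub = at_risk_filter(cohort)
        fracs.append(sub["participant_id"].nunique()
                     / cohort["participant_id"].nunique())
    # normal baseline draws put ~60-70% below 10,000 steps/day
    assert 0.5 < np.mean(fracs) < 0.8


def test_chi_square_dropout_counts():
    res = chi_square_2x2(46, 91, 30, 107)
    assert res.statistic == pytest.approx(4.661, abs=5e-4)
    assert res.df == 1
    assert res.p_value == pytest.approx(0.03, abs=0.005)


def test_chi_square_independence_is_zero():
    assert chi_square_2x2(10, 10, 10, 10).statistic == pytest.approx(0.0)


def test_chi_square_matches_closed_form_oracle():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        a, b, c, d = rng.integers(1, 200, size=4)
        res = chi_square_2x2(a, b, c, d)
        stat, p = chi2_closed_form(a, b, c, d)
        assert abs(res.statistic - stat) < 1e-9
        assert abs(res.p_value - p) < 1e-9


def test_chi_square_rejects_degenerate_margins():
    with pytest.raises(ValueError):
        chi_square_2x2(0, 0, 5, 7)


def test_baseline_comparison_flags_sitting_shift():
    """Arms differing only in sitting time flag sitting as the covariate."""
    cfg = default_config_from_paper("total")  # sitting 526.7 vs 465.2
    hits = 0
    n_rep = 40
    for i in range(n_rep):
        cohort = simulate_cohort(cfg, seed=600 + i)
        _, covs = baseline_comparison(cohort, quantitative=("sitting",))
        hits += "sitting" in covs
    # analytical power for a 61.5 min/day shift at n=137+137 is ~0.8;
    # require a clear majority of replicates
    assert hits > n_rep * 0.6


def test_baseline_comparison_type_i_rate_with_identical_arms():
    cfg = null_config(100, 100)
    hits = 0
    n_rep = 60
    for i in range(n_rep):
        cohort = simulate_cohort(cfg, seed=700 + i)
        _, covs = baseline_comparison(cohort, quantitative=("steps",))
        hits += "steps" in covs
    assert hits <= 10  # ~alpha x 60 = 3 expected; 10 allows noise


def test_baseline_comparison_skips_constant_characteristic(small_cohort):
    cohort = small_cohort.copy()
    cohort["shoe_size"] = 42.0
    with pytest.warns(UserWarning, match="shoe_size"):
        rows, covs = baseline_comparison(cohort,
                                         quantitative=("shoe_size",))
    assert rows[0].result is None and covs == []


def test_cluster_variance_lrt_null_and_power():
    cfg = default_config_from_paper("total")
    null_stat = cluster_variance_test(simulate_cohort(cfg, seed=31),
                                      "steps")
    assert null_stat.statistic >= 0.0
    big = replace(cfg, cluster_sd=1500.0)
    alt_stat = cluster_variance_test(simulate_cohort(big, seed=31), "steps")
    assert alt_stat.statistic > null_stat.statistic
    assert alt_stat.statistic > 3.84  # detectable worksite variance


def test_cluster_variance_requires_multiple_clusters(small_cohort):
    one = small_cohort[small_cohort["cluster"] == "school_a"]
    with pytest.raises(ValueError):
        cluster_variance_test(one, "steps")


def test_rm_ancova_agrees_with_mixed_anova_oracle(small_cohort):
    """Change-score F equals the 2x2 mixed-ANOVA interaction F (no covs)."""
    pingouin = pytest.importorskip("pingouin")
    row = rm_ancova(small_cohort, "steps", ("T0", "T1"), covariates=(),
                    transform="none")
    long = small_cohort[small_cohort["wave"].isin(["T0", "T1"])]
    aov = pingouin.mixed_anova(long, dv="steps", within="wave",
                               subject="participant_id", between="arm")
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    assert row.f_statistic == pytest.approx(float(inter["F"]), rel=1e-6)
    assert row.p_value == pytest.approx(float(inter["p_unc"]), rel=1e-6)
    assert row.df == (1, int(inter["DF2"]))


def test_rm_ancova_df_accounts_for_covariates(small_cohort):
    row = rm_ancova(small_cohort, "steps", ("T0", "T1"),
                    covariates=("sitting",))
    n = row.n["IG"] + row.n["CG"]
    assert row.df == (1, n - 2 - 1)
    assert row.covariates == ("sitting",)


def test_rm_ancova_detects_paper_sized_effect():
    """At-risk defaults: the step-count interaction is found at T0->T1."""
    cfg = default_config_from_paper("at_risk")
    hits = 0
    for i in range(20):
        cohort = apply_dropout(simulate_cohort(cfg, seed=40 + i), cfg,
                               seed=140 + i)
        row = rm_ancova(cohort, "steps", ("T0", "T1"),
                        covariates=("sitting",))
        hits += row.p_value <= 0.05
    assert hits >= 12  # significant in the clear majority of replicates


def test_rm_ancova_ignores_pure_time_effect():
    """Both arms shifting by +1000 steps is not a time x group interaction."""
    cfg = null_config()
    shifted = {
        a: replace(p, step_means=(p.step_means[0], p.step_means[0] + 1000,
                                  p.step_means[0] + 1000))
        for a, p in cfg.arms.items()
    }
    hits = 0
    for i in range(40):
        cohort = simulate_cohort(replace(cfg, arms=shifted), seed=800 + i)
        row = rm_ancova(cohort, "steps", ("T0", "T1"), transform="none")
        hits += row.p_value <= 0.05
    assert hits <= 7  # ~alpha x 40 = 2 expected


def test_rm_ancova_needs_two_per_arm(small_cohort):
    tiny = small_cohort[small_cohort["participant_id"].isin(["P0000"])]
    with pytest.raises(ValueError):
        rm_ancova(tiny, "steps", ("T0", "T1"))


def test_effect_table_shape_and_determinism(small_cohort):
    t1 = effect_table(small_cohort, sample="at_risk", contrast="t0t1")
    t2 = effect_table(small_cohort, sample="at_risk", contrast="t0t1")
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1["outcome"]) == ["steps", "sitting", "walking", "moderate",
                                   "vigorous", "total_pa"]
    assert (t1["df1"] == 1).all()
    assert ((t1["p"] > 0) & (t1["p"] <= 1)).all()
    assert (t1[["n_IG", "n_CG"]].to_numpy() <= 139).all()


@pytest.mark.parametrize("num, den, expected",
                         [(36, 55, 65), (16, 53, 30), (35, 97, 36),
                          (29, 83, 35), (0, 50, 0)])
def test_attainment_from_printed_fractions(num, den, expected):
    res = attainment_fraction(num, den)
    assert res.percent == expected
    assert 0 <= res.numerator <= res.denominator


def test_guideline_attainment_counts_observed_only(small_cohort):
    cfg = default_config_from_paper("at_risk")
    dropped = apply_dropout(small_cohort, cfg, seed=3)
    res = guideline_attainment(dropped, "T1", "IG")
    obs = dropped[(dropped["wave"] == "T1") & (dropped["arm"] == "IG")
                  & dropped["observed"]]
    assert res.denominator == len(obs)
    assert res.numerator == int((obs["steps"] >= 10000).sum())
    assert 0 <= res.percent <= 100


def test_change_summary_reproduces_reported_deltas(small_cohort):
    row = rm_ancova(small_cohort, "steps", ("T0", "T1"), transform="none")
    # exact arithmetic on the published at-risk means
    published = replace(row, means={"IG": (6697.34, 7753.18),
                                    "CG": (6898.16, 6640.43)})
    deltas = change_summary(published)
    assert deltas == {"IG": 1056, "CG": -258}


def test_dropout_analysis_recovers_arm_difference():
    cfg = default_config_from_paper("total")
    cohort = apply_dropout(simulate_cohort(cfg, seed=55), cfg, seed=56)
    table = dropout_analysis(cohort)
    arm_row = table[table["characteristic"] == "arm"].iloc[0]
    assert arm_row["test"] == "chi2" and arm_row["df"] == 1
    assert set(table["characteristic"]) >= {"arm", "cluster_type", "steps"}


def test_dropout_analysis_degenerate_without_dropout(small_cohort):
    with pytest.warns(UserWarning, match="no variation"):
        table = dropout_analysis(small_cohort)
    assert table.empty


def test_chi_square_table_extends_to_2x3():
    res = chi_square_table(np.array([[20, 30, 10], [25, 15, 30]]))
    assert res.df == 2
    assert res.statistic > 0
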