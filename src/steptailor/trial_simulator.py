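"""Synthetic cluster-RCT cohorts.

Generates cohorts with the statistical structure of an 8-worksite, 2-arm
(intervention IG vs waiting-list control CG), 3-wave (T0 baseline, T1 one
month, T2 three months) workplace physical-activity trial:

* pedometer steps/day drawn per participant from a multivariate normal
  across waves (test-retest correlation ``rho``), plus an optional
  worksite-level random intercept, truncated at 20,000 steps/day;
* self-reported walking/moderate/vigorous minutes drawn lognormal (heavy
  right tail, as self-report data show) with a configurable over-reporting
  factor; sitting minutes drawn normal per arm;
* monotone dropout (no re-entry) with per-arm marginal retention at T1 and
  T2, optionally inflated in commercial worksites.

Default parameters are the trial's published arm x wave means/SDs/ns and
retention fractions, for either the full randomized sample or the at-risk
subsample (participants below 10,000 steps/day at baseline).

Randomness is streamed per participant from the master seed, so enlarging
a cohort never perturbs the draws of earlier participants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd

WAVES = ("T0", "T1", "T2")
ARMS = ("IG", "CG")
CLUSTER_TYPES = ("school", "commercial", "nonprofit")
DEFAULT_TRUNCATION_CAP = 20_000.0
DEFAULT_RHO = 0.6

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    kind: str  # school / commercial / nonprofit
    arm: str  # IG / CG
    size: int

    def __post_init__(self) -> None:
        if self.kind not in CLUSTER_TYPES:
            raise ValueError(f"unknown cluster type {self.kind!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.size < 0:
            raise ValueError("cluster size must be nonnegative")


@dataclass(frozen=True)
class ArmParams:
    """Outcome-generating parameters for one arm across the three waves."""

    n: int
    step_means: Triple
    step_sds: Triple
    sitting_mean: float
    sitting_sd: float
    walking_means: Triple
    walking_sds: Triple
    moderate_means: Triple
    moderate_sds: Triple
    vigorous_means: Triple
    vigorous_sds: Triple
    retention: tuple[float, float]  # marginal P(observed) at T1, T2

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("arm size must be positive")
        for s in self.step_sds:
            if s <= 0:
                raise ValueError("step SDs must be positive")
        r1, r2 = self.retention
        if not (0 <= r2 <= r1 <= 1):
            raise ValueError(
                "retention must satisfy 0 <= T2 <= T1 <= 1 (monotone dropout)"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration for one synthetic trial."""

    arms: dict[str, ArmParams]
    clusters: tuple[ClusterSpec, ...]
    rho: float = DEFAULT_RHO
    cluster_sd: float = 0.0
    selfreport_bias: float = 1.0
    commercial_dropout_multiplier: float = 1.0
    truncation_cap: float = DEFAULT_TRUNCATION_CAP

    def __post_init__(self) -> None:
        if set(self.arms) != set(ARMS):
            raise ValueError(f"arms must be exactly {ARMS}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be nonnegative")
        for arm in ARMS:
            sizes = sum(c.size for c in self.clusters if c.arm == arm)
            if sizes != self.arms[arm].n:
                raise ValueError(
                    f"cluster sizes for {arm} sum to {sizes}, "
                    f"expected n={self.arms[arm].n}"
                )
            for kind in CLUSTER_TYPES:
                if not any(c.arm == arm and c.kind == kind
                           for c in self.clusters):
                    raise ValueError(
                        f"arm {arm} needs at least one {kind} worksite"
                    )
            for s in self.arms[arm].step_sds:
                if s ** 2 <= self.cluster_sd ** 2:
                    raise ValueError(
                        "wave step SD must exceed the between-cluster SD"
                    )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        arms = {
            a: ArmParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in p.items()
            })
            for a, p in d["arms"].items()
        }
        clusters = tuple(ClusterSpec(**c) for c in d["clusters"])
        extra = {k: v for k, v in d.items() if k not in ("arms", "clusters")}
        return cls(arms=arms, clusters=clusters, **extra)


def _split_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _default_clusters(n_ig: int, n_cg: int) -> tuple[ClusterSpec, ...]:
    # 8 worksites: 3 schools, 3 commercial, 2 nonprofit; each arm holds at
    # least one worksite of every type.
    ig_kinds = [("school_a", "school"), ("school_b", "school"),
                ("commercial_a", "commercial"), ("nonprofit_a", "nonprofit")]
    cg_kinds = [("school_c", "school"), ("commercial_b", "commercial"),
                ("commercial_c", "commercial"), ("nonprofit_b", "nonprofit")]
    specs = []
    for (labels, arm, n) in ((ig_kinds, "IG", n_ig), (cg_kinds, "CG", n_cg)):
        for (label, kind), size in zip(labels, _split_sizes(n, len(labels))):
            specs.append(ClusterSpec(label=label, kind=kind, arm=arm,
                                     size=size))
    return tuple(specs)


# Published arm x wave moments.  T0/T1 come from the baseline-to-one-month
# table, T2 from the baseline-to-three-month table (available-case ns
# differ between tables; the T0 entries of the former are used).
_AT_RISK = {
    "IG": ArmParams(
        n=65,
        step_means=(6697.34, 7753.18, 8019.24),
        step_sds=(1864.33, 3196.10, 3997.34),
        sitting_mean=534.07, sitting_sd=163.11,
        walking_means=(12.49, 39.48, 31.45),
        walking_sds=(24.17, 113.45, 56.88),
        moderate_means=(16.94, 21.62, 30.38),
        moderate_sds=(24.05, 34.70, 36.23),
        vigorous_means=(6.88, 6.67, 10.98),
        vigorous_sds=(13.57, 12.70, 20.89),
        retention=(101 / 137, 91 / 137),
    ),
    "CG": ArmParams(
        n=74,
        step_means=(6898.16, 6640.43, 7308.22),
        step_sds=(1979.35, 2751.43, 3803.62),
        sitting_mean=497.46, sitting_sd=193.33,
        walking_means=(12.56, 19.55, 37.87),
        walking_sds=(16.60, 22.35, 50.84),
        moderate_means=(19.45, 9.56, 33.95),
        moderate_sds=(37.70, 11.27, 55.84),
        vigorous_means=(5.87, 3.68, 6.03),
        vigorous_sds=(18.68, 8.13, 14.02),
        retention=(112 / 137, 107 / 137),
    ),
}

_TOTAL = {
    "IG": ArmParams(
        n=137,
        step_means=(8759.98, 9235.48, 9483.86),
        step_sds=(3771.32, 4281.05, 4875.34),
        sitting_mean=526.7, sitting_sd=163.7,
        walking_means=(14.49, 37.05, 35.16),
        walking_sds=(22.86, 92.52, 52.49),
        moderate_means=(23.30, 25.59, 32.37),
        moderate_sds=(28.11, 36.85, 37.68),
        vigorous_means=(10.64, 9.13, 13.73),
        vigorous_sds=(17.80, 15.20, 21.58),
        retention=(101 / 137, 91 / 137),
    ),
    "CG": ArmParams(
        n=137,
        step_means=(8627.69, 8101.77, 8589.15),
        step_sds=(3786.73, 3882.31, 4379.61),
        sitting_mean=465.2, sitting_sd=186.1,
        walking_means=(26.17, 42.37, 47.37),
        walking_sds=(51.93, 86.66, 72.60),
        moderate_means=(24.94, 15.43, 38.44),
        moderate_sds=(36.21, 20.08, 60.04),
        vigorous_means=(9.76, 6.78, 10.69),
        vigorous_sds=(23.10, 13.48, 18.44),
        retention=(112 / 137, 107 / 137),
    ),
}


def default_config_from_paper(
    sample: Literal["total", "at_risk"] = "total",
) -> SimConfig:
    """Config preloaded with the trial's published moments and retention.

    ``sample="total"`` uses the full randomized arms (n=137 each);
    ``sample="at_risk"`` uses the below-10,000-steps subsample moments
    (n=65 IG / 74 CG).
    """
    if sample == "total":
        arms = dict(_TOTAL)
    elif sample == "at_risk":
        arms = dict(_AT_RISK)
    else:
        raise ValueError("sample must be 'total' or 'at_risk'")
    clusters = _default_clusters(arms["IG"].n, arms["CG"].n)
    return SimConfig(arms=arms, clusters=clusters)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _step_cholesky(params: ArmParams, rho: float,
                   cluster_sd: float) -> np.ndarray:
    sds = np.sqrt(np.asarray(params.step_sds) ** 2 - cluster_sd ** 2)
    cov = rho * np.outer(sds, sds)
    np.fill_diagonal(cov, sds ** 2)
    return np.linalg.cholesky(cov)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(index,)))


def simulate_cohort(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw one fully observed cohort in long (participant x wave) format.

    Columns: participant_id, cluster, cluster_type, arm, wave, steps,
    sitting, walking, moderate, vigorous, observed (all True here; dropout
    is applied separately by :func:`apply_dropout`).
    """
    chol = {arm: _step_cholesky(config.arms[arm], config.rho,
                                config.cluster_sd)
            for arm in ARMS}
    cluster_effects = {}
    for ci, cluster in enumerate(config.clusters):
        rng = _participant_rng(seed, 1_000_000 + ci)
        cluster_effects[cluster.label] = (
            rng.normal(0.0, config.cluster_sd) if config.cluster_sd > 0
            else 0.0
        )

    rows = []
    index = 0
    for cluster in config.clusters:
        params = config.arms[cluster.arm]
        mu = np.asarray(params.step_means)
        for _ in range(cluster.size):
            rng = _participant_rng(seed, index)
            pid = f"P{index:04d}"
            steps = mu + cluster_effects[cluster.label] \
                + chol[cluster.arm] @ rng.standard_normal(3)
            # only the cap is applied: a zero floor would bias the wave
            # means/SDs the generator is calibrated to reproduce
            steps = np.minimum(steps, config.truncation_cap)
            sitting = rng.normal(params.sitting_mean, params.sitting_sd,
                                 size=3)
            selfreport = {}
            for outcome in ("walking", "moderate", "vigorous"):
                means = np.asarray(getattr(params, f"{outcome}_means"))
                sds = np.asarray(getattr(params, f"{outcome}_sds"))
                vals = np.zeros(3)
                for w in range(3):
                    m = means[w] * config.selfreport_bias
                    if m > 0:
                        lmu, lsig = _lognormal_params(m, sds[w])
                        vals[w] = rng.lognormal(lmu, lsig)
                selfreport[outcome] = vals
            for w, wave in enumerate(WAVES):
                rows.append({
                    "participant_id": pid,
                    "cluster": cluster.label,
                    "cluster_type": cluster.kind,
                    "arm": cluster.arm,
                    "wave": wave,
                    "steps": steps[w],
                    "sitting": sitting[w],
                    "walking": selfreport["walking"][w],
                    "moderate": selfreport["moderate"][w],
                    "vigorous": selfreport["vigorous"][w],
                    "observed": True,
                })
            index += 1
    return pd.DataFrame(rows)


def apply_dropout(cohort: pd.DataFrame, config: SimConfig,
                  seed: int) -> pd.DataFrame:
    """Mark monotone dropout: a participant missing T1 also misses T2.

    Retention is missing-completely-at-random within arm; commercial
    worksites have their per-wave dropout hazard multiplied by the
    configured factor (capped at certain dropout).
    """
    out = cohort.copy()
    pids = cohort["participant_id"].unique()
    info = (cohort[cohort["wave"] == "T0"]
            .set_index("participant_id")[["arm", "cluster_type"]])
    for i, pid in enumerate(sorted(pids)):
        arm = info.loc[pid, "arm"]
        kind = info.loc[pid, "cluster_type"]
        r1, r2 = config.arms[arm].retention
        d1 = 1.0 - r1
        d2 = 1.0 - (r2 / r1 if r1 > 0 else 0.0)
        if kind == "commercial":
            d1 = min(1.0, d1 * config.commercial_dropout_multiplier)
            d2 = min(1.0, d2 * config.commercial_dropout_multiplier)
        rng = _participant_rng(seed, 2_000_000 + i)
        u1, u2 = rng.random(2)
        seen_t1 = u1 >= d1
        seen_t2 = seen_t1 and u2 >= d2
        mask = out["participant_id"] == pid
        out.loc[mask & (out["wave"] == "T1"), "observed"] = seen_t1
        out.loc[mask & (out["wave"] == "T2"), "observed"] = seen_t2
    return out


def mean_change(cohort: pd.DataFrame, outcome: str, arm: str,
                wave_from: str = "T0", wave_to: str = "T1") -> float:
    """Available-case mean change in ``outcome`` between two waves, one arm.

    Uses participants observed at both waves (the trial's available-case
    convention) and differences their wave means.
    """
    sub = cohort[(cohort["arm"] == arm) & cohort["observed"]]
    wide = (sub[sub["wave"].isin([wave_from, wave_to])]
            .pivot(index="participant_id", columns="wave", values=outcome)
            .dropna())
    if wide.empty:
        raise ValueError(f"no participants observed at both {wave_from} "
                         f"and {wave_to} in arm {arm}")
    return float(wide[wave_to].mean() - wide[wave_from].mean())
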