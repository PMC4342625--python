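"""IPAQ short-form scoring.

Scores the last-week frequency/duration answers for walking, moderate and
vigorous activity plus sitting into minutes/day, after the standard
cleaning steps of the public IPAQ scoring protocol:

* per-domain episodes shorter than 10 min/day are set to 0;
* per-domain daily minutes are truncated at 180 (3 h);
* respondents reporting more than 960 min/day of total activity are
  flagged for exclusion (16 h; the rest assumed sleeping).

Outcomes that are positively skewed are log(x+1)-transformed before
inferential analysis; the decision is made by a normality screen
(Kolmogorov-Smirnov with estimated moments, i.e. Lilliefors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

MIN_EPISODE_MINUTES = 10.0
MAX_DOMAIN_MINUTES = 180.0
MAX_TOTAL_MINUTES = 960.0
DOMAINS = ("walking", "moderate", "vigorous")
#: normality-screen significance level triggering the log transform
TRANSFORM_ALPHA = 0.05
MIN_N_FOR_SCREEN = 8


@dataclass(frozen=True)
class IpaqResponse:
    """One participant's IPAQ short-form answers for one wave.

    ``days_*`` are days/week (0-7) on which the activity was performed;
    ``minutes_*`` are min/day on those active days.  ``sitting_minutes`` is
    min/day on a usual weekday.
    """

    days_walking: float
    minutes_walking: float
    days_moderate: float
    minutes_moderate: float
    days_vigorous: float
    minutes_vigorous: float
    sitting_minutes: float

    def __post_init__(self) -> None:
        for d in DOMAINS:
            days = getattr(self, f"days_{d}")
            minutes = getattr(self, f"minutes_{d}")
            if not 0 <= days <= 7:
                raise ValueError(f"days_{d} must lie in [0, 7]")
            if minutes < 0:
                raise ValueError(f"minutes_{d} must be nonnegative")
        if self.sitting_minutes < 0:
            raise ValueError("sitting_minutes must be nonnegative")


@dataclass(frozen=True)
class CleanedIpaq:
    """Cleaning result: the cleaned response plus the exclusion flag."""

    response: IpaqResponse
    excluded: bool
    notes: tuple[str, ...] = ()


def clean_ipaq(response: IpaqResponse) -> CleanedIpaq:
    """Apply the IPAQ cleaning rules; exclusion is a flag, never an error.

    The >960 min/day total-activity screen is evaluated on the reported
    (pre-truncation) daily minutes, then the 10-min floor and 180-min cap
    are applied per domain.  Idempotent on the response part.
    """
    notes: list[str] = []
    reported_total = sum(getattr(response, f"minutes_{d}") for d in DOMAINS)
    excluded = reported_total > MAX_TOTAL_MINUTES
    if excluded:
        notes.append(f"total reported activity {reported_total:.0f} min/day "
                     f"exceeds {MAX_TOTAL_MINUTES:.0f}")
    fields = {}
    for d in DOMAINS:
        minutes = getattr(response, f"minutes_{d}")
        if 0 < minutes < MIN_EPISODE_MINUTES:
            minutes = 0.0
            notes.append(f"{d}: episode under {MIN_EPISODE_MINUTES:.0f} min "
                         "set to 0")
        elif minutes > MAX_DOMAIN_MINUTES:
            minutes = MAX_DOMAIN_MINUTES
            notes.append(f"{d}: truncated at {MAX_DOMAIN_MINUTES:.0f} min/day")
        fields[f"minutes_{d}"] = minutes
    cleaned = replace(response, **fields)
    return CleanedIpaq(response=cleaned, excluded=excluded, notes=tuple(notes))


def minutes_per_day(days: float, minutes: float) -> float:
    """Convert (days/week, min/day-on-active-days) to average min/day."""
    if not 0 <= days <= 7:
        raise ValueError("days must lie in [0, 7]")
    if minutes < 0:
        raise ValueError("minutes must be nonnegative")
    return days * minutes / 7.0


def domain_minutes_per_day(response: IpaqResponse) -> dict[str, float]:
    """Average min/day per activity domain."""
    return {
        d: minutes_per_day(getattr(response, f"days_{d}"),
                           getattr(response, f"minutes_{d}"))
        for d in DOMAINS
    }


def total_pa(response: IpaqResponse) -> float:
    """Total activity in min/day: walking + moderate + vigorous."""
    return sum(domain_minutes_per_day(response).values())


def score_ipaq(response: IpaqResponse) -> dict[str, float]:
    """Clean and score one response into the per-outcome min/day table."""
    cleaned = clean_ipaq(response)
    out = domain_minutes_per_day(cleaned.response)
    out["total_pa"] = sum(out.values())
    out["sitting"] = cleaned.response.sitting_minutes
    out["excluded"] = float(cleaned.excluded)
    return out


@dataclass(frozen=True)
class TransformDecision:
    """Outcome of the skewness-triggered log transform."""

    values: np.ndarray
    decision: str  # "transformed" / "untransformed"
    statistic: float
    p_value: float

    @property
    def transformed(self) -> bool:
        return self.decision == "transformed"


def log_transform_if_skewed(values: Sequence[float],
                            alpha: float = TRANSFORM_ALPHA) -> TransformDecision:
    """Return log(x+1)-transformed values when normality is rejected.

    A significant Kolmogorov-Smirnov screen (Lilliefors variant, estimated
    mean/SD) at ``alpha`` triggers the transform; log(x+1) admits the zero
    counts common in self-reported activity.  Constant input cannot reject
    normality and is returned untransformed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < MIN_N_FOR_SCREEN:
        raise ValueError(
            f"need a 1-d sample of at least {MIN_N_FOR_SCREEN} values"
        )
    if np.any(arr < 0):
        raise ValueError("activity values must be nonnegative")
    if np.ptp(arr) == 0:  # zero-variance guard
        return TransformDecision(values=arr, decision="untransformed",
                                 statistic=0.0, p_value=1.0)
    stat, p = lilliefors(arr, dist="norm")
    if p <= alpha:
        return TransformDecision(values=np.log1p(arr), decision="transformed",
                                 statistic=float(stat), p_value=float(p))
    return TransformDecision(values=arr, decision="untransformed",
                             statistic=float(stat), p_value=float(p))
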