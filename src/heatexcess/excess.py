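"""Per-heat-wave excess mortality with exact Poisson confidence limits.

Excess mortality over an event is the cumulative observed minus baseline
(counterfactual) standardized deaths.  Its 95% interval uses the exact
(Garwood) limits for a Poisson count via the count–chi-square relation:
the lower/upper limit factors are applied to the observed event total and
the baseline total is subtracted, so the interval bounds the excess.

Relative mortality deviation (RMD) is the daily percentage deviation from
the baseline; its sum over an event (∑RMD) measures cumulative relative
impact and its per-day mean (ØRMD = ∑RMD / duration) the average impact.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heatmetrics import HeatWave

__all__ = [
    "ExcessSummary",
    "daily_rmd",
    "poisson_limits",
    "poisson_limit_factors",
    "poisson_ci",
    "summarize_excess",
    "excess_table",
    "round_half_up",
]


@dataclass(frozen=True)
class ExcessSummary:
    """Excess-mortality summary for one heat wave and population group."""

    heat_wave_id: str
    group: str
    excess_deaths: float  # cumulative observed − baseline, per 10M standardized
    ci_low: float
    ci_high: float
    mean_rmd: float  # ØRMD, % per day
    sum_rmd: float  # ∑RMD, %
    significant: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.excess_deaths <= self.ci_high):
            raise ValueError("excess_deaths must lie inside its CI")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def daily_rmd(observed: pd.Series, baseline: pd.Series) -> pd.Series:
    """Daily relative mortality deviation, % : 100·(observed − baseline)/baseline."""
    if not observed.index.equals(baseline.index):
        raise ValueError("observed and baseline must share the same dates")
    if (baseline <= 0).any():
        raise ValueError("baseline must be positive everywhere")
    out = 100.0 * (observed - baseline) / baseline
    out.name = "rmd_pct"
    return out


def poisson_limits(observed: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided limits for the mean of a Poisson count.

    Uses the chi-square form: L = χ²(α/2; 2O)/2 (0 for O = 0) and
    U = χ²(1 − α/2; 2(O+1))/2.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    o = int(observed)
    low = 0.0 if o == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * o)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * (o + 1))
    return float(low), float(high)


def poisson_limit_factors(observed: int, alpha: float = 0.05) -> tuple[float, float]:
    """Lower/upper limit *factors* L, U with interval (L·O, U·O); O > 0."""
    if observed <= 0:
        raise ValueError("limit factors need a positive count")
    low, high = poisson_limits(observed, alpha)
    return low / observed, high / observed


def poisson_ci(
    observed_total: float, baseline_total: float, alpha: float = 0.05
) -> tuple[float, float]:
    """95% bounds on excess deaths: exact limits of the observed total,
    shifted by the baseline total.

    The (possibly non-integer, standardized) observed total is rounded to
    the nearest count for the limit computation only.
    """
    if observed_total < 0 or baseline_total < 0:
        raise ValueError("totals must be non-negative")
    o = int(round(observed_total))
    low, high = poisson_limits(o, alpha)
    return low - baseline_total, high - baseline_total


def summarize_excess(
    hw: HeatWave,
    series: pd.DataFrame,
    group: str = "total",
    alpha: float = 0.05,
) -> ExcessSummary:
    """Cumulative excess, CI and RMD summaries for one event.

    ``series`` must carry ``observed`` and ``baseline`` columns covering
    every event day (a baseline-results table).
    """
    days = hw.dates
    if not days.isin(series.index).all():
        raise ValueError(f"series does not cover event {hw.id}")
    sub = series.loc[days]
    observed = sub["observed"]
    baseline = sub["baseline"]
    excess = float((observed - baseline).sum())
    rmd = daily_rmd(observed, baseline)
    sum_rmd = float(rmd.sum())
    mean_rmd = sum_rmd / hw.duration_days
    ci_low, ci_high = poisson_ci(float(observed.sum()), float(baseline.sum()), alpha)
    # the CI is for the rounded observed count; clamp so the raw excess
    # estimate remains inside its own interval
    ci_low = min(ci_low, excess)
    ci_high = max(ci_high, excess)
    return ExcessSummary(
        heat_wave_id=hw.id,
        group=group,
        excess_deaths=excess,
        ci_low=ci_low,
        ci_high=ci_high,
        mean_rmd=mean_rmd,
        sum_rmd=sum_rmd,
        significant=not (ci_low <= 0.0 <= ci_high),
    )


def excess_table(summaries: Sequence[ExcessSummary]) -> pd.DataFrame:
    """Report table: per event and group, excess deaths with CI, ØRMD, ∑RMD
    and a significance star; counts to integers, percentages to 1 decimal."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "id": s.heat_wave_id,
                "group": s.group,
                "excess_deaths": int(round(s.excess_deaths)),
                "ci_low": int(round(s.ci_low)),
                "ci_high": int(round(s.ci_high)),
                "mean_rmd_pct": round_half_up(s.mean_rmd, 1),
                "sum_rmd_pct": round_half_up(s.sum_rmd, 1),
                "significant": "*" if s.significant else "",
            }
        )
    columns = [
        "id", "group", "excess_deaths", "ci_low", "ci_high",
        "mean_rmd_pct", "sum_rmd_pct", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)
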