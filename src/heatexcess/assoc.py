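"""Associations between heat-wave characteristics and excess mortality.

Each detected heat wave contributes one point: its cumulative relative
mortality deviation (∑RMD, %) against a meteorological characteristic —
cumulative excess heat factor (∑EHF), cumulative significance or
acclimatization index, average or maximum daily mean temperature, or
duration.  Ordinary least squares per predictor and population group gives
the slope, R² and a pointwise 95% confidence band of the fitted line; the
comparison of R² across predictors shows which characteristic best explains
the magnitude of excess mortality.  Group-level mean impacts are compared
with a Welch two-sample t-test on per-event mean RMDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .excess import ExcessSummary
from .heatmetrics import HeatWave

__all__ = [
    "PREDICTORS",
    "RegressionResult",
    "GroupComparison",
    "predictor_values",
    "fit_association",
    "association_table",
    "compare_groups",
    "plot_association",
]

#: predictor name -> HeatWave attribute
PREDICTORS = {
    "sum_ehf": "sum_ehf",
    "sum_ehi_sig": "sum_ehi_sig",
    "sum_ehi_accl": "sum_ehi_accl",
    "avg_tmean": "avg_tmean",
    "max_tmean": "max_tmean",
    "duration": "duration_days",
}


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, slope
    ci_band: pd.DataFrame  # columns x, fit, lo, hi (pointwise 95%)
    n_events: int
    n_excluded: int  # events dropped for undefined predictor values


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    degenerate: bool  # flagged when both samples have (near-)zero variance


def predictor_values(events: Sequence[HeatWave], predictor: str) -> np.ndarray:
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}; choose from {sorted(PREDICTORS)}")
    attr = PREDICTORS[predictor]
    vals = [getattr(hw, attr) for hw in events]
    return np.array([np.nan if v is None else float(v) for v in vals])


def fit_association(
    events: Sequence[tuple[HeatWave, ExcessSummary]],
    predictor: str,
    group: str = "total",
) -> RegressionResult:
    """OLS of per-event ∑RMD on one heat-wave characteristic.

    Events with an undefined predictor (e.g. warm-up overlap leaves ∑EHF
    unset) are excluded listwise and counted.  Requires ≥ 3 usable events
    and a non-constant predictor.
    """
    hws = [hw for hw, _ in events]
    y_all = np.array([float(s.sum_rmd) for _, s in events])
    x_all = predictor_values(hws, predictor)
    keep = np.isfinite(x_all) & np.isfinite(y_all)
    x, y = x_all[keep], y_all[keep]
    n_excluded = int((~keep).sum())
    if len(x) < 3:
        raise ValueError(f"need at least 3 events with defined {predictor}")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor} is constant across events")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = res.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    band = pd.DataFrame(
        {
            "x": grid,
            "fit": res.params[0] + res.params[1] * grid,
            "lo": pred[:, 0],
            "hi": pred[:, 1],
        }
    )
    return RegressionResult(
        predictor=predictor,
        group=group,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        ci_band=band,
        n_events=int(len(x)),
        n_excluded=n_excluded,
    )


def association_table(
    events_by_group: dict[str, Sequence[tuple[HeatWave, ExcessSummary]]],
    predictors: Sequence[str] = tuple(PREDICTORS),
) -> pd.DataFrame:
    """Predictor × group table of slopes, R² and p-values."""
    rows = []
    for predictor in predictors:
        for group, events in events_by_group.items():
            r = fit_association(events, predictor, group)
            rows.append(
                {
                    "predictor": predictor,
                    "group": group,
                    "slope": r.slope,
                    "r_squared": r.r_squared,
                    "p_value": r.p_value,
                    "n_events": r.n_events,
                }
            )
    return pd.DataFrame(rows, columns=["predictor", "group", "slope", "r_squared", "p_value", "n_events"])


def compare_groups(
    per_event_rmd_a: Sequence[float],
    per_event_rmd_b: Sequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Welch two-sample t-test on per-event mean RMDs of two groups."""
    a = np.asarray(per_event_rmd_a, dtype=float)
    b = np.asarray(per_event_rmd_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 events per group")
    degenerate = bool(np.ptp(a) == 0 and np.ptp(b) == 0)
    if degenerate:
        stat, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        degenerate=degenerate,
    )


def plot_association(
    events: Sequence[tuple[HeatWave, ExcessSummary]],
    predictor: str,
    group: str = "total",
    ax=None,
):
    """Scatter of per-event ∑RMD vs one characteristic with the fitted line
    and its 95% band."""
    import matplotlib.pyplot as plt

    result = fit_association(events, predictor, group)
    hws = [hw for hw, _ in events]
    x = predictor_values(hws, predictor)
    y = np.array([s.sum_rmd for _, s in events])
    keep = np.isfinite(x)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x[keep], y[keep], s=20, color="k")
    ax.plot(result.ci_band["x"], result.ci_band["fit"], color="C3")
    ax.plot(result.ci_band["x"], result.ci_band["lo"], "-.", color="C3", lw=0.8)
    ax.plot(result.ci_band["x"], result.ci_band["hi"], "-.", color="C3", lw=0.8)
    ax.set_xlabel(predictor)
    ax.set_ylabel("cumulative RMD (%)")
    ax.set_title(f"{group}: R² = {result.r_squared:.2f}")
    return ax
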