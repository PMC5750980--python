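"""Heat-wave detection and daily excess-heat indices.

A heat wave is a run of at least three consecutive days whose daily mean
temperature reaches or exceeds the 95th percentile of the all-days
("annual") temperature distribution, with at least one day strictly
exceeding the 98th percentile.  Daily heat load is measured by the excess
heat factor (EHF), built from two indices computed over backward-looking
windows:

* ``EHIsig`` (significance index): mean of days *i*, *i-1*, *i-2* minus the
  95th-percentile threshold — how hot the last three days were in absolute
  terms.
* ``EHIaccl`` (acclimatization index): the same three-day mean minus the
  mean of the 30 days preceding the window (days *i-3* … *i-32*) — how hot
  they were relative to what the population recently experienced.
* ``EHF = max(0, EHIsig) × max(1, EHIaccl)``.

All windows look backward because mortality on day *i* can respond to heat
on that day or earlier, never to upcoming days.  The first 2 days of a
series have undefined ``EHIsig``; the first 32 days have undefined
``EHIaccl`` and ``EHF`` (the warm-up period).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "HeatWave",
    "validate_temperature",
    "compute_thresholds",
    "detect_heat_waves",
    "ehi_sig",
    "ehi_accl",
    "ehf",
    "compute_daily_metrics",
    "summarize_heat_wave",
    "heat_wave_table",
]


@dataclass(frozen=True)
class Thresholds:
    """Percentile temperature thresholds defining heat waves.

    ``t95`` is the qualifying threshold (every heat-wave day must reach it),
    ``t98`` the intensity threshold (at least one day must exceed it).
    """

    t95: float
    t98: float
    reference_period: tuple[dt.date, dt.date]

    def __post_init__(self) -> None:
        if not (self.t95 <= self.t98):
            raise ValueError(f"t95 ({self.t95}) must not exceed t98 ({self.t98})")


@dataclass(frozen=True)
class HeatWave:
    """One detected heat-wave event with its heat-load summaries.

    ``id`` is ``"<year>_<ordinal>"`` where the year is the calendar year of
    the start date and the ordinal counts events within that year by start
    date.  The cumulative index sums (``sum_ehi_sig`` etc.) are ``None``
    until :func:`summarize_heat_wave` fills them.
    """

    id: str
    start: dt.date
    end: dt.date
    duration_days: int
    avg_tmean: float
    max_tmean: float
    sum_ehi_sig: Optional[float] = None
    sum_ehi_accl: Optional[float] = None
    sum_ehf: Optional[float] = None

    def __post_init__(self) -> None:
        expected = (self.end - self.start).days + 1
        if self.duration_days != expected:
            raise ValueError(
                f"duration_days={self.duration_days} inconsistent with "
                f"{self.start}..{self.end} ({expected} days)"
            )
        if self.duration_days < 3:
            raise ValueError("a heat wave lasts at least 3 days")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


def validate_temperature(temp: pd.Series) -> pd.Series:
    """Check that ``temp`` is a finite, gap-free daily series.

    Returns the series with a normalized (midnight) DatetimeIndex.
    """
    if not isinstance(temp, pd.Series) or len(temp) == 0:
        raise ValueError("temperature must be a non-empty pandas Series")
    if not isinstance(temp.index, pd.DatetimeIndex):
        raise ValueError("temperature must be indexed by dates")
    temp = temp.copy()
    temp.index = temp.index.normalize()
    if not temp.index.is_monotonic_increasing or temp.index.has_duplicates:
        raise ValueError("temperature dates must be strictly increasing")
    full = pd.date_range(temp.index[0], temp.index[-1], freq="D")
    if len(full) != len(temp):
        raise ValueError("temperature series has calendar gaps")
    if not np.isfinite(temp.to_numpy(dtype=float)).all():
        raise ValueError("temperature values must be finite")
    return temp


def compute_thresholds(
    temp: pd.Series, p_low: float = 0.95, p_high: float = 0.98
) -> Thresholds:
    """Empirical percentile thresholds from *all* days of the series.

    The thresholds are quantiles of the annual (all-days) distribution over
    the full reference period — not a summer-only subset.  Quantiles use
    linear interpolation between order statistics.
    """
    temp = validate_temperature(temp)
    if not (0 < p_low <= p_high < 1):
        raise ValueError("need 0 < p_low <= p_high < 1")
    if len(temp) < 365:
        raise ValueError("thresholds need at least one full year of data")
    values = temp.to_numpy(dtype=float)
    t95, t98 = np.quantile(values, [p_low, p_high])
    return Thresholds(
        t95=float(t95),
        t98=float(t98),
        reference_period=(temp.index[0].date(), temp.index[-1].date()),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_heat_waves(temp: pd.Series, thresholds: Thresholds) -> list[HeatWave]:
    """Maximal runs of days with tmean ≥ t95, kept if the run lasts ≥ 3 days
    and contains at least one day with tmean > t98.

    The comparison operators follow the definition exactly: a day qualifies
    by *reaching or exceeding* t95 (``>=``) while the intensity day must
    *exceed* t98 (``>``).  Events are disjoint and sorted by construction;
    ids are assigned per calendar year of the start date.
    """
    temp = validate_temperature(temp)
    values = temp.to_numpy(dtype=float)
    events: list[HeatWave] = []
    counts: dict[int, int] = {}
    for i0, i1 in _runs(values >= thresholds.t95):
        if i1 - i0 < 3:
            continue
        window = values[i0:i1]
        if not (window > thresholds.t98).any():
            continue
        start = temp.index[i0].date()
        end = temp.index[i1 - 1].date()
        year = start.year
        counts[year] = counts.get(year, 0) + 1
        events.append(
            HeatWave(
                id=f"{year}_{counts[year]}",
                start=start,
                end=end,
                duration_days=i1 - i0,
                avg_tmean=float(window.mean()),
                max_tmean=float(window.max()),
            )
        )
    return events


def ehi_sig(temp: pd.Series, thresholds: Thresholds | float) -> pd.Series:
    """Significance index: backward 3-day mean minus the t95 threshold.

    Undefined (NaN) on the first two days of the series.
    """
    temp = validate_temperature(temp)
    t95 = thresholds.t95 if isinstance(thresholds, Thresholds) else float(thresholds)
    out = temp.rolling(3).mean() - t95
    out.name = "ehi_sig"
    return out

def ehi_accl(temp: pd.Series) -> pd.Series:
    """Acclimatization index: backward 3-day mean minus the mean of the 30
    preceding days (days i-3 … i-32).  Undefined before day 33.
    """
    temp = validate_temperature(temp)
    out = temp.rolling(3).mean() - temp.shift(3).rolling(30).mean()
    out.name = "ehi_accl"
    return out


def ehf(ehi_sig_series: pd.Series, ehi_accl_series: pd.Series) -> pd.Series:
    """Excess heat factor: ``max(0, EHIsig) × max(1, EHIaccl)``.

    Non-negative wherever defined; zero whenever the 3-day mean does not
    exceed the threshold.  NaN wherever either input is NaN.
    """
    if not ehi_sig_series.index.equals(ehi_accl_series.index):
        raise ValueError("EHIsig and EHIaccl series must share the same dates")
    sig = ehi_sig_series.to_numpy(dtype=float)
    accl = ehi_accl_series.to_numpy(dtype=float)
    out = pd.Series(
        np.maximum(0.0, sig) * np.maximum(1.0, accl),
        index=ehi_sig_series.index,
        name="ehf",
    )
    out[np.isnan(sig) | np.isnan(accl)] = np.nan
    return out


def compute_daily_metrics(temp: pd.Series, thresholds: Thresholds) -> pd.DataFrame:
    """Convenience: DataFrame with ehi_sig, ehi_accl, ehf columns by date."""
    sig = ehi_sig(temp, thresholds)
    accl = ehi_accl(temp)
    return pd.DataFrame({"ehi_sig": sig, "ehi_accl": accl, "ehf": ehf(sig, accl)})


def summarize_heat_wave(
    hw: HeatWave, temp: pd.Series, metrics: pd.DataFrame
) -> HeatWave:
    """Fill the event's cumulative heat-load summaries.

    Daily EHIsig, EHIaccl and EHF are summed raw over event days to give the
    total heat load (negative daily EHIsig values on early event days are
    included; EHF is already floored at zero daywise).  Events overlapping
    the 32-day warm-up, where the indices are undefined, are rejected.
    """
    temp = validate_temperature(temp)
    days = hw.dates
    if not days.isin(temp.index).all() or not days.isin(metrics.index).all():
        raise ValueError(f"event {hw.id} not fully covered by the series")
    sub = metrics.loc[days, ["ehi_sig", "ehi_accl", "ehf"]]
    if sub.isna().any().any():
        raise ValueError(
            f"event {hw.id} overlaps the warm-up period: daily indices are "
            "undefined on some of its days"
        )
    window = temp.loc[days].to_numpy(dtype=float)
    return replace(
        hw,
        avg_tmean=float(window.mean()),
        max_tmean=float(window.max()),
        sum_ehi_sig=float(sub["ehi_sig"].sum()),
        sum_ehi_accl=float(sub["ehi_accl"].sum()),
        sum_ehf=float(sub["ehf"].sum()),
    )


def heat_wave_table(events: Sequence[HeatWave]) -> pd.DataFrame:
    """Tabulate events with the report column set (one row per event)."""
    rows = [
        {
            "id": hw.id,
            "start": hw.start.isoformat(),
            "end": hw.end.isoformat(),
            "days": hw.duration_days,
            "avg_tmean": hw.avg_tmean,
            "max_tmean": hw.max_tmean,
            "sum_ehi_sig": hw.sum_ehi_sig,
            "sum_ehi_accl": hw.sum_ehi_accl,
            "sum_ehf": hw.sum_ehf,
        }
        for hw in events
    ]
    columns = [
        "id", "start", "end", "days", "avg_tmean", "max_tmean",
        "sum_ehi_sig", "sum_ehi_accl", "sum_ehf",
    ]
    return pd.DataFrame(rows, columns=columns)
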