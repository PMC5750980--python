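"""Seeded synthetic inputs: daily temperature, stratified deaths, populations.

The generator emulates the statistical structure the downstream analysis
assumes for a mid-latitude national registry:

* temperature — a sinusoidal annual cycle (peak mid-July) plus stationary
  AR(1) noise, with flat additive "heat episode" bumps injectable at chosen
  dates to manufacture heat waves;
* mortality — per-stratum daily counts drawn from a Poisson law whose
  log-mean is the sum of a slow secular trend, a winter-peaked seasonal
  cycle, a weekly cycle (maximum Monday, minimum Sunday), and an additive
  heat effect on heat-wave days (a constant log offset, or proportional to
  the daily excess heat factor);
* population — four sex × age strata whose shares drift linearly across
  the simulated years (the 65+ share rising from ~13% to ~18%), evaluated
  at mid-year (1 July) and held constant within each calendar year, as
  registry denominators are.

Everything is reproducible for a fixed seed: temperature and mortality use
independent child streams of the configured seed, so regenerating one never
perturbs the other.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .standardize import STRATA, default_standard_population

__all__ = ["HeatEpisode", "SynthConfig", "generate_temperature", "generate_mortality", "write_inputs"]

_DAYS_PER_YEAR = 365.25
# day-of-year phase anchors: temperature peaks mid-July, mortality mid-January
_TEMP_PEAK_DOY = 197
_MORT_PEAK_DOY = 15


@dataclass(frozen=True)
class HeatEpisode:
    """A flat additive temperature bump of ``amplitude_c`` °C lasting
    ``length_days`` days from ``start`` (inclusive)."""

    start: dt.date
    length_days: int
    amplitude_c: float

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError("episode length must be at least 1 day")


def _default_dow_effects() -> tuple[float, ...]:
    # Monday..Sunday log-scale offsets, sum-to-zero, max Monday min Sunday
    return (0.020, 0.010, 0.005, 0.000, -0.003, -0.007, -0.025)


def _default_age_start() -> dict[str, float]:
    # 65+ population share 13% at the series start, split evenly by sex
    return {"M_0-64": 0.435, "F_0-64": 0.435, "M_65+": 0.055, "F_65+": 0.075}


def _default_age_end() -> dict[str, float]:
    # 65+ share 18% by the series end
    return {"M_0-64": 0.410, "F_0-64": 0.410, "M_65+": 0.075, "F_65+": 0.105}


def _default_death_shares() -> dict[str, float]:
    # stratum shares of expected deaths: sex split ~49/51, age split ~22/78,
    # crossed under independence (typical of an ageing Central European
    # national registry)
    raw = {
        "M_0-64": 0.4928 * 0.2160,
        "M_65+": 0.4928 * 0.7840,
        "F_0-64": 0.5072 * 0.2160,
        "F_65+": 0.5072 * 0.7840,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass
class SynthConfig:
    """Parameters of the synthetic registry; defaults give Czech-like
    magnitudes (≈10.5M inhabitants, ≈300 natural-cause deaths/day)."""

    n_years: int = 5
    start_date: dt.date = dt.date(2000, 1, 1)
    temp_mean_annual: float = 9.0
    temp_seasonal_amplitude: float = 10.0
    ar1_coefficient: float = 0.7
    noise_sd: float = 2.0  # marginal (stationary) sd of the AR(1) noise, °C
    heat_episodes: list[HeatEpisode] = field(default_factory=list)
    base_daily_deaths: float = 300.0
    secular_trend: float = -0.005  # relative change per year
    mortality_seasonal_amplitude: float = 0.10  # relative, log scale
    dow_effects: tuple[float, ...] = field(default_factory=_default_dow_effects)
    heat_effect_beta: float = 0.12
    heat_effect_mode: str = "binary"  # "binary" (per heat-wave day) or "ehf" (per unit EHF)
    age_structure_start: Mapping[str, float] = field(default_factory=_default_age_start)
    age_structure_end: Mapping[str, float] = field(default_factory=_default_age_end)
    death_shares: Mapping[str, float] = field(default_factory=_default_death_shares)
    total_population: float = 10.5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError(
                "n_years must be >= 2: the acclimatization index needs a "
                "32-day history and the baseline model multi-year seasonality"
            )
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1 for stationarity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.base_daily_deaths < 0:
            raise ValueError("base_daily_deaths must be non-negative")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Monday..Sunday)")
        if not np.isclose(sum(self.dow_effects), 0.0, atol=1e-9):
            raise ValueError("dow_effects must sum to zero (identification)")
        if self.heat_effect_mode not in ("binary", "ehf"):
            raise ValueError("heat_effect_mode must be 'binary' or 'ehf'")
        for name in ("age_structure_start", "age_structure_end", "death_shares"):
            shares = getattr(self, name)
            if set(shares) != set(STRATA):
                raise ValueError(f"{name} must cover strata {STRATA}")
            if not np.isclose(sum(shares.values()), 1.0, atol=1e-6):
                raise ValueError(f"{name} shares must sum to 1")
        self.heat_episodes = [
            ep if isinstance(ep, HeatEpisode) else HeatEpisode(*ep)
            for ep in self.heat_episodes
        ]

    @property
    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start_date)
        end = start + pd.DateOffset(years=self.n_years) - pd.Timedelta(days=1)
        return pd.date_range(start, end, freq="D")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent child streams per component, all derived from config.seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_temperature(config: SynthConfig) -> pd.Series:
    """Daily mean temperature: seasonal cycle + AR(1) noise + episode bumps."""
    dates = config.dates
    doy = dates.dayofyear.to_numpy()
    seasonal = config.temp_mean_annual + config.temp_seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _TEMP_PEAK_DOY) / _DAYS_PER_YEAR
    )

    n = len(dates)
    noise = np.zeros(n)
    if config.noise_sd > 0:
        rng = _rng(config, 0)
        phi = config.ar1_coefficient
        innov_sd = config.noise_sd * np.sqrt(1 - phi**2)
        eps = rng.normal(0.0, 1.0, size=n)
        noise[0] = eps[0] * config.noise_sd  # stationary start
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + innov_sd * eps[i]

    temp = seasonal + noise
    series = pd.Series(temp, index=dates, name="tmean_c")
    for ep in config.heat_episodes:
        ep_start = pd.Timestamp(ep.start)
        ep_end = ep_start + pd.Timedelta(days=ep.length_days - 1)
        if ep_start < dates[0] or ep_end > dates[-1]:
            raise ValueError(
                f"heat episode {ep.start} (+{ep.length_days}d) falls outside "
                f"the simulated range {dates[0].date()}..{dates[-1].date()}"
            )
        series.loc[ep_start:ep_end] += ep.amplitude_c
    return series


def stratum_populations(config: SynthConfig) -> pd.DataFrame:
    """Mid-year population per stratum and calendar year (wide, year-indexed).

    Stratum shares interpolate linearly from ``age_structure_start`` in the
    first simulated year to ``age_structure_end`` in the last; the mid-year
    (1 July) value is held constant across each year, as registry
    denominators are.
    """
    years = sorted({d.year for d in config.dates})
    k = np.arange(len(years))
    frac = k / max(len(years) - 1, 1)
    data = {}
    for stratum in STRATA:
        s0 = config.age_structure_start[stratum]
        s1 = config.age_structure_end[stratum]
        data[stratum] = (s0 + frac * (s1 - s0)) * config.total_population
    return pd.DataFrame(data, index=pd.Index(years, name="year"))


def generate_mortality(
    config: SynthConfig,
    temp: pd.Series,
    heat_wave_days: set | Sequence,
    ehf_series: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-stratum daily death counts with trend, season, weekday and heat
    structure, plus linearly drifting population denominators.

    ``heat_wave_days`` is the set of dates carrying the heat effect in
    binary mode (it may be empty).  In ``"ehf"`` mode the log-scale heat
    term is ``heat_effect_beta × EHF_i`` instead, and ``ehf_series`` must be
    supplied (NaN warm-up days contribute no heat term).

    Returns a long-format DataFrame (date, stratum, deaths, population).
    """
    dates = config.dates
    if not dates.equals(temp.index):
        raise ValueError("temperature series must cover the configured date range")
    hw_days = pd.DatetimeIndex(sorted(pd.Timestamp(d) for d in heat_wave_days))
    if len(hw_days) and (~hw_days.isin(dates)).any():
        raise ValueError("heat_wave_days must lie within the simulated range")

    years_elapsed = (dates - dates[0]).days.to_numpy() / _DAYS_PER_YEAR
    doy = dates.dayofyear.to_numpy()
    log_mu = (
        np.log(max(config.base_daily_deaths, 1e-12))
        + years_elapsed * np.log1p(config.secular_trend)
        + config.mortality_seasonal_amplitude
        * np.cos(2 * np.pi * (doy - _MORT_PEAK_DOY) / _DAYS_PER_YEAR)
        + np.asarray(config.dow_effects)[dates.dayofweek.to_numpy()]
    )

    if config.heat_effect_mode == "binary":
        log_mu = log_mu + config.heat_effect_beta * dates.isin(hw_days).astype(float)
    else:
        if ehf_series is None:
            raise ValueError("heat_effect_mode='ehf' requires ehf_series")
        ehf_vals = ehf_series.reindex(dates).fillna(0.0).to_numpy(dtype=float)
        log_mu = log_mu + config.heat_effect_beta * ehf_vals

    pops = stratum_populations(config)
    year_idx = dates.year.to_numpy()
    rng = _rng(config, 1)
    frames = []
    for stratum in STRATA:
        share = config.death_shares[stratum]
        counts = rng.poisson(np.exp(log_mu) * share)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "stratum": stratum,
                    "deaths": counts,
                    "population": pops.loc[year_idx, stratum].to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["date", "stratum"], kind="stable").reset_index(drop=True)


def write_inputs(
    config: SynthConfig,
    out_dir: str | Path,
    temp: pd.Series,
    mortality: pd.DataFrame,
) -> dict[str, Path]:
    """Write temperature.csv, mortality.csv, standard_population.csv and the
    config (YAML) to ``out_dir``; ISO-8601 dates throughout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": out_dir / "temperature.csv",
        "mortality": out_dir / "mortality.csv",
        "standard_population": out_dir / "standard_population.csv",
        "config": out_dir / "config.yaml",
    }
    temp.rename("tmean_c").rename_axis("date").to_csv(
        paths["temperature"], lineterminator="\r\n"
    )
    mort = mortality.copy()
    mort["date"] = pd.to_datetime(mort["date"]).dt.strftime("%Y-%m-%d")
    mort.to_csv(paths["mortality"], index=False, lineterminator="\r\n")
    default_standard_population().rename_axis("stratum").to_csv(
        paths["standard_population"], lineterminator="\r\n"
    )
    cfg = dataclasses.asdict(config)
    cfg["start_date"] = config.start_date.isoformat()
    cfg["heat_episodes"] = [
        {"start": ep.start.isoformat(), "length_days": ep.length_days,
         "amplitude_c": ep.amplitude_c}
        for ep in config.heat_episodes
    ]
    for key in ("age_structure_start", "age_structure_end", "death_shares"):
        cfg[key] = dict(cfg[key])
    cfg["dow_effects"] = list(config.dow_effects)
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
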