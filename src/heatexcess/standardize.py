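"""Direct age-standardization of daily death counts.

Daily deaths are converted to rates per 10,000,000 standard population so
that series from years with different age structures are comparable: the
age-specific rates of the study population are weighted by a fixed standard
population instead of the population actually at risk.  Sex is never
standardized over — male/female series apply age weights within sex.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRATA",
    "AGE_BANDS",
    "GROUPS",
    "default_standard_population",
    "standardized_rate",
    "standardize_series",
]

#: sex × age strata used throughout: M/F crossed with 0–64 and 65+.
STRATA = ("M_0-64", "M_65+", "F_0-64", "F_65+")
AGE_BANDS = ("0-64", "65+")
#: population groups reported by the pipeline.
GROUPS = ("total", "male", "female", "0-64", "65+")

PER = 1e7  # rates are per 10,000,000 standard population

# European standard population (the classic WHO reference, totalling
# 100,000 across 5-year bands) aggregated to the two analysis age bands.
_ESP_WEIGHTS = {"0-64": 0.89, "65+": 0.11}


def default_standard_population() -> pd.Series:
    """Standard-population weights by age band (sum to 1)."""
    return pd.Series(_ESP_WEIGHTS, name="weight")


def split_stratum(stratum: str) -> tuple[str, str]:
    """``"M_65+" -> ("M", "65+")``."""
    sex, _, age = stratum.partition("_")
    if sex not in ("M", "F") or age not in AGE_BANDS:
        raise ValueError(f"unknown stratum label {stratum!r}")
    return sex, age


def _check_weights(weights: pd.Series) -> pd.Series:
    weights = pd.Series(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("standard-population weights must be non-negative")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("standard-population weights must sum to 1")
    return weights


def standardized_rate(
    deaths: Mapping[str, float] | pd.Series,
    population: Mapping[str, float] | pd.Series,
    weights: Mapping[str, float] | pd.Series,
) -> float:
    """Directly standardized rate per 10,000,000 for one day.

    ``deaths`` and ``population`` are indexed by age band; the result is
    ``Σ_a (deaths_a / population_a) × weight_a × 10^7``.  Every age band in
    the weight table must be present with a positive population.
    """
    deaths = pd.Series(deaths, dtype=float)
    population = pd.Series(population, dtype=float)
    weights = _check_weights(pd.Series(weights, dtype=float))
    missing = weights.index.difference(deaths.index).union(
        weights.index.difference(population.index)
    )
    if len(missing):
        raise ValueError(f"missing age strata: {list(missing)}")
    deaths = deaths.loc[weights.index]
    population = population.loc[weights.index]
    if (deaths < 0).any():
        raise ValueError("death counts must be non-negative")
    if (population <= 0).any():
        raise ValueError("populations must be positive")
    return float(((deaths / population) * weights).sum() * PER)


def standardize_series(
    mortality: pd.DataFrame,
    std_pop: pd.Series | None = None,
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Daily age-standardized rates for each requested population group.

    ``mortality`` is long-format with columns ``date``, ``stratum``,
    ``deaths``, ``population`` over the four sex × age strata.  For the
    sexed groups, deaths and populations of the other sex are dropped and
    age weights are applied within sex; for the single-age-band groups the
    "standardization" reduces to the crude rate of that band.

    Returns a date-indexed DataFrame with one column per group.
    """
    if std_pop is None:
        std_pop = default_standard_population()
    std_pop = _check_weights(pd.Series(std_pop, dtype=float))

    required = {"date", "stratum", "deaths", "population"}
    if not required.issubset(mortality.columns):
        raise ValueError(f"mortality table needs columns {sorted(required)}")
    df = mortality.copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["deaths"] < 0).any():
        raise ValueError("death counts must be non-negative")
    if (df["population"] <= 0).any():
        raise ValueError("populations must be positive")

    sexes = df["stratum"].map(lambda s: split_stratum(s)[0])
    ages = df["stratum"].map(lambda s: split_stratum(s)[1])
    df = df.assign(sex=sexes, age=ages)

    def _age_table(sub: pd.DataFrame, col: str) -> pd.DataFrame:
        out = sub.pivot_table(index="date", columns="age", values=col, aggfunc="sum")
        missing = [a for a in std_pop.index if a not in out.columns]
        if missing:
            raise ValueError(f"missing age strata: {missing}")
        if out.isna().any().any():
            raise ValueError("mortality table has date gaps for some strata")
        return out[list(std_pop.index)]

    result: dict[str, pd.Series] = {}
    for group in groups:
        if group == "total":
            sub = df
        elif group == "male":
            sub = df[df["sex"] == "M"]
        elif group == "female":
            sub = df[df["sex"] == "F"]
        elif group in AGE_BANDS:
            sub = df[df["age"] == group]
        else:
            raise ValueError(f"unknown group {group!r}")
        if group in AGE_BANDS:
            # single age band: weight 1 on that band (crude rate)
            d = sub.groupby("date")["deaths"].sum()
            p = sub.groupby("date")["population"].sum()
            if (p <= 0).any():
                raise ValueError("populations must be positive")
            result[group] = d / p * PER
        else:
            deaths = _age_table(sub, "deaths")
            pops = _age_table(sub, "population")
            rates = deaths.to_numpy() / pops.to_numpy()
            result[group] = pd.Series(
                rates @ std_pop.to_numpy() * PER, index=deaths.index
            )

    out = pd.DataFrame(result)
    out.index.name = "date"
    return out
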