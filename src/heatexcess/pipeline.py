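"""End-to-end orchestration: generate/load → detect → fit → excess → EHP → assoc.

Stages run in a fixed order, each writing its report table as RFC-4180 CSV
with ISO-8601 dates; a failure aborts with the stage name and cause.  For a
fixed configuration the run is fully deterministic, so repeated runs emit
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import baseline as baseline_mod
from . import displacement as disp_mod
from . import excess as excess_mod
from . import heatmetrics as hm
from . import standardize as std_mod
from .synth import HeatEpisode, SynthConfig, generate_mortality, generate_temperature, write_inputs

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "example_synth_config", "STAGES"]

STAGES = ("inputs", "detect", "standardize", "baseline", "excess", "ehp", "assoc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def example_synth_config(
    seed: int = 0,
    n_years: int = 6,
    heat_effect_mode: str = "binary",
    heat_effect_beta: Optional[float] = None,
) -> SynthConfig:
    """A ready-made synthetic study: two summer heat episodes per year with
    staggered timing, length (3–9 days) and strength (7–11 °C)."""
    if heat_effect_beta is None:
        # per heat-wave day on the log scale, or per °C² of daily EHF
        heat_effect_beta = 0.12 if heat_effect_mode == "binary" else 0.01
    start_year = 2000
    episodes = []
    for y in range(n_years):
        episodes.append(
            HeatEpisode(
                dt.date(start_year + y, 7, 1 + (y % 3)),
                3 + (y % 5),
                7.0 + (y % 3),
            )
        )
        episodes.append(
            HeatEpisode(
                dt.date(start_year + y, 8, 5 + ((2 * y) % 4)),
                4 + ((y + 2) % 6),
                8.0 + ((y + 1) % 4),
            )
        )
    return SynthConfig(
        n_years=n_years,
        start_date=dt.date(start_year, 1, 1),
        heat_episodes=episodes,
        heat_effect_mode=heat_effect_mode,
        heat_effect_beta=heat_effect_beta,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic by default).

    Supply ``temperature_csv``/``mortality_csv``/``standard_population_csv``
    to analyse real inputs instead of generating synthetic ones.
    """

    out_dir: str = "heatexcess_out"
    synth: SynthConfig = field(default_factory=example_synth_config)
    temperature_csv: Optional[str] = None
    mortality_csv: Optional[str] = None
    standard_population_csv: Optional[str] = None
    p_low: float = 0.95
    p_high: float = 0.98
    df_per_year: int = 6
    alpha: float = 0.05
    ehp_scan_cap: int = 30
    groups: tuple[str, ...] = std_mod.GROUPS
    seed: Optional[int] = None  # overrides synth.seed when set

    def __post_init__(self) -> None:
        if not (0 < self.p_low < self.p_high < 1):
            raise ValueError("need 0 < p_low < p_high < 1")
        for path in (self.temperature_csv, self.mortality_csv, self.standard_population_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if self.seed is not None:
            self.synth = dataclasses.replace(self.synth, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", None)
        if synth_raw is not None:
            if "start_date" in synth_raw:
                synth_raw["start_date"] = dt.date.fromisoformat(synth_raw["start_date"])
            if "heat_episodes" in synth_raw:
                synth_raw["heat_episodes"] = [
                    HeatEpisode(
                        dt.date.fromisoformat(ep["start"]),
                        int(ep["length_days"]),
                        float(ep["amplitude_c"]),
                    )
                    if isinstance(ep, dict)
                    else HeatEpisode(*ep)
                    for ep in synth_raw["heat_episodes"]
                ]
            if "dow_effects" in synth_raw:
                synth_raw["dow_effects"] = tuple(synth_raw["dow_effects"])
            raw["synth"] = SynthConfig(**synth_raw)
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.temperature_csv is not None:
        temp = pd.read_csv(config.temperature_csv, parse_dates=["date"]).set_index("date")["tmean_c"]
        mortality = pd.read_csv(config.mortality_csv, parse_dates=["date"])
        std_pop = pd.read_csv(config.standard_population_csv).set_index("stratum")["weight"]
        return temp, mortality, std_pop, None

    temp = generate_temperature(config.synth)
    thresholds = hm.compute_thresholds(temp, config.p_low, config.p_high)
    events = hm.detect_heat_waves(temp, thresholds)
    hw_days = {d for hw in events for d in hw.dates}
    metrics = hm.compute_daily_metrics(temp, thresholds)
    mortality = generate_mortality(
        config.synth, temp, hw_days, ehf_series=metrics["ehf"]
    )
    return temp, mortality, std_mod.default_standard_population(), thresholds


def run_pipeline(
    config: PipelineConfig, through: str = "assoc", write: bool = True
) -> dict:
    """Run the pipeline up to stage ``through`` and return its artifacts.

    Returns a dict holding the in-memory objects (temperature, events,
    rates, baseline results, summaries, tables).  With ``write=True`` the
    report CSVs and a JSON run log are written under ``config.out_dir``.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    stop = STAGES.index(through)
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}

    def _write_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        if write:
            df.to_csv(out_dir / name, index=index, lineterminator="\r\n")

    # --- inputs ---------------------------------------------------------
    try:
        temp, mortality, std_pop, thresholds = _load_inputs(config)
        artifacts.update(temperature=temp, mortality=mortality, std_pop=std_pop)
        if write and config.temperature_csv is None:
            write_inputs(config.synth, out_dir, temp, mortality)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError("inputs", exc) from exc
    if stop == 0:
        return artifacts

    # --- detect ---------------------------------------------------------
    try:
        if thresholds is None:
            thresholds = hm.compute_thresholds(temp, config.p_low, config.p_high)
        metrics = hm.compute_daily_metrics(temp, thresholds)
        events = hm.detect_heat_waves(temp, thresholds)
        summarized: list[hm.HeatWave] = []
        for hw in events:
            try:
                summarized.append(hm.summarize_heat_wave(hw, temp, metrics))
            except ValueError:
                summarized.append(hw)  # warm-up overlap: sums stay undefined
        artifacts.update(thresholds=thresholds, metrics=metrics, heat_waves=summarized)
        _write_csv(hm.heat_wave_table(summarized), "heatwaves.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("detect", exc) from exc
    if stop == 1:
        return artifacts

    # --- standardize ----------------------------------------------------
    try:
        rates = std_mod.standardize_series(mortality, std_pop, config.groups)
        artifacts["rates"] = rates
        out = rates.round(6).reset_index().melt(
            id_vars="date", var_name="group", value_name="rate_per_10M"
        )
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        _write_csv(out.sort_values(["group", "date"], kind="stable"), "standardized_rates.csv")
    except Exception as exc:
        raise PipelineError("standardize", exc) from exc
    if stop == 2:
        return artifacts

    # --- baseline -------------------------------------------------------
    try:
        hw_days = {d for hw in artifacts["heat_waves"] for d in hw.dates}
        fits = {}
        series = {}
        for group in config.groups:
            res = baseline_mod.fit_baseline(rates[group], hw_days, config.df_per_year)
            fits[group] = res
            series[group] = res.baseline_series()
        artifacts.update(baseline_fits=fits, baseline_series=series)
        frames = []
        for group, df in series.items():
            f = df.round(6).reset_index().rename(columns={"index": "date"})
            f.insert(1, "group", group)
            f["date"] = pd.to_datetime(f["date"]).dt.strftime("%Y-%m-%d")
            frames.append(f)
        _write_csv(pd.concat(frames, ignore_index=True), "baseline.csv")
        if write:
            summary = {g: fits[g].to_dict() for g in fits}
            (out_dir / "baseline_model.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
    except Exception as exc:
        raise PipelineError("baseline", exc) from exc
    if stop == 3:
        return artifacts

    # --- excess ---------------------------------------------------------
    try:
        summaries: dict[str, list[excess_mod.ExcessSummary]] = {}
        for group in config.groups:
            summaries[group] = [
                excess_mod.summarize_excess(hw, series[group], group, config.alpha)
                for hw in artifacts["heat_waves"]
            ]
        artifacts["excess"] = summaries
        flat = [s for group in config.groups for s in summaries[group]]
        _write_csv(excess_mod.excess_table(flat), "excess_by_heatwave.csv")
    except Exception as exc:
        raise PipelineError("excess", exc) from exc
    if stop == 4:
        return artifacts

    # --- ehp (mortality displacement; whole-population deviations) ------
    try:
        total = series["total"] if "total" in series else series[config.groups[0]]
        rmd = excess_mod.daily_rmd(total["observed"], total["baseline"])
        smoothed = disp_mod.moving_average_3(rmd)
        ehps = disp_mod.delimit_ehps(
            artifacts["heat_waves"], smoothed, scan_cap=config.ehp_scan_cap
        )
        artifacts.update(smoothed_rmd=smoothed, ehps=ehps)
        _write_csv(disp_mod.ehp_table(ehps), "ehp.csv")
    except Exception as exc:
        raise PipelineError("ehp", exc) from exc
    if stop == 5:
        return artifacts

    # --- assoc ----------------------------------------------------------
    try:
        events_by_group = {
            group: list(zip(artifacts["heat_waves"], summaries[group]))
            for group in config.groups
        }
        usable = [
            hw for hw in artifacts["heat_waves"] if hw.sum_ehf is not None
        ]
        if len(usable) >= 3:
            table = assoc_mod.association_table(events_by_group)
        else:
            table = pd.DataFrame(
                columns=["predictor", "group", "slope", "r_squared", "p_value", "n_events"]
            )
        artifacts["association"] = table
        _write_csv(table.round(6), "association.csv")
        if write:
            log = {
                "seed": config.synth.seed,
                "stages": list(STAGES[: stop + 1]),
                "n_heat_waves": len(artifacts["heat_waves"]),
                "versions": _versions(),
            }
            (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineError("assoc", exc) from exc
    return artifacts


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "heatexcess": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
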