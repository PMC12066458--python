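"""Synthetic 20-year wheat–maize rotation datasets.

The generator emulates the statistical structure the accounting
pipeline assumes for a North China Plain winter wheat–summer maize
rotation: linear multi-year trends in yields, climate and the net
budget, a soil organic carbon trajectory that gains during the wheat
season (straw incorporated by tillage) and loses during the maize
season (straw surface-mulched), and Gaussian observation noise.  Its
defaults reproduce the study conditions of a two-decade on-farm
rotation: yields climbing 70 (wheat) and 184 (maize) kg ha⁻¹ yr⁻¹,
warming of 0.08 °C yr⁻¹, sunshine increasing 57 h yr⁻¹, and seasonal
SOC increments of +0.58 (wheat) and −0.72 (maize) g kg⁻¹ yr⁻¹.

With all noise standard deviations at zero every configured trend is
recovered exactly by the corresponding pipeline estimator, which makes
the generator double as an oracle for end-to-end tests; with noise the
estimators are unbiased and the recovery harness quantifies the error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    Crop,
    EmissionFactorTable,
    SeasonRecord,
    default_emission_factor_table,
    write_season_records,
)
from .errors import ValidationError
from .footprint_econ import carbon_cost
from .ghg_inventory import total_ghg
from .soc_carbon import seasonal_sequestration, soc_annual_rate
from .trend_stats import ols_trend

#: Typical per-season input schedules (per hectare).  Most fertilizer,
#: all P and K, and the irrigation load fall in the wheat season, as in
#: the local rotation practice.
DEFAULT_WHEAT_INPUTS: dict[str, float] = {
    "n_fertilizer": 300.0,  # kg N
    "p_fertilizer": 60.0,   # kg P
    "k_fertilizer": 75.0,   # kg K
    "irrigation": 1800.0,   # m^3
    "electricity": 500.0,   # kWh
    "diesel": 70.0,         # L
    "seeds": 150.0,         # kg
    "pesticides": 3.0,      # kg a.i.
}

DEFAULT_MAIZE_INPUTS: dict[str, float] = {
    "n_fertilizer": 120.0,
    "p_fertilizer": 0.0,
    "k_fertilizer": 0.0,
    "irrigation": 400.0,
    "electricity": 120.0,
    "diesel": 40.0,
    "seeds": 30.0,
    "pesticides": 1.5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic rotation generator.

    Yield intercepts are the expected yield in the first study year;
    trends are per calendar year.  SOC increments are the within-season
    change applied once per season.  Noise standard deviations apply to
    the observed yields, SOC measurements, input costs and climate
    variables; the underlying trajectories stay noiseless so that
    configured trends are exactly recoverable at zero noise.
    """

    start_year: int = 2003
    n_years: int = 20
    seed: int = 0

    wheat_yield_intercept: float = 5877.0  # kg ha^-1 in start_year
    wheat_yield_trend: float = 70.0        # kg ha^-1 yr^-1
    maize_yield_intercept: float = 6949.0
    maize_yield_trend: float = 184.0

    wheat_soc_increment: float = 0.58   # g kg^-1 per wheat season
    maize_soc_increment: float = -0.72  # g kg^-1 per maize season
    soc_initial: float = 7.0            # g kg^-1 (12.06 g kg^-1 SOM x 0.58)
    bd: float = 1.33                    # g cm^-3
    depth: float = 0.2                  # m

    temp_baseline: float = 14.4    # deg C annual mean in start_year
    temp_trend: float = 0.08       # deg C yr^-1
    sunshine_baseline: float = 2180.0  # h yr^-1
    sunshine_trend: float = 57.0       # h yr^-1 per year

    wheat_price: float = 0.33  # US$ per kg grain
    maize_price: float = 0.27
    wheat_input_cost: float = 814.0  # US$ ha^-1 mean
    maize_input_cost: float = 576.0

    wheat_inputs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WHEAT_INPUTS)
    )
    maize_inputs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAIZE_INPUTS)
    )
    harvest_index_wheat: float = 0.45
    harvest_index_maize: float = 0.50
    straw_return_fraction: float = 0.9
    straw_n_content_wheat: float = 0.006  # mass fraction
    straw_n_content_maize: float = 0.011

    yield_sd: float = 300.0  # kg ha^-1
    soc_sd: float = 0.3      # g kg^-1
    cost_sd: float = 60.0    # US$ ha^-1
    temp_sd: float = 0.4     # deg C
    sunshine_sd: float = 90.0  # h

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValidationError(f"n_years must be >= 3, got {self.n_years}")
        for name in ("yield_sd", "soc_sd", "cost_sd", "temp_sd", "sunshine_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.straw_return_fraction <= 1.0:
            raise ValidationError("straw_return_fraction must be in [0, 1]")

    def noiseless(self) -> "GeneratorConfig":
        """A copy with every noise standard deviation set to zero."""
        return dataclasses.replace(
            self, yield_sd=0.0, soc_sd=0.0, cost_sd=0.0, temp_sd=0.0, sunshine_sd=0.0
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RotationData:
    """One generated dataset: season records, soil observations, climate."""

    config: GeneratorConfig
    seasons: list[SeasonRecord]
    soil: pd.DataFrame
    climate: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write seasons/soil/climate CSVs plus the true-parameter JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "seasons": outdir / "season_records.csv",
            "soil": outdir / "soil_observations.csv",
            "climate": outdir / "climate.csv",
            "truth": outdir / "generator_config.json",
        }
        write_season_records(self.seasons, paths["seasons"])
        self.soil.to_csv(paths["soil"], index=False)
        self.climate.to_csv(paths["climate"], index=False)
        paths["truth"].write_text(json.dumps(self.config.to_dict(), indent=2))
        return paths


def _straw_biomass(grain_yield: float, harvest_index: float) -> float:
    """Non-grain aboveground biomass implied by yield and harvest index."""
    return grain_yield * (1.0 / harvest_index - 1.0)


def generate_rotation(config: GeneratorConfig) -> RotationData:
    """Generate a deterministic synthetic rotation dataset.

    Per calendar year one wheat season (harvested early in the year)
    and one maize season (harvested later the same year) are produced.
    Yields follow intercept + trend × (year − start) plus Gaussian
    noise; incomes are yield × price; straw returned is a fixed
    fraction of the previous season's non-grain biomass.  Soil
    observations bracket each season (pre-season and harvest) around a
    noiseless SOC trajectory that steps by the configured per-season
    increments, with measurement noise added on top.  Identical seeds
    give identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    seasons: list[SeasonRecord] = []
    soil_rows: list[dict] = []
    climate_rows: list[dict] = []

    # SOC state at the very first wheat pre-season sampling.
    soc_state = config.soc_initial
    # Straw available to the first wheat season: previous maize at its
    # expected first-year level.
    prev_maize_straw = _straw_biomass(
        config.maize_yield_intercept, config.harvest_index_maize
    )

    for t in range(config.n_years):
        year = config.start_year + t
        climate_rows.append(
            {
                "year": year,
                "temperature": config.temp_baseline
                + config.temp_trend * t
                + rng.normal(0.0, config.temp_sd),
                "sunshine_hours": config.sunshine_baseline
                + config.sunshine_trend * t
                + rng.normal(0.0, config.sunshine_sd),
            }
        )

        for crop in (Crop.WHEAT, Crop.MAIZE):
            if crop is Crop.WHEAT:
                mean_yield = (
                    config.wheat_yield_intercept + config.wheat_yield_trend * t
                )
                price = config.wheat_price
                inputs = dict(config.wheat_inputs)
                cost_mean = config.wheat_input_cost
                straw = config.straw_return_fraction * prev_maize_straw
                straw_n = config.straw_n_content_wheat
                increment = config.wheat_soc_increment
                hi = config.harvest_index_wheat
            else:
                mean_yield = (
                    config.maize_yield_intercept + config.maize_yield_trend * t
                )
                price = config.maize_price
                inputs = dict(config.maize_inputs)
                cost_mean = config.maize_input_cost
                # maize receives the wheat straw harvested earlier the
                # same calendar year
                straw = config.straw_return_fraction * _straw_biomass(
                    seasons[-1].grain_yield, config.harvest_index_wheat
                )
                straw_n = config.straw_n_content_maize
                increment = config.maize_soc_increment
                hi = config.harvest_index_maize

            grain_yield = max(0.0, mean_yield + rng.normal(0.0, config.yield_sd))
            cost = max(0.0, cost_mean + rng.normal(0.0, config.cost_sd))
            seasons.append(
                SeasonRecord(
                    crop=crop,
                    year=year,
                    inputs=inputs,
                    straw_returned=straw,
                    straw_n_content=straw_n,
                    grain_yield=grain_yield,
                    grain_income=grain_yield * price,
                    input_cost=cost,
                )
            )
            if crop is Crop.MAIZE:
                prev_maize_straw = _straw_biomass(grain_yield, hi)

            # bracketing soil observations around the noiseless state
            for phase, state in (
                ("preseason", soc_state),
                ("harvest", soc_state + increment),
            ):
                soil_rows.append(
                    {
                        "crop": crop.value,
                        "year": year,
                        "phase": phase,
                        "soc": max(0.0, state + rng.normal(0.0, config.soc_sd)),
                        "bd": config.bd,
                        "depth": config.depth,
                    }
                )
            soc_state += increment

    soil = pd.DataFrame(soil_rows)
    soil["soc_value"] = soil["soc"]
    return RotationData(
        config=config,
        seasons=seasons,
        soil=soil,
        climate=pd.DataFrame(climate_rows),
    )


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

_RECOVERY_PARAMS = (
    "wheat_yield_trend",
    "maize_yield_trend",
    "wheat_soc_rate",
    "maize_soc_rate",
    "wheat_neeb_trend",
    "maize_neeb_trend",
)


def _estimate(data: RotationData, ef: EmissionFactorTable) -> dict[str, float]:
    """Run the pipeline estimators on one dataset."""
    out: dict[str, float] = {}
    for crop in (Crop.WHEAT, Crop.MAIZE):
        recs = [r for r in data.seasons if r.crop is crop]
        years = [r.year for r in recs]
        out[f"{crop.value}_yield_trend"] = ols_trend(
            years, [r.grain_yield for r in recs]
        ).slope
        neebs = [
            r.grain_income
            - r.input_cost
            - carbon_cost(total_ghg(r, ef).total, ef.carbon_price)
            for r in recs
        ]
        out[f"{crop.value}_neeb_trend"] = ols_trend(years, neebs).slope
    per_season = seasonal_sequestration(data.soil)
    rates = soc_annual_rate(per_season)
    out["wheat_soc_rate"] = rates[Crop.WHEAT.value]
    out["maize_soc_rate"] = rates[Crop.MAIZE.value]
    return out


def recovery_report(
    data: RotationData,
    ef: EmissionFactorTable | None = None,
    tolerance: float = 0.25,
) -> pd.DataFrame:
    """Compare pipeline estimates against the generator's true values.

    The true value of every target (yield trends, per-season SOC rates,
    NEEB trends) is obtained by regenerating the dataset with all noise
    set to zero and running the same estimator, so noiseless inputs
    give zero error by construction.  Rows whose relative error exceeds
    ``tolerance`` are flagged.
    """
    ef = ef if ef is not None else default_emission_factor_table()
    estimated = _estimate(data, ef)
    truth = _estimate(generate_rotation(data.config.noiseless()), ef)
    rows = []
    for name in _RECOVERY_PARAMS:
        true_v, est_v = truth[name], estimated[name]
        rel = abs(est_v - true_v) / abs(true_v) if true_v != 0 else abs(est_v)
        rows.append(
            {
                "parameter": name,
                "true": true_v,
                "estimated": est_v,
                "relative_error": rel,
                "flagged": rel > tolerance,
            }
        )
    return pd.DataFrame(rows)
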