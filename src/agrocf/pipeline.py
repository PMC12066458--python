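"""End-to-end pipeline runs and the fixture verification mode.

:func:`run_pipeline` drives the full chain — season records → GHG
inventory → soil carbon stocks → footprints → aggregates → trends —
and writes full-precision CSV outputs plus a JSON run summary.

:func:`verify_fixture` recomputes the derivable statistics of the
packaged 14-wheat / 15-maize season economics table and compares them
with the published reference values: column means, the per-row NEEB
identity at the US$ 17 t⁻¹ carbon price, the mean-of-yearly-ratios
CF_NEEB, and the OLS annual NEEB increases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_data import (
    Crop,
    EmissionFactorTable,
    SeasonRecord,
    default_emission_factor_table,
    load_table1_fixture,
    read_emission_factors,
    read_season_records,
    read_soil_observations,
)
from .errors import AgroCFError
from .footprint_econ import (
    AggregationMode,
    aggregate_seasons,
    carbon_cost,
    cf_neeb,
    neeb,
    season_footprint,
)
from .ghg_inventory import total_ghg
from .soc_carbon import seasonal_sequestration, soc_annual_rate
from .trend_stats import DEFAULT_BLOCKS, ols_trend, round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters of one pipeline run."""

    records_path: str | Path
    outdir: str | Path
    ef_path: str | Path | None = None
    soil_path: str | Path | None = None
    mode: AggregationMode = AggregationMode.MEAN_OF_RATIOS
    block_edges: tuple[tuple[int, int], ...] = DEFAULT_BLOCKS
    carbon_price: float | None = None  # overrides the EF config when set
    gwp_n2o: float | None = None


def _load_ef(config: RunConfig) -> EmissionFactorTable:
    ef = (
        read_emission_factors(config.ef_path)
        if config.ef_path is not None
        else default_emission_factor_table()
    )
    overrides = {}
    if config.carbon_price is not None:
        overrides["carbon_price"] = config.carbon_price
    if config.gwp_n2o is not None:
        overrides["gwp_n2o"] = config.gwp_n2o
    return dataclasses.replace(ef, **overrides) if overrides else ef


def run_pipeline(config: RunConfig) -> dict:
    """Run the full accounting chain and write outputs to ``outdir``.

    Produces ``ghg_breakdown.csv``, ``footprints.csv``,
    ``aggregates.csv`` (both aggregation modes, labelled),
    ``trends.csv``, ``soil_stocks.csv`` when soil observations are
    supplied, and ``run_summary.json``.  Returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_season_records(config.records_path)
    logger.info("loaded %d season records", len(records))
    ef = _load_ef(config)

    seqrate: dict[tuple[str, int], float] = {}
    stocks = None
    if config.soil_path is not None:
        soil = read_soil_observations(config.soil_path)
        stocks = seasonal_sequestration(soil)
        seqrate = {
            (row["crop"], int(row["year"])): float(row["c_seqrate_kg"])
            for _, row in stocks.iterrows()
        }
        stocks.to_csv(outdir / "soil_stocks.csv", index=False)
        logger.info("computed %d seasonal carbon stocks", len(stocks))

    breakdown_rows = []
    footprints = []
    for rec in records:
        bd = total_ghg(rec, ef)
        row = {"crop": rec.crop.value, "year": rec.year, **bd.components}
        row["total"] = bd.total
        breakdown_rows.append(row)
        footprints.append(
            season_footprint(
                crop=rec.crop,
                year=rec.year,
                ghg_total=bd.total,
                grain_yield=rec.grain_yield,
                y_gain=rec.grain_income,
                a_cost=rec.input_cost,
                c_seqrate=seqrate.get((rec.crop.value, rec.year), 0.0),
                carbon_price=ef.carbon_price,
            )
        )
    pd.DataFrame(breakdown_rows).to_csv(
        outdir / "ghg_breakdown.csv", index=False
    )
    fp_df = pd.DataFrame(
        [
            {
                "crop": f.crop.value,
                "year": f.year,
                **{
                    k: getattr(f, k)
                    for k in (
                        "cf_a_with_soc",
                        "cf_a_without_soc",
                        "cf_y_with_soc",
                        "cf_y_without_soc",
                        "cf_neeb_with_soc",
                        "cf_neeb_without_soc",
                        "neeb",
                        "c_cost",
                        "c_seqrate",
                        "grain_yield",
                    )
                },
            }
            for f in footprints
        ]
    )
    fp_df.to_csv(outdir / "footprints.csv", index=False)

    agg_rows = []
    for crop in sorted({f.crop for f in footprints}, key=lambda c: c.value):
        per_crop = [f for f in footprints if f.crop is crop]
        for mode in AggregationMode:
            agg = aggregate_seasons(per_crop, mode)
            agg_rows.append(
                {
                    "crop": crop.value,
                    "aggregation_mode": mode.value,
                    "n_years": agg.n_years,
                    **{
                        k: getattr(agg, k)
                        for k in (
                            "mean_cf_a_with_soc",
                            "mean_cf_a_without_soc",
                            "mean_cf_y_with_soc",
                            "mean_cf_y_without_soc",
                            "mean_cf_neeb_with_soc",
                            "mean_cf_neeb_without_soc",
                            "mean_ghg",
                            "mean_neeb",
                        )
                    },
                }
            )
    pd.DataFrame(agg_rows).to_csv(
        outdir / "aggregates.csv", index=False
    )

    trend_rows = []
    soc_rates: dict[str, float] = {}
    if stocks is not None and (stocks.groupby("crop").size() >= 3).all():
        soc_rates = soc_annual_rate(stocks)
    for crop in sorted({r.crop for r in records}, key=lambda c: c.value):
        recs = [r for r in records if r.crop is crop]
        if len(recs) < 3:
            logger.warning("too few %s seasons for trends; skipping", crop.value)
            continue
        years = [r.year for r in recs]
        fps = {f.year: f for f in footprints if f.crop is crop}
        for variable, series in (
            ("yield", [r.grain_yield for r in recs]),
            ("grain_income", [r.grain_income for r in recs]),
            ("input_cost", [r.input_cost for r in recs]),
            ("neeb", [fps[r.year].neeb for r in recs]),
        ):
            tr = ols_trend(years, series)
            trend_rows.append(
                {
                    "crop": crop.value,
                    "variable": variable,
                    "slope_per_year": tr.slope,
                    "intercept": tr.intercept,
                    "n_years": tr.n,
                    "r_squared": tr.r_squared,
                }
            )
        if crop.value in soc_rates:
            trend_rows.append(
                {
                    "crop": crop.value,
                    "variable": "soc",
                    "slope_per_year": soc_rates[crop.value],
                    "intercept": float("nan"),
                    "n_years": int((stocks["crop"] == crop.value).sum()),
                    "r_squared": float("nan"),
                }
            )
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(outdir / "trends.csv", index=False)

    summary = {
        "version": __version__,
        "n_records": len(records),
        "carbon_price": ef.carbon_price,
        "gwp_n2o": ef.gwp_n2o,
        "aggregation_mode_default": config.mode.value,
        "aggregates": agg_rows,
        "trends": trend_rows,
        "soc_annual_rates": soc_rates,
        "outputs": [
            str(p.name)
            for p in sorted(outdir.glob("*.csv"))
        ],
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


# ---------------------------------------------------------------------------
# Fixture verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCheck:
    """One verification check: a recomputed value vs its reference."""

    name: str
    computed: float
    expected: float
    passed: bool


#: Published reference values recomputed by :func:`verify_fixture`:
#: per-crop column means (income, input cost, GHG, NEEB), the
#: mean-of-ratios CF_NEEB without SOC, and the OLS annual NEEB increase.
FIXTURE_REFERENCE = {
    "wheat": {
        "mean_grain_income": 2183,
        "mean_input_cost": 814,
        "mean_ghg_total": 7307,
        "mean_neeb": 1244,
        "cf_neeb_mean_of_ratios": 7.4,
        "neeb_slope": 83,
    },
    "maize": {
        "mean_grain_income": 2368,
        "mean_input_cost": 576,
        "mean_ghg_total": 2999,
        "mean_neeb": 1741,
        "cf_neeb_mean_of_ratios": 2.2,
        "neeb_slope": 120,
    },
}


def verify_fixture(
    fixture: pd.DataFrame | None = None,
    carbon_price: float = 17.0,
) -> list[FixtureCheck]:
    """Recompute the fixture's derivable statistics and check each one.

    Checks, per crop: the four column means against the printed Average
    row (nearest integer); the NEEB identity
    income − cost − price × GHG/1000 against every printed NEEB (within
    ±1 US$ after integer rounding); the mean of yearly GHG/NEEB ratios
    (one decimal); and the OLS slope of NEEB against calendar year
    (nearest integer).  Returns one :class:`FixtureCheck` per check.
    """
    df = fixture if fixture is not None else load_table1_fixture()
    checks: list[FixtureCheck] = []
    for crop, refs in FIXTURE_REFERENCE.items():
        sub = df[df["crop"] == crop]
        for col, key in (
            ("grain_income", "mean_grain_income"),
            ("input_cost", "mean_input_cost"),
            ("ghg_total", "mean_ghg_total"),
            ("neeb", "mean_neeb"),
        ):
            computed = float(sub[col].mean())
            checks.append(
                FixtureCheck(
                    name=f"{crop}:{key}",
                    computed=computed,
                    expected=refs[key],
                    passed=round_half_up(computed) == refs[key],
                )
            )
        for _, row in sub.iterrows():
            cost = carbon_cost(float(row["ghg_total"]), carbon_price)
            computed = neeb(
                float(row["grain_income"]), float(row["input_cost"]), cost
            ).neeb
            checks.append(
                FixtureCheck(
                    name=f"{crop}:neeb_identity:{int(row['year'])}",
                    computed=computed,
                    expected=float(row["neeb"]),
                    passed=abs(round_half_up(computed) - row["neeb"]) <= 1,
                )
            )
        ratios = [
            cf_neeb(float(r["ghg_total"]), float(r["neeb"]))
            for _, r in sub.iterrows()
        ]
        mean_ratio = sum(ratios) / len(ratios)
        checks.append(
            FixtureCheck(
                name=f"{crop}:cf_neeb_mean_of_ratios",
                computed=mean_ratio,
                expected=refs["cf_neeb_mean_of_ratios"],
                passed=round_half_up(mean_ratio, 1)
                == refs["cf_neeb_mean_of_ratios"],
            )
        )
        slope = ols_trend(sub["year"].to_list(), sub["neeb"].to_list()).slope
        checks.append(
            FixtureCheck(
                name=f"{crop}:neeb_slope",
                computed=slope,
                expected=refs["neeb_slope"],
                passed=round_half_up(slope) == refs["neeb_slope"],
            )
        )
    return checks
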