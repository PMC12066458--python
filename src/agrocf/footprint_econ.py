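"""Net ecosystem economic budget and multi-scale carbon footprints.

NEEB = Y_gain − A_cost − C_cost, where Y_gain is grain income, A_cost
the summed agricultural input costs, and C_cost the carbon-trade cost
of the season's total GHG emissions (price × emissions, default
US$ 17 per metric ton CO₂-eq).

Carbon footprints are reported on three scales:

* per area: CF_a = total GHG − C_seqrate (the soil sequestration term
  is dropped when SOC change is excluded),
* per kg grain: CF_y = CF_a / yield,
* per US$ of net income: CF_NEEB = CF_a / NEEB.

Negative CF values denote a net carbon sink.  Multi-year aggregation
supports two labelled conventions — the arithmetic mean of per-year
ratios (default) and the ratio of column means — which differ whenever
the denominator varies across years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core_data import Crop, FootprintResult
from .errors import InsufficientDataError, UndefinedRatioError, ValidationError

logger = logging.getLogger(__name__)


class AggregationMode(str, Enum):
    """How per-year ratio footprints are combined across years."""

    MEAN_OF_RATIOS = "mean_of_ratios"
    RATIO_OF_MEANS = "ratio_of_means"


@dataclass(frozen=True)
class EconomicResult:
    """One season's economics: neeb = y_gain − a_cost − c_cost."""

    y_gain: float
    a_cost: float
    c_cost: float
    neeb: float


@dataclass(frozen=True)
class SeasonalAggregate:
    """Multi-year footprint means for one crop under a declared mode."""

    crop: Crop
    n_years: int
    aggregation_mode: AggregationMode
    mean_cf_a_with_soc: float
    mean_cf_a_without_soc: float
    mean_cf_y_with_soc: float
    mean_cf_y_without_soc: float
    mean_cf_neeb_with_soc: float
    mean_cf_neeb_without_soc: float
    mean_ghg: float
    mean_neeb: float


def carbon_cost(ghg_total: float, carbon_price: float) -> float:
    """Carbon-trade cost, US$ ha⁻¹: emissions (kg) / 1000 × price (US$ t⁻¹)."""
    if ghg_total < 0 or carbon_price < 0:
        raise ValidationError("ghg_total and carbon_price must be >= 0")
    return ghg_total / 1000.0 * carbon_price


def neeb(y_gain: float, a_cost: float, c_cost: float) -> EconomicResult:
    """Net ecosystem economic budget; may be negative in bad years."""
    for name, value in (("y_gain", y_gain), ("a_cost", a_cost), ("c_cost", c_cost)):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    return EconomicResult(
        y_gain=y_gain, a_cost=a_cost, c_cost=c_cost, neeb=y_gain - a_cost - c_cost
    )


def cf_area(ghg_total: float, c_seqrate: float, include_soc: bool) -> float:
    """Area-scaled footprint, kg CO₂-eq ha⁻¹.

    With SOC included the sequestration rate (kg CO₂-eq ha⁻¹, positive
    = sink) is subtracted from the emissions total and the result may
    be negative; without SOC the footprint equals the emissions total.
    """
    if ghg_total < 0:
        raise ValidationError(f"ghg_total must be >= 0, got {ghg_total}")
    return ghg_total - c_seqrate if include_soc else ghg_total


def cf_yield(cf_a: float, grain_yield: float) -> float:
    """Yield-scaled footprint, kg CO₂-eq per kg grain."""
    if grain_yield <= 0:
        raise ValidationError(f"yield must be > 0, got {grain_yield}")
    return cf_a / grain_yield


def cf_neeb(cf_a: float, neeb_value: float) -> float:
    """Income-scaled footprint, kg CO₂-eq per US$ of NEEB.

    A negative NEEB flips the ratio's sign; it is allowed with a
    warning because net budgets can be negative in bad years.
    """
    if neeb_value == 0:
        raise UndefinedRatioError("CF_NEEB undefined for NEEB = 0")
    if neeb_value < 0:
        logger.warning("negative NEEB %.2f flips the CF_NEEB sign", neeb_value)
    return cf_a / neeb_value


def season_footprint(
    crop: Crop | str,
    year: int,
    ghg_total: float,
    grain_yield: float,
    y_gain: float,
    a_cost: float,
    c_seqrate: float = 0.0,
    carbon_price: float = 17.0,
) -> FootprintResult:
    """All footprint scales and economics for one season.

    ``c_seqrate`` is the soil sequestration rate in kg CO₂-eq ha⁻¹
    (positive = sink); when unknown, pass 0 and read only the
    without-SOC outputs.
    """
    cost = carbon_cost(ghg_total, carbon_price)
    econ = neeb(y_gain, a_cost, cost)
    a_with = cf_area(ghg_total, c_seqrate, include_soc=True)
    a_without = cf_area(ghg_total, c_seqrate, include_soc=False)
    return FootprintResult(
        crop=Crop.coerce(crop),
        year=int(year),
        cf_a_with_soc=a_with,
        cf_a_without_soc=a_without,
        cf_y_with_soc=cf_yield(a_with, grain_yield),
        cf_y_without_soc=cf_yield(a_without, grain_yield),
        cf_neeb_with_soc=cf_neeb(a_with, econ.neeb),
        cf_neeb_without_soc=cf_neeb(a_without, econ.neeb),
        neeb=econ.neeb,
        c_cost=cost,
        c_seqrate=c_seqrate,
        grain_yield=grain_yield,
    )


def aggregate_seasons(
    results: Sequence[FootprintResult],
    mode: AggregationMode | str = AggregationMode.MEAN_OF_RATIOS,
) -> SeasonalAggregate:
    """Combine per-year footprints of one crop into multi-year means.

    Under ``mean_of_ratios`` the per-year CF_y and CF_NEEB ratios are
    averaged arithmetically; under ``ratio_of_means`` the mean CF_a is
    divided by the mean yield (resp. mean NEEB).  CF_a, GHG and NEEB
    means are plain column means under both modes.
    """
    if not results:
        raise InsufficientDataError("aggregate_seasons needs >= 1 season")
    mode = AggregationMode(mode)
    crops = {r.crop for r in results}
    if len(crops) != 1:
        raise ValidationError(f"aggregate one crop at a time, got {crops}")
    a_with = np.array([r.cf_a_with_soc for r in results])
    a_without = np.array([r.cf_a_without_soc for r in results])
    ghg = np.array([r.cf_a_without_soc for r in results])
    neeb_v = np.array([r.neeb for r in results])
    yields = np.array([r.grain_yield for r in results])
    if mode is AggregationMode.MEAN_OF_RATIOS:
        y_with = float(np.mean([r.cf_y_with_soc for r in results]))
        y_without = float(np.mean([r.cf_y_without_soc for r in results]))
        n_with = float(np.mean([r.cf_neeb_with_soc for r in results]))
        n_without = float(np.mean([r.cf_neeb_without_soc for r in results]))
    else:
        y_with = float(a_with.mean() / yields.mean())
        y_without = float(a_without.mean() / yields.mean())
        n_with = float(a_with.mean() / neeb_v.mean())
        n_without = float(a_without.mean() / neeb_v.mean())
    return SeasonalAggregate(
        crop=crops.pop(),
        n_years=len(results),
        aggregation_mode=mode,
        mean_cf_a_with_soc=float(a_with.mean()),
        mean_cf_a_without_soc=float(a_without.mean()),
        mean_cf_y_with_soc=y_with,
        mean_cf_y_without_soc=y_without,
        mean_cf_neeb_with_soc=n_with,
        mean_cf_neeb_without_soc=n_without,
        mean_ghg=float(ghg.mean()),
        mean_neeb=float(neeb_v.mean()),
    )
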