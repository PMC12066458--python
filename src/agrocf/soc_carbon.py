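"""Topsoil organic-carbon stock accounting.

Soil organic matter (SOM) converts to soil organic carbon (SOC) with
the standard van Bemmelen factor 0.58.  The area-basis carbon stock of
a soil layer is

    SCS [Mg C ha⁻¹] = SOC [g kg⁻¹] × BD [g cm⁻³] × H [m] × 10,

where the factor 10 converts kg m⁻² to Mg ha⁻¹.  The seasonal carbon
sequestration rate is the change in stock over one growing season
(harvest minus pre-season) converted to CO₂ equivalents with the 44/12
C→CO₂ mass ratio; a positive rate is a carbon sink, a negative rate a
source.  The long-term per-crop SOC rate is the least-squares slope of
the cumulative within-season SOC changes against calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import Crop
from .errors import InsufficientDataError, ValidationError
from .trend_stats import ols_trend

#: van Bemmelen conversion factor, g C per g organic matter.
SOM_TO_SOC = 0.58

#: Default topsoil bulk density, g cm⁻³ (site long-term average).
DEFAULT_BULK_DENSITY = 1.33

#: Default accounting layer thickness, m.
DEFAULT_DEPTH = 0.2

#: Exact C → CO₂ molar mass ratio.
C_TO_CO2 = 44.0 / 12.0


@dataclass(frozen=True)
class CarbonStock:
    """SOC stock of a soil layer: ``scs`` = soc × bd × depth × 10."""

    scs: float  # Mg C ha^-1
    soc: float  # g kg^-1
    bd: float   # g cm^-3
    depth: float  # m


@dataclass(frozen=True)
class SequestrationRate:
    """Seasonal carbon sequestration in CO₂ equivalents.

    ``c_seqrate_mg`` is in Mg CO₂-eq ha⁻¹ per season and
    ``c_seqrate_kg`` the same quantity × 1000 for use alongside the
    kg-basis GHG inventory.  Positive = sink, negative = loss.
    """

    c_seqrate_mg: float
    c_seqrate_kg: float


def som_to_soc(som: float) -> float:
    """Convert soil organic matter to organic carbon (g kg⁻¹ → g kg⁻¹)."""
    if som < 0:
        raise ValidationError(f"som must be >= 0, got {som}")
    return som * SOM_TO_SOC


def soc_storage(
    soc: float,
    bd: float = DEFAULT_BULK_DENSITY,
    depth: float = DEFAULT_DEPTH,
) -> CarbonStock:
    """SOC storage of a topsoil layer, Mg C ha⁻¹.

    Parameters are SOC concentration (g kg⁻¹), bulk density (g cm⁻³)
    and layer thickness (m).  Only topsoil layers (≤ 1 m) are accepted.
    """
    if soc < 0 or bd < 0 or depth < 0:
        raise ValidationError("soc, bd and depth must all be >= 0")
    if depth > 1.0:
        raise ValidationError(
            f"depth {depth} m exceeds the 1 m topsoil accounting limit"
        )
    return CarbonStock(scs=soc * bd * depth * 10.0, soc=soc, bd=bd, depth=depth)


def sequestration_rate(
    scs_harvest: float, scs_preseason: float
) -> SequestrationRate:
    """Seasonal C sequestration from stocks after and before the season.

    ``(scs_harvest − scs_preseason) × 44/12`` in Mg CO₂-eq ha⁻¹, also
    returned on the kg basis used by the footprint equations.
    """
    if scs_harvest < 0 or scs_preseason < 0:
        raise ValidationError("carbon stocks must be >= 0")
    mg = (scs_harvest - scs_preseason) * C_TO_CO2
    return SequestrationRate(c_seqrate_mg=mg, c_seqrate_kg=mg * 1000.0)


def seasonal_sequestration(
    soil: pd.DataFrame,
    bd: float | None = None,
    depth: float | None = None,
) -> pd.DataFrame:
    """Per-season sequestration rates from paired soil observations.

    ``soil`` must carry columns ``crop``, ``year``, ``phase``
    (``preseason``/``harvest``) and ``soc_value`` (g kg⁻¹), plus
    optional ``bd`` and ``depth`` columns used unless overridden by the
    ``bd``/``depth`` arguments.  Returns one row per (crop, year) with
    the pre-season and harvest SOC, the stock change and the
    sequestration rate in both unit bases.
    """
    rows = []
    for (crop, year), grp in soil.groupby(["crop", "year"], sort=True):
        phases = dict(zip(grp["phase"], grp.index))
        if "preseason" not in phases or "harvest" not in phases:
            raise ValidationError(
                f"season {crop} {year} needs both a preseason and a "
                "harvest observation"
            )
        pre = grp.loc[phases["preseason"]]
        post = grp.loc[phases["harvest"]]
        use_bd = bd if bd is not None else float(pre.get("bd", DEFAULT_BULK_DENSITY))
        use_depth = (
            depth if depth is not None else float(pre.get("depth", DEFAULT_DEPTH))
        )
        stock_pre = soc_storage(float(pre["soc_value"]), use_bd, use_depth)
        stock_post = soc_storage(float(post["soc_value"]), use_bd, use_depth)
        rate = sequestration_rate(stock_post.scs, stock_pre.scs)
        rows.append(
            {
                "crop": crop,
                "year": int(year),
                "soc_preseason": stock_pre.soc,
                "soc_harvest": stock_post.soc,
                "scs_preseason": stock_pre.scs,
                "scs_harvest": stock_post.scs,
                "c_seqrate_mg": rate.c_seqrate_mg,
                "c_seqrate_kg": rate.c_seqrate_kg,
            }
        )
    return pd.DataFrame(rows)


def soc_annual_rate(seasons: pd.DataFrame) -> dict[str, float]:
    """Long-term SOC rate per crop season, g kg⁻¹ yr⁻¹.

    ``seasons`` carries one row per (crop, year) with ``soc_preseason``
    and ``soc_harvest`` columns (as produced by
    :func:`seasonal_sequestration`).  For each crop the within-season
    SOC changes are accumulated over years and the ordinary
    least-squares slope of that cumulative series against calendar year
    is reported; with a constant yearly increment the slope equals the
    increment exactly.  Requires at least three seasons per crop.
    """
    rates: dict[str, float] = {}
    for crop, grp in seasons.groupby("crop", sort=True):
        grp = grp.sort_values("year")
        if len(grp) < 3:
            raise InsufficientDataError(
                f"need >= 3 seasons for crop {crop}, got {len(grp)}"
            )
        change = (grp["soc_harvest"] - grp["soc_preseason"]).to_numpy(float)
        cumulative = np.cumsum(change)
        trend = ols_trend(grp["year"].to_numpy(int), cumulative)
        rates[Crop.coerce(crop).value] = trend.slope
    return rates
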