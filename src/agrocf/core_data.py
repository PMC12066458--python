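"""Domain types and file readers/writers for rotation carbon accounting.

The central record types are:

* :class:`SeasonRecord` — one crop season's management inputs, production
  and economics (agricultural input quantities ``AI_i``, grain yield,
  grain income ``Y_gain`` and input cost ``A_cost``).
* :class:`EmissionFactorTable` — per-input embodied emission factors
  ``EF_i`` plus the N₂O pathway coefficients (direct fraction, the
  volatilization and leaching fractions and their emission factors),
  the N₂O global warming potential, and the carbon-trade price.
* :class:`SoilObservation` — a dated topsoil measurement of organic
  matter or organic carbon with bulk density and layer thickness.
* :class:`GHGBreakdown` — component-wise CO₂-eq emissions for a season.
* :class:`FootprintResult` — area-, yield- and income-scaled carbon
  footprints for a season, with and without the soil carbon change.

Season records and soil observations travel as plain CSV; emission
factors and run parameters travel as YAML or TOML configuration.  A
packaged fixture carries the 14 wheat and 15 maize seasons of printed
income / input-cost / GHG / NEEB values used by the verification mode.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The fixed vocabulary of per-hectare agricultural input categories.
#: Quantities are kg N, kg P, kg K, m³ water, kWh, L, kg seed and
#: kg active ingredient respectively.
INPUT_CATEGORIES: tuple[str, ...] = (
    "n_fertilizer",
    "p_fertilizer",
    "k_fertilizer",
    "irrigation",
    "electricity",
    "diesel",
    "seeds",
    "pesticides",
)

#: Default global warming potential of N₂O on the 100-year horizon
#: (CO₂ = 1).
DEFAULT_GWP_N2O = 265.0

#: Default carbon-trade price, US$ per metric ton CO₂-eq.
DEFAULT_CARBON_PRICE = 17.0


class Crop(str, Enum):
    """The two rotation crops: winter wheat and summer maize."""

    WHEAT = "wheat"
    MAIZE = "maize"

    @classmethod
    def coerce(cls, value: "Crop | str") -> "Crop":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown crop {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


def _require_nonnegative(name: str, value: float, context: str = "") -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"{name} is missing{context}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}{context}")


def _require_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SeasonRecord:
    """Management, production and economics of one crop season.

    Parameters
    ----------
    crop
        ``Crop.WHEAT`` or ``Crop.MAIZE``.
    year
        Calendar year of harvest.
    inputs
        Mapping of input category to applied quantity per hectare; see
        :data:`INPUT_CATEGORIES` for the units.  Missing categories are
        treated as zero.
    straw_returned
        Straw returned to the field, kg dry matter ha⁻¹.
    straw_n_content
        Nitrogen mass fraction of the returned straw (kg N per kg straw).
    grain_yield
        Grain yield, kg ha⁻¹.
    grain_income
        Grain income ``Y_gain``, US$ ha⁻¹.
    input_cost
        Total cost of agricultural inputs ``A_cost``, US$ ha⁻¹.
    """

    crop: Crop
    year: int
    inputs: Mapping[str, float] = field(default_factory=dict)
    straw_returned: float = 0.0
    straw_n_content: float = 0.0
    grain_yield: float = 0.0
    grain_income: float = 0.0
    input_cost: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "crop", Crop.coerce(self.crop))
        object.__setattr__(self, "inputs", dict(self.inputs))
        for cat, qty in self.inputs.items():
            _require_nonnegative(cat, qty)
        for name in ("straw_returned", "grain_yield", "grain_income", "input_cost"):
            _require_nonnegative(name, getattr(self, name))
        if not 0.0 <= self.straw_n_content <= 0.1:
            raise ValidationError(
                "straw_n_content must be in [0, 0.1] "
                f"(mass fraction), got {self.straw_n_content}"
            )

    def input_quantity(self, category: str) -> float:
        """Applied quantity for ``category``, zero when absent."""
        return float(self.inputs.get(category, 0.0))


@dataclass(frozen=True)
class EmissionFactorTable:
    """Emission factors and N₂O coefficients for the GHG inventory.

    ``ef`` maps each input category to its embodied emission factor in
    kg CO₂-eq per input unit.  The N₂O pathway coefficients follow the
    emission-factor convention: ``sigma1`` is the direct N₂O-N emission
    fraction of applied N; ``frac_vol``/``frac_leach`` are the fractions
    of applied N lost to NH₃ volatilization and to leaching, and
    ``sigma2``/``sigma3`` the N₂O-N emission fractions of those losses.
    """

    ef: Mapping[str, float] = field(default_factory=dict)
    sigma1: float = 0.01
    sigma2: float = 0.01
    sigma3: float = 0.0075
    frac_vol: float = 0.1
    frac_leach: float = 0.2
    gwp_n2o: float = DEFAULT_GWP_N2O
    carbon_price: float = DEFAULT_CARBON_PRICE

    def __post_init__(self) -> None:
        object.__setattr__(self, "ef", dict(self.ef))
        for cat, value in self.ef.items():
            _require_nonnegative(f"ef[{cat}]", value)
        for name in ("sigma1", "sigma2", "sigma3", "frac_vol", "frac_leach"):
            _require_fraction(name, getattr(self, name))
        if self.gwp_n2o <= 0:
            raise ValidationError(f"gwp_n2o must be > 0, got {self.gwp_n2o}")
        _require_nonnegative("carbon_price", self.carbon_price)

    def factor(self, category: str) -> float:
        """Emission factor for ``category``; zero (with a warning) when absent."""
        if category not in self.ef:
            logger.warning(
                "no emission factor for input category %r; using 0", category
            )
            return 0.0
        return float(self.ef[category])


#: Documented default embodied emission factors, kg CO₂-eq per input
#: unit.  These are order-of-magnitude defaults in the range of widely
#: used life-cycle inventories for Chinese cropping systems; site
#: studies should supply their own configuration.
DEFAULT_EMISSION_FACTORS: dict[str, float] = {
    "n_fertilizer": 8.3,    # per kg N (manufacture + transport)
    "p_fertilizer": 0.79,   # per kg P
    "k_fertilizer": 0.55,   # per kg K
    "irrigation": 0.0,      # water itself; pumping energy under electricity
    "electricity": 1.0,     # per kWh (coal-dominated grid)
    "diesel": 3.3,          # per L
    "seeds": 1.0,           # per kg seed
    "pesticides": 18.0,     # per kg active ingredient
}


def default_emission_factor_table() -> EmissionFactorTable:
    """The documented default :class:`EmissionFactorTable`."""
    return EmissionFactorTable(ef=dict(DEFAULT_EMISSION_FACTORS))


@dataclass(frozen=True)
class SoilObservation:
    """One dated topsoil observation.

    Exactly one of ``som`` (soil organic matter, g kg⁻¹) or ``soc``
    (soil organic carbon, g kg⁻¹) may be omitted; the other is derived
    with the standard 0.58 conversion when needed.
    """

    date: str
    som: float | None = None
    soc: float | None = None
    bd: float = 1.33
    depth: float = 0.2

    def __post_init__(self) -> None:
        if self.som is None and self.soc is None:
            raise ValidationError("one of som or soc is required")
        for name in ("som", "soc"):
            value = getattr(self, name)
            if value is not None:
                _require_nonnegative(name, value)
        if not 0.0 < self.bd < 2.5:
            raise ValidationError(f"bd must be in (0, 2.5) g cm^-3, got {self.bd}")
        if not 0.0 < self.depth <= 1.0:
            raise ValidationError(f"depth must be in (0, 1] m, got {self.depth}")

    @property
    def soc_value(self) -> float:
        """SOC in g kg⁻¹, converting from SOM (× 0.58) when necessary."""
        if self.soc is not None:
            return float(self.soc)
        return float(self.som) * 0.58


@dataclass(frozen=True)
class GHGBreakdown:
    """Component-wise CO₂-eq emissions for one season, kg CO₂-eq ha⁻¹.

    ``components`` maps component name (an input category or one of
    ``n2o_direct``, ``n2o_volatilization``, ``n2o_leaching``) to its
    emission; ``total`` is their exact sum.
    """

    components: Mapping[str, float]

    N2O_COMPONENTS = ("n2o_direct", "n2o_volatilization", "n2o_leaching")

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", dict(self.components))
        for name, value in self.components.items():
            _require_nonnegative(f"component {name}", value)

    @property
    def total(self) -> float:
        """Sum of all components, kg CO₂-eq ha⁻¹."""
        return float(sum(self.components.values()))

    @property
    def n2o_total(self) -> float:
        """Direct plus indirect N₂O emissions, kg CO₂-eq ha⁻¹."""
        return float(
            sum(self.components.get(k, 0.0) for k in self.N2O_COMPONENTS)
        )


@dataclass(frozen=True)
class FootprintResult:
    """Season-level carbon footprints on three scales plus economics.

    ``cf_a_*`` are per hectare (kg CO₂-eq ha⁻¹), ``cf_y_*`` per kg of
    grain, and ``cf_neeb_*`` per US$ of net ecosystem economic budget.
    Negative values denote a net carbon sink.
    """

    crop: Crop
    year: int
    cf_a_with_soc: float
    cf_a_without_soc: float
    cf_y_with_soc: float
    cf_y_without_soc: float
    cf_neeb_with_soc: float
    cf_neeb_without_soc: float
    neeb: float
    c_cost: float
    c_seqrate: float
    grain_yield: float = float("nan")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_MANDATORY_SEASON_COLUMNS = ("crop", "year", "yield", "grain_income", "input_cost")
_OPTIONAL_SEASON_COLUMNS = INPUT_CATEGORIES + ("straw_returned", "straw_n_content")


def _cell(row: pd.Series, name: str, default: float = 0.0) -> float:
    value = row.get(name, default)
    if value is None or pd.isna(value):
        return default
    return float(value)


def read_season_records(path: str | Path) -> list[SeasonRecord]:
    """Read season records from CSV, one row per crop-season.

    The header must name ``crop``, ``year``, ``yield``, ``grain_income``
    and ``input_cost``; input-category columns and the straw columns are
    optional and default to zero.  Unknown columns are ignored with a
    warning.  Records are returned sorted by (year, crop).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"season record file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _MANDATORY_SEASON_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    known = set(_MANDATORY_SEASON_COLUMNS) | set(_OPTIONAL_SEASON_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown columns %s in %s", unknown, path)

    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SeasonRecord(
                    crop=Crop.coerce(row["crop"]),
                    year=int(row["year"]),
                    inputs={
                        cat: float(row[cat])
                        for cat in INPUT_CATEGORIES
                        if cat in df.columns and pd.notna(row[cat])
                    },
                    straw_returned=_cell(row, "straw_returned"),
                    straw_n_content=_cell(row, "straw_n_content"),
                    grain_yield=float(row["yield"]),
                    grain_income=float(row["grain_income"]),
                    input_cost=float(row["input_cost"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i + 1} of {path}: {exc}") from exc
    records.sort(key=lambda r: (r.year, r.crop.value))
    return records


def write_season_records(records: list[SeasonRecord], path: str | Path) -> None:
    """Write season records to CSV with full float precision.

    Round-trips bit-identically through :func:`read_season_records`.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {"crop": r.crop.value, "year": r.year}
        for cat in INPUT_CATEGORIES:
            row[cat] = r.input_quantity(cat)
        row.update(
            straw_returned=r.straw_returned,
            straw_n_content=r.straw_n_content,
            **{"yield": r.grain_yield},
            grain_income=r.grain_income,
            input_cost=r.input_cost,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_soil_observations(path: str | Path) -> pd.DataFrame:
    """Read a soil-observation CSV into a validated DataFrame.

    Expected columns: ``crop``, ``year``, ``phase`` (``preseason`` or
    ``harvest``), ``date`` (optional), one of ``som``/``soc``, and
    optional ``bd`` (default 1.33 g cm⁻³) and ``depth`` (default 0.2 m).
    A derived ``soc_value`` column (g kg⁻¹) is always present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"soil observation file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("crop", "year", "phase"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    if "som" not in df.columns and "soc" not in df.columns:
        raise FormatError(f"need a som or soc column in {path}")
    if "bd" not in df.columns:
        df["bd"] = 1.33
    if "depth" not in df.columns:
        df["depth"] = 0.2
    bad_phase = ~df["phase"].isin(["preseason", "harvest"])
    if bad_phase.any():
        raise ValidationError(
            f"phase must be 'preseason' or 'harvest' in {path}, "
            f"first bad row {int(bad_phase.idxmax()) + 1}"
        )
    soc = df["soc"] if "soc" in df.columns else pd.Series(float("nan"), index=df.index)
    som = df["som"] if "som" in df.columns else pd.Series(float("nan"), index=df.index)
    df["soc_value"] = soc.where(soc.notna(), som * 0.58)
    if df["soc_value"].isna().any() or (df["soc_value"] < 0).any():
        raise ValidationError(f"missing or negative som/soc values in {path}")
    df["crop"] = df["crop"].map(lambda c: Crop.coerce(c).value)
    return df


# ---------------------------------------------------------------------------
# Emission-factor configuration
# ---------------------------------------------------------------------------

_EF_SCALAR_FIELDS = (
    "sigma1",
    "sigma2",
    "sigma3",
    "frac_vol",
    "frac_leach",
    "gwp_n2o",
    "carbon_price",
)


def read_emission_factors(path: str | Path) -> EmissionFactorTable:
    """Read an :class:`EmissionFactorTable` from a YAML or TOML config.

    The config holds an ``ef`` mapping (input category → kg CO₂-eq per
    unit) and the scalar coefficients; ``gwp_n2o`` defaults to 265 and
    ``carbon_price`` to US$ 17 per ton CO₂-eq when omitted.  Input
    categories without a factor default to 0 with a warning at use time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"emission factor config not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raise FormatError(
            f"unsupported emission factor config format {path.suffix!r} "
            "(use .yaml, .yml or .toml)"
        )
    if not isinstance(raw, dict):
        raise FormatError(f"emission factor config {path} must be a mapping")
    ef = {str(k): float(v) for k, v in (raw.get("ef") or {}).items()}
    missing = [c for c in INPUT_CATEGORIES if c not in ef]
    if missing:
        logger.warning(
            "emission factor config %s has no EF for %s; they default to 0",
            path,
            missing,
        )
    kwargs = {k: float(raw[k]) for k in _EF_SCALAR_FIELDS if k in raw}
    return EmissionFactorTable(ef=ef, **kwargs)


def write_emission_factors(table: EmissionFactorTable, path: str | Path) -> None:
    """Write an emission-factor table to YAML."""
    payload = {"ef": dict(table.ef)}
    payload.update({k: getattr(table, k) for k in _EF_SCALAR_FIELDS})
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 14-wheat / 15-maize season economics fixture.

    Returns a DataFrame with columns ``crop``, ``year``,
    ``grain_income`` (US$ ha⁻¹), ``input_cost`` (US$ ha⁻¹),
    ``ghg_total`` (kg CO₂-eq ha⁻¹) and ``neeb`` (US$ ha⁻¹) covering
    wheat seasons 2006–2017, 2019, 2020 and maize seasons 2005–2017,
    2019, 2020 (2018 is absent for both crops).
    """
    with resources.files("agrocf.data").joinpath("table1.csv").open("rb") as fh:
        return pd.read_csv(fh)
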