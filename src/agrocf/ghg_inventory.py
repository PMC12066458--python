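"""Seasonal greenhouse-gas inventory by the emission-factor method.

A season's total emissions (kg CO₂-eq ha⁻¹) are the embodied emissions
of every agricultural input (quantity × emission factor, summed over
categories) plus soil N₂O converted to CO₂ equivalents:

* direct N₂O: (F_synthetic + F_straw) × σ₁ × 44/28,
* N₂O after NH₃ volatilization: N × Frac_vol × σ₂ × 44/28,
* N₂O after leaching: N × Frac_leach × σ₃ × 44/28,

where N is the same applied-nitrogen pool (synthetic fertilizer N plus
straw-returned N), 44/28 converts N mass to N₂O mass exactly, and the
resulting N₂O is weighted by its 100-year global warming potential
(default 265).  CH₄ is excluded: dryland wheat–maize systems emit a
negligible amount.  All terms are linear in the inputs, so the total is
additive over any partition of the input categories and scales
proportionally with the quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .core_data import (
    EmissionFactorTable,
    GHGBreakdown,
    INPUT_CATEGORIES,
    SeasonRecord,
)
from .errors import UndefinedRatioError, ValidationError

#: Exact N → N₂O mass conversion (molar masses 44 and 28 g mol⁻¹).
N_TO_N2O = float(Fraction(44, 28))


@dataclass(frozen=True)
class NitrogenInput:
    """Applied nitrogen pool, kg N ha⁻¹: synthetic fertilizer plus straw."""

    f_synthetic: float = 0.0
    f_straw: float = 0.0

    def __post_init__(self) -> None:
        if self.f_synthetic < 0 or self.f_straw < 0:
            raise ValidationError("nitrogen inputs must be >= 0")

    @property
    def total(self) -> float:
        return self.f_synthetic + self.f_straw


def straw_n_input(straw_returned: float, straw_n_content: float) -> float:
    """Nitrogen returned with straw: amount × N mass fraction, kg N ha⁻¹."""
    if straw_returned < 0:
        raise ValidationError("straw_returned must be >= 0")
    if not 0.0 <= straw_n_content <= 0.1:
        raise ValidationError(
            f"straw_n_content must be in [0, 0.1], got {straw_n_content}"
        )
    return straw_returned * straw_n_content


def direct_n2o(n: NitrogenInput, sigma1: float) -> float:
    """Direct soil N₂O emission, kg N₂O ha⁻¹: N × σ₁ × 44/28."""
    if not 0.0 <= sigma1 <= 1.0:
        raise ValidationError(f"sigma1 must be in [0, 1], got {sigma1}")
    return n.total * sigma1 * N_TO_N2O


def indirect_n2o(
    n: NitrogenInput,
    frac_vol: float,
    sigma2: float,
    frac_leach: float,
    sigma3: float,
) -> dict[str, float]:
    """Indirect N₂O via volatilization and leaching, kg N₂O ha⁻¹ each."""
    for name, value in (
        ("frac_vol", frac_vol),
        ("sigma2", sigma2),
        ("frac_leach", frac_leach),
        ("sigma3", sigma3),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return {
        "n2o_vol": n.total * frac_vol * sigma2 * N_TO_N2O,
        "n2o_leach": n.total * frac_leach * sigma3 * N_TO_N2O,
    }


def n2o_to_co2eq(n2o_direct: float, n2o_indirect: float, gwp: float) -> float:
    """Convert N₂O mass to CO₂ equivalents: (direct + indirect) × GWP."""
    if gwp <= 0:
        raise ValidationError(f"gwp must be > 0, got {gwp}")
    return (n2o_direct + n2o_indirect) * gwp


def input_embodied(
    record: SeasonRecord, ef: EmissionFactorTable
) -> dict[str, float]:
    """Embodied emissions per input category, kg CO₂-eq ha⁻¹.

    Categories present in the record but absent from the factor table
    contribute zero (with a warning from the table lookup); factor-table
    categories not applied in the record contribute nothing.
    """
    categories = list(INPUT_CATEGORIES) + [
        c for c in record.inputs if c not in INPUT_CATEGORIES
    ]
    return {c: record.input_quantity(c) * ef.factor(c) for c in categories}


def total_ghg(record: SeasonRecord, ef: EmissionFactorTable) -> GHGBreakdown:
    """Full seasonal GHG breakdown: embodied inputs plus N₂O pathways."""
    components = input_embodied(record, ef)
    n = NitrogenInput(
        f_synthetic=record.input_quantity("n_fertilizer"),
        f_straw=straw_n_input(record.straw_returned, record.straw_n_content),
    )
    d = direct_n2o(n, ef.sigma1)
    ind = indirect_n2o(n, ef.frac_vol, ef.sigma2, ef.frac_leach, ef.sigma3)
    components["n2o_direct"] = n2o_to_co2eq(d, 0.0, ef.gwp_n2o)
    components["n2o_volatilization"] = n2o_to_co2eq(ind["n2o_vol"], 0.0, ef.gwp_n2o)
    components["n2o_leaching"] = n2o_to_co2eq(ind["n2o_leach"], 0.0, ef.gwp_n2o)
    return GHGBreakdown(components=components)


def component_shares(breakdown: GHGBreakdown) -> dict[str, float]:
    """Percent share of each component in the total (sums to 100)."""
    total = breakdown.total
    if total <= 0:
        raise UndefinedRatioError("component shares undefined for total <= 0")
    return {name: value / total * 100.0 for name, value in breakdown.components.items()}
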