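"""Emission-factor GHG inventory: embodied inputs plus N2O pathways."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from agrocf import (
    Crop,
    EmissionFactorTable,
    NitrogenInput,
    SeasonRecord,
    UndefinedRatioError,
    ValidationError,
    component_shares,
    direct_n2o,
    indirect_n2o,
    input_embodied,
    n2o_to_co2eq,
    straw_n_input,
    total_ghg,
)

# the worked single-input season: 200 kg N, EF 8.3, IPCC-style N2O set
N_ONLY_RECORD = SeasonRecord(
    crop=Crop.WHEAT, year=2010, inputs={"n_fertilizer": 200.0}, grain_yield=6000.0
)
N_ONLY_EF = EmissionFactorTable(
    ef={"n_fertilizer": 8.3},
    sigma1=0.01,
    sigma2=0.01,
    sigma3=0.0075,
    frac_vol=0.1,
    frac_leach=0.2,
    gwp_n2o=265.0,
)


class TestStrawN:
    @pytest.mark.parametrize(
        "straw, frac, expected", [(0.0, 0.006, 0.0), (5000.0, 0.006, 30.0),
                                  (8000.0, 0.011, 88.0)]
    )
    def test_product(self, straw, frac, expected):
        assert straw_n_input(straw, frac) == pytest.approx(expected)

    def test_implausible_n_content_rejected(self):
        with pytest.raises(ValidationError):
            straw_n_input(5000.0, 0.2)


class TestN2OPathways:
    def test_zero_nitrogen_emits_nothing(self):
        n = NitrogenInput()
        assert direct_n2o(n, 0.01) == 0.0
        assert indirect_n2o(n, 0.1, 0.01, 0.2, 0.0075) == {
            "n2o_vol": 0.0,
            "n2o_leach": 0.0,
        }

    @pytest.mark.parametrize(
        "f_syn, f_straw, expected",
        [(200.0, 50.0, 3.9286), (100.0, 0.0, 1.5714)],
    )
    def test_direct(self, f_syn, f_straw, expected):
        n = NitrogenInput(f_synthetic=f_syn, f_straw=f_straw)
        assert direct_n2o(n, 0.01) == pytest.approx(expected, abs=5e-5)

    def test_indirect_components(self):
        n = NitrogenInput(f_synthetic=250.0)
        out = indirect_n2o(n, frac_vol=0.1, sigma2=0.01, frac_leach=0.2,
                           sigma3=0.0075)
        assert out["n2o_vol"] == pytest.approx(0.3929, abs=5e-5)
        assert out["n2o_leach"] == pytest.approx(0.5893, abs=5e-5)

    @pytest.mark.parametrize(
        "direct, indirect, expected",
        [(0.0, 0.0, 0.0), (1.0, 0.0, 265.0), (3.9286, 0.9821, 1301.3)],
    )
    def test_co2eq_conversion(self, direct, indirect, expected):
        assert n2o_to_co2eq(direct, indirect, 265.0) == pytest.approx(
            expected, abs=0.1
        )

    def test_sigma_out_of_range(self):
        with pytest.raises(ValidationError):
            direct_n2o(NitrogenInput(f_synthetic=100.0), 1.5)


class TestInventory:
    def test_zero_record_is_zero(self, ef_table):
        rec = SeasonRecord(crop=Crop.MAIZE, year=2005, grain_yield=1.0)
        assert total_ghg(rec, ef_table).total == 0.0

    def test_embodied_per_category(self):
        rec = SeasonRecord(
            crop=Crop.WHEAT, year=2010,
            inputs={"electricity": 100.0, "diesel": 50.0}, grain_yield=1.0,
        )
        ef = EmissionFactorTable(ef={"electricity": 1.0, "diesel": 2.0})
        parts = input_embodied(rec, ef)
        assert parts["electricity"] == 100.0
        assert parts["diesel"] == 100.0
        assert sum(parts.values()) == 200.0

    def test_worked_n_fertilizer_season(self):
        # 1660 embodied + 265 x (2 + 0.2 + 0.3) x 44/28 = 2701.07
        breakdown = total_ghg(N_ONLY_RECORD, N_ONLY_EF)
        assert breakdown.components["n_fertilizer"] == pytest.approx(1660.0)
        assert breakdown.n2o_total == pytest.approx(1041.07, abs=0.01)
        assert breakdown.total == pytest.approx(2701.07, abs=0.01)

    def test_extra_registry_category_used_only_if_present(self):
        rec = SeasonRecord(
            crop=Crop.WHEAT, year=2010, inputs={"plastic_film": 10.0},
            grain_yield=1.0,
        )
        ef = EmissionFactorTable(ef={"plastic_film": 2.5, "lime": 100.0})
        parts = input_embodied(rec, ef)
        assert parts["plastic_film"] == 25.0
        assert "lime" not in parts


class TestComponentShares:
    def test_single_component_is_100(self):
        from agrocf import GHGBreakdown

        shares = component_shares(GHGBreakdown(components={"seeds": 42.0}))
        assert shares["seeds"] == pytest.approx(100.0)

    def test_proportional_split(self):
        from agrocf import GHGBreakdown

        shares = component_shares(GHGBreakdown(components={"a": 75.0, "b": 25.0}))
        assert shares == {"a": pytest.approx(75.0), "b": pytest.approx(25.0)}

    def test_worked_record_fertilizer_share(self):
        shares = component_shares(total_ghg(N_ONLY_RECORD, N_ONLY_EF))
        assert shares["n_fertilizer"] == pytest.approx(61.5, abs=0.05)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_undefined(self):
        from agrocf import GHGBreakdown

        with pytest.raises(UndefinedRatioError):
            component_shares(GHGBreakdown(components={"a": 0.0}))


quantities = st.dictionaries(
    st.sampled_from(["n_fertilizer", "electricity", "diesel", "seeds"]),
    st.floats(0.0, 1e4, allow_nan=False),
    max_size=4,
)


class TestInventoryProperties:
    @given(inputs=quantities, scale=st.floats(0.0, 10.0, allow_nan=False))
    def test_linearity_in_all_inputs(self, ef_table, inputs, scale):
        base = SeasonRecord(
            crop=Crop.WHEAT, year=2010, inputs=inputs, straw_returned=1000.0,
            straw_n_content=0.006, grain_yield=1.0,
        )
        scaled = SeasonRecord(
            crop=Crop.WHEAT, year=2010,
            inputs={k: v * scale for k, v in inputs.items()},
            straw_returned=1000.0 * scale, straw_n_content=0.006, grain_yield=1.0,
        )
        assert total_ghg(scaled, ef_table).total == pytest.approx(
            scale * total_ghg(base, ef_table).total, rel=1e-9, abs=1e-9
        )

    @given(inputs=quantities, bump=st.floats(0.0, 100.0, allow_nan=False))
    def test_monotone_in_each_quantity(self, ef_table, inputs, bump):
        base = SeasonRecord(
            crop=Crop.WHEAT, year=2010, inputs=inputs, grain_yield=1.0
        )
        bumped_inputs = dict(inputs)
        bumped_inputs["n_fertilizer"] = bumped_inputs.get("n_fertilizer", 0.0) + bump
        bumped = SeasonRecord(
            crop=Crop.WHEAT, year=2010, inputs=bumped_inputs, grain_yield=1.0
        )
        assert total_ghg(bumped, ef_table).total >= total_ghg(base, ef_table).total

    @given(inputs=quantities)
    def test_additive_over_category_partition(self, ef_table, inputs):
        """Splitting the non-N categories across two records conserves the
        total, with the single N2O term carried by the N-bearing half."""
        full = SeasonRecord(
            crop=Crop.WHEAT, year=2010, inputs=inputs, grain_yield=1.0
        )
        n_part = {k: v for k, v in inputs.items() if k == "n_fertilizer"}
        rest = {k: v for k, v in inputs.items() if k != "n_fertilizer"}
        rec_n = SeasonRecord(crop=Crop.WHEAT, year=2010, inputs=n_part,
                             grain_yield=1.0)
        rec_rest = SeasonRecord(crop=Crop.WHEAT, year=2010, inputs=rest,
                                grain_yield=1.0)
        left = total_ghg(full, ef_table).total
        right = (
            total_ghg(rec_n, ef_table).total
            + sum(input_embodied(rec_rest, ef_table).values())
        )
        assert left == pytest.approx(right, rel=1e-12, abs=1e-9)
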