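"""Domain types, CSV/config IO, and the packaged season-economics fixture."""

import math

import pytest

import agrocf
from agrocf import (
    Crop,
    EmissionFactorTable,
    FormatError,
    GHGBreakdown,
    SeasonRecord,
    SoilObservation,
    ValidationError,
    read_emission_factors,
    read_season_records,
    read_soil_observations,
    write_season_records,
)

WHEAT_2006 = dict(
    crop="wheat",
    year=2006,
    n_fertilizer=300.0,
    p_fertilizer=60.0,
    k_fertilizer=75.0,
    irrigation=1800.0,
    electricity=500.0,
    diesel=70.0,
    seeds=150.0,
    pesticides=3.0,
    straw_returned=5000.0,
    straw_n_content=0.011,
    grain_income=1125.0,
    input_cost=556.0,
    **{"yield": 6000.0},
)


class TestSeasonRecordIO:
    def test_single_row_parses(self, season_csv):
        records = read_season_records(season_csv([WHEAT_2006]))
        assert len(records) == 1
        rec = records[0]
        assert rec.crop is Crop.WHEAT
        assert rec.year == 2006
        assert rec.grain_yield == 6000.0
        assert rec.input_quantity("n_fertilizer") == 300.0
        assert rec.input_quantity("not_a_category") == 0.0

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("crop,year,yield,grain_income,input_cost\n")
        assert read_season_records(path) == []

    def test_negative_quantity_cites_row(self, season_csv):
        row = dict(WHEAT_2006, n_fertilizer=-5.0)
        with pytest.raises(ValidationError, match="row 1"):
            read_season_records(season_csv([row]))

    def test_missing_mandatory_column_named(self, season_csv):
        row = {k: v for k, v in WHEAT_2006.items() if k != "grain_income"}
        with pytest.raises(FormatError, match="grain_income"):
            read_season_records(season_csv([row]))

    def test_unknown_column_ignored_with_warning(self, season_csv, caplog):
        row = dict(WHEAT_2006, mystery_column=42)
        with caplog.at_level("WARNING"):
            records = read_season_records(season_csv([row]))
        assert len(records) == 1
        assert "mystery_column" in caplog.text

    def test_roundtrip_is_bit_identical(self, tmp_path):
        records = [
            SeasonRecord(
                crop=Crop.MAIZE,
                year=2011,
                inputs={"n_fertilizer": 120.123456789012345, "diesel": 40.0},
                straw_returned=6173.9999999999,
                straw_n_content=0.0061,
                grain_yield=8403.3333333333,
                grain_income=2268.9000000001,
                input_cost=481.0,
            ),
            SeasonRecord(crop=Crop.WHEAT, year=2011, grain_yield=7120.0),
        ]
        path = tmp_path / "rt.csv"
        write_season_records(records, path)
        back = read_season_records(path)
        originals = sorted(records, key=lambda r: (r.year, r.crop.value))
        assert len(back) == len(originals)
        for got, want in zip(back, originals):
            assert (got.crop, got.year) == (want.crop, want.year)
            for cat in agrocf.core_data.INPUT_CATEGORIES:
                assert got.input_quantity(cat) == want.input_quantity(cat)
            for name in ("straw_returned", "straw_n_content", "grain_yield",
                         "grain_income", "input_cost"):
                assert getattr(got, name) == getattr(want, name)

    def test_sorted_by_year_then_crop(self, season_csv):
        rows = [
            dict(WHEAT_2006, year=2010),
            dict(WHEAT_2006, crop="maize", year=2008),
            dict(WHEAT_2006, year=2008),
        ]
        records = read_season_records(season_csv(rows))
        assert [(r.year, r.crop.value) for r in records] == [
            (2008, "maize"),
            (2008, "wheat"),
            (2010, "wheat"),
        ]


class TestSeasonRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"crop": "rice"},
            {"straw_n_content": 0.2},
            {"grain_yield": -1.0},
            {"inputs": {"irrigation": -10.0}},
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(crop="wheat", year=2006, grain_yield=6000.0)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            SeasonRecord(**base)


class TestEmissionFactorConfig:
    def test_yaml_defaults_gwp_and_price(self, tmp_path):
        path = tmp_path / "ef.yaml"
        path.write_text(
            "ef:\n  n_fertilizer: 8.3\n"
            "sigma1: 0.01\nsigma2: 0.01\nsigma3: 0.0075\n"
            "frac_vol: 0.1\nfrac_leach: 0.2\n"
        )
        table = read_emission_factors(path)
        assert table.gwp_n2o == 265
        assert table.carbon_price == 17
        assert table.factor("n_fertilizer") == 8.3

    def test_toml_roundtrip_of_scalars(self, tmp_path):
        path = tmp_path / "ef.toml"
        path.write_text(
            'sigma1 = 0.012\ncarbon_price = 25.0\n[ef]\nn_fertilizer = 7.0\n'
        )
        table = read_emission_factors(path)
        assert table.sigma1 == 0.012
        assert table.carbon_price == 25.0
        assert table.gwp_n2o == 265

    def test_fraction_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "ef.yaml"
        path.write_text("frac_vol: 1.2\n")
        with pytest.raises(ValidationError):
            read_emission_factors(path)

    def test_missing_category_defaults_to_zero(self, caplog):
        table = EmissionFactorTable(ef={"n_fertilizer": 8.3})
        with caplog.at_level("WARNING"):
            assert table.factor("diesel") == 0.0
        assert "diesel" in caplog.text

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_emission_factors(tmp_path / "nope.yaml")


class TestSoilObservation:
    def test_soc_derived_from_som(self):
        obs = SoilObservation(date="2003-11-01", som=12.06)
        assert obs.soc_value == pytest.approx(6.9948)

    def test_soc_takes_precedence_when_given(self):
        obs = SoilObservation(date="2003-11-01", som=12.06, soc=8.0)
        assert obs.soc_value == 8.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {},  # neither som nor soc
            {"soc": 10.0, "bd": 3.0},
            {"soc": 10.0, "depth": 1.5},
            {"som": -1.0},
        ],
    )
    def test_invalid_observations(self, kwargs):
        with pytest.raises(ValidationError):
            SoilObservation(date="2003-11-01", **kwargs)

    def test_csv_reader_fills_defaults(self, season_csv):
        path = season_csv(
            [
                {"crop": "wheat", "year": 2003, "phase": "preseason", "som": 12.06},
                {"crop": "wheat", "year": 2003, "phase": "harvest", "som": 13.06},
            ],
            name="soil.csv",
        )
        df = read_soil_observations(path)
        assert (df["bd"] == 1.33).all()
        assert (df["depth"] == 0.2).all()
        assert df["soc_value"].tolist() == pytest.approx([6.9948, 7.5748])


class TestGHGBreakdown:
    def test_total_is_exact_component_sum(self):
        bd = GHGBreakdown(components={"a": 1.25, "b": 2.5, "n2o_direct": 0.25})
        assert bd.total == 4.0
        assert bd.n2o_total == 0.25

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            GHGBreakdown(components={"a": -1.0})


class TestTable1Fixture:
    def test_row_counts(self, table1):
        counts = table1.groupby("crop").size()
        assert counts["wheat"] == 14
        assert counts["maize"] == 15

    def test_spot_rows(self, table1):
        w2006 = table1.query("crop == 'wheat' and year == 2006").iloc[0]
        assert tuple(w2006[["grain_income", "input_cost", "ghg_total", "neeb"]]) == (
            1125,
            556,
            7978,
            433,
        )
        m2005 = table1.query("crop == 'maize' and year == 2005").iloc[0]
        assert tuple(m2005[["grain_income", "input_cost", "ghg_total", "neeb"]]) == (
            743,
            229,
            2986,
            463,
        )

    def test_2018_absent_for_both_crops(self, table1):
        assert not (table1["year"] == 2018).any()

    def test_column_means_match_printed_average_row(self, table1):
        expected = {
            "wheat": (2183, 814, 7307, 1244),
            "maize": (2368, 576, 2999, 1741),
        }
        for crop, (income, cost, ghg, neeb) in expected.items():
            means = table1[table1["crop"] == crop][
                ["grain_income", "input_cost", "ghg_total", "neeb"]
            ].mean()
            assert [agrocf.round_half_up(m) for m in means] == [
                income,
                cost,
                ghg,
                neeb,
            ]
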