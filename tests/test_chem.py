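"""Unit conversions, hardness, charge balance and guideline screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hydroqual.chem import (
    ION_REGISTRY,
    StandardsTable,
    WaterSample,
    charge_balance_error,
    mg_to_meq,
    read_samples,
    round_half_up,
    screen,
    total_hardness,
)


class TestMeqConversion:
    @pytest.mark.parametrize(
        "ion, conc, expected, tol",
        [
            ("Ca", 40.08, 2.000, 1e-3),  # one mmol of a divalent ion
            ("Ca", 0.0, 0.0, 0.0),
            ("HCO3", 235.0, 3.852, 1e-3),
            ("Mg", 24.305, 2.0, 1e-12),
        ],
    )
    def test_known_conversions(self, ion, conc, expected, tol):
        assert mg_to_meq(conc, ion) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_unknown_ion_is_configuration_error(self):
        with pytest.raises(KeyError):
            mg_to_meq(1.0, "Fe")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mg_to_meq(-1.0, "Ca")

    @given(
        a=st.floats(0, 1e4, allow_nan=False),
        b=st.floats(0, 1e4, allow_nan=False),
        ion=st.sampled_from(sorted(ION_REGISTRY)),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, a, b, ion):
        assert mg_to_meq(a + b, ion) == pytest.approx(
            mg_to_meq(a, ion) + mg_to_meq(b, ion), rel=1e-9, abs=1e-12
        )
        assert mg_to_meq(0.0, ion) == 0.0


class TestTotalHardness:
    @pytest.mark.parametrize(
        "ca, mg, expected",
        [(0, 0, 0.0), (100, 0, 249.7), (0, 100, 411.5), (82.78, 37.15, 359.6)],
    )
    def test_formula(self, ca, mg, expected):
        assert total_hardness(ca, mg) == pytest.approx(expected, abs=0.05)

    @given(
        ca=st.floats(0, 500), mg=st.floats(0, 500), dca=st.floats(0, 50), dmg=st.floats(0, 50)
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_nondecreasing(self, ca, mg, dca, dmg):
        assert total_hardness(ca + dca, mg + dmg) >= total_hardness(ca, mg)


class TestChargeBalance:
    def test_balanced_sample_is_zero(self):
        # 1 meq/L of every side: Na 22.990 mg/L vs Cl 35.453 mg/L
        assert charge_balance_error({"Na": 22.990, "Cl": 35.453}) == pytest.approx(0.0, abs=1e-9)

    def test_cations_only_is_plus_100(self):
        assert charge_balance_error({"Ca": 40.078}) == pytest.approx(100.0)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            charge_balance_error({"Ca": 0.0, "Cl": 0.0})

    def test_survey_mean_composition_matches_spreadsheet_oracle(self):
        # wet-season mean major-ion composition; oracle computed with
        # independent hand constants (conc / molar mass * |z|)
        sample = {
            "Ca": 82.78, "Mg": 37.15, "Na": 32.41, "K": 1.09,
            "HCO3": 235.0, "Cl": 29.89, "SO4": 32.67, "NO3": 35.70,
        }
        cat = 82.78 / 40.078 * 2 + 37.15 / 24.305 * 2 + 32.41 / 22.990 + 1.09 / 39.098
        an = 235.0 / 61.016 + 29.89 / 35.453 + 32.67 / 96.06 * 2 + 35.70 / 62.004
        expected = 100.0 * (cat - an) / (cat + an)
        assert charge_balance_error(sample) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(18.35, abs=0.05)

    @given(
        data=st.dictionaries(
            st.sampled_from(["Ca", "Mg", "Na", "K", "HCO3", "Cl", "SO4", "NO3"]),
            st.floats(0.01, 1e3),
            min_size=1,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_between_minus_and_plus_100(self, data):
        cbe = charge_balance_error(data)
        assert -100.0 <= cbe <= 100.0


class TestScreening:
    def test_nitrate_above_50_flagged(self, toy_df):
        df = toy_df.copy()
        df.loc[0, "NO3"] = 61.0
        rep = screen(df)
        assert "NO3" in rep.exceedances(df.loc[0, "well_id"], "wet")

    def test_values_exactly_at_limit_pass(self):
        std = StandardsTable.who_defaults()
        df = pd.DataFrame(
            [{
                "well_id": "w", "season": "wet", "x": 0, "y": 0,
                "pH": 8.5, "EC": 1500.0, "TDS": 1000.0, "TH": 500.0,
                "BOD": 5.0, "COD": 20.0, "Ca": 200.0, "Mg": 150.0,
                "Na": 200.0, "K": 12.0, "HCO3": 500.0, "Cl": 250.0,
                "SO4": 250.0, "NO3": 50.0,
            }]
        )
        rep = screen(df, std)
        assert rep.exceedances("w", "wet") == []

    def test_raising_one_parameter_adds_exactly_it(self):
        base = {
            "well_id": "w", "season": "wet", "x": 0, "y": 0,
            "pH": 7.5, "EC": 1500.0, "TDS": 1000.0, "TH": 500.0,
            "BOD": 5.0, "COD": 20.0, "Ca": 200.0, "Mg": 150.0,
            "Na": 200.0, "K": 12.0, "HCO3": 500.0, "Cl": 250.0,
            "SO4": 250.0, "NO3": 50.0,
        }
        bumped = dict(base, NO3=50.0 + 1e-6)
        rep = screen(pd.DataFrame([bumped]))
        assert rep.exceedances("w", "wet") == ["NO3"]

    def test_ph_outside_band_counts_as_exceedance(self):
        rec = {
            "well_id": "w", "season": "dry", "x": 0, "y": 0,
            "pH": 6.0, "EC": 400.0, "TDS": 300.0, "TH": 200.0,
            "BOD": 4.0, "COD": 10.0, "Ca": 50.0, "Mg": 20.0,
            "Na": 20.0, "K": 1.0, "HCO3": 150.0, "Cl": 20.0,
            "SO4": 20.0, "NO3": 10.0,
        }
        rep = screen(pd.DataFrame([rec]))
        assert rep.exceedances("w", "dry") == ["pH"]

    def test_missing_values_reported_not_silently_passed(self, toy_df):
        df = toy_df.copy()
        df.loc[1, "NO3"] = np.nan
        rep = screen(df)
        flags = rep.flags
        row = flags[
            (flags.well_id == df.loc[1, "well_id"]) & (flags.parameter == "NO3")
        ].iloc[0]
        assert row["status"] == "not screened"

    def test_seven_of_27_gives_25_93_percent(self, survey_df):
        rep = screen(survey_df[survey_df.season == "wet"])
        row = rep.summary[(rep.summary.parameter == "NO3")].iloc[0]
        assert row["n"] == 27 and row["n_exceed"] == 7
        assert 25.92 <= row["pct_exceed"] <= 25.93


class TestWaterSampleValidation:
    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            WaterSample(
                well_id="w", season="wet", x=0, y=0, pH=7, EC=1, TDS=1, BOD=1,
                COD=1, Ca=-1, Mg=1, Na=1, K=1, HCO3=1, Cl=1, SO4=1, NO3=1,
            )

    def test_rejects_bad_season_and_ph(self):
        kwargs = dict(
            well_id="w", x=0, y=0, pH=7, EC=1, TDS=1, BOD=1,
            COD=1, Ca=1, Mg=1, Na=1, K=1, HCO3=1, Cl=1, SO4=1, NO3=1,
        )
        with pytest.raises(ValueError):
            WaterSample(season="monsoon", **kwargs)
        with pytest.raises(ValueError):
            WaterSample(season="wet", **{**kwargs, "pH": 15.0})

    def test_th_computed_when_missing(self):
        s = WaterSample(
            well_id="w", season="wet", x=0, y=0, pH=7, EC=1, TDS=1, BOD=1,
            COD=1, Ca=100.0, Mg=0.0, Na=1, K=1, HCO3=1, Cl=1, SO4=1, NO3=1,
        )
        assert s.th == pytest.approx(249.7)


def test_read_samples_roundtrip(tmp_path, survey_df):
    path = tmp_path / "samples.csv"
    survey_df.to_csv(path, index=False)
    df = read_samples(path)
    assert len(df) == len(survey_df)
    assert set(df.season) == {"wet", "dry"}


def test_round_half_up_matches_report_convention():
    assert round_half_up(25.925925) == 25.93
    assert round_half_up(88.885) == 88.89
    assert round_half_up(1.005) == 1.01
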