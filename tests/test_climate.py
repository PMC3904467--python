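import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aridforest import climate, synth


def _make_table(records):
    return pd.DataFrame(records, columns=["station", "year", "month", "T", "P"])


def _thornthwaite_oracle(monthly_t, latitude=None):
    """Independent month-by-month transcription of the published
    Thornthwaite equations (unadjusted when latitude is None)."""
    heat = sum((t / 5.0) ** 1.514 for t in monthly_t if t > 0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    out = []
    month_days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    doy = 0
    for m, t in enumerate(monthly_t):
        if t <= 0:
            pet = 0.0
        elif t <= 26.5:
            pet = 16.0 * (10.0 * t / heat) ** a
        else:
            pet = -415.85 + 32.24 * t - 0.43 * t * t
        if latitude is not None:
            mid = doy + month_days[m] / 2
            decl = 0.409 * math.sin(2 * math.pi * mid / 365 - 1.39)
            cos_w = -math.tan(math.radians(latitude)) * math.tan(decl)
            w = math.acos(max(-1.0, min(1.0, cos_w)))
            daylight = 24.0 / math.pi * w
            pet *= (daylight / 12.0) * (month_days[m] / 30.0)
        out.append(pet)
        doy += month_days[m]
    return out


class TestStationRegression:
    def test_exact_linear_relation_recovered(self):
        rows = [("a", 2000, m, 2 * m + 5, 10.0 * m) for m in range(1, 13)]
        rows += [("b", 2000, m, float(m), 5.0 * m) for m in range(1, 13)]
        reg = climate.fit_station_regression(_make_table(rows), "a", "b", "T")
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(5.0)
        assert reg.r == pytest.approx(1.0)
        assert reg.n_overlap == 12

    def test_constant_target_convention(self):
        rows = [("a", 2000, m, 7.0, 0.0) for m in range(1, 13)]
        rows += [("b", 2000, m, float(m), 0.0) for m in range(1, 13)]
        reg = climate.fit_station_regression(_make_table(rows), "a", "b", "T")
        assert reg.slope == 0.0 and reg.intercept == 7.0 and reg.r == 0.0

    def test_zero_predictor_variance_errors(self):
        rows = [("a", 2000, m, float(m), 0.0) for m in range(1, 13)]
        rows += [("b", 2000, m, 3.0, 0.0) for m in range(1, 13)]
        with pytest.raises(ValueError, match="variance"):
            climate.fit_station_regression(_make_table(rows), "a", "b", "T")

    def test_insufficient_overlap_errors(self):
        rows = [("a", 2000, 1, 1.0, 0.0), ("b", 2000, 2, 2.0, 0.0)]
        with pytest.raises(ValueError, match="overlap"):
            climate.fit_station_regression(_make_table(rows), "a", "b", "T")

    def test_noisy_slope_recovered_within_three_se(self):
        # generating slope 1.1, intercept −3, noise sd 5 over 588 months
        spec = synth.ClimateSimSpec(noise_sd_p=5.0, gap_fraction=0.0, seed=17)
        sim = synth.simulate_climate(spec)
        reg = climate.fit_station_regression(sim.table, "st1", "st0", "P")
        wide = sim.table.pivot_table(index=["year", "month"], columns="station", values="P")
        oracle = stats.linregress(wide["st0"], wide["st1"])
        assert reg.slope == pytest.approx(oracle.slope)
        assert abs(reg.slope - 1.1) < 3 * oracle.stderr
        assert reg.n_overlap == 588


class TestFillGaps:
    def test_table_without_gaps_unchanged(self, noise_free_climate):
        _, sim = noise_free_climate
        out = climate.fill_gaps(sim.table, [])
        pd.testing.assert_frame_equal(
            out[["station", "year", "month", "T", "P"]], sim.table
        )
        assert not out["T_filled"].any() and not out["P_filled"].any()

    def test_noise_free_fill_is_exact(self):
        spec = synth.ClimateSimSpec(
            noise_sd_t=0.0, noise_sd_p=0.0, intercepts_p=(4.0, 5.0),
            gap_fraction=0.1, seed=21,
        )
        sim = synth.simulate_climate(spec)
        regs = [
            climate.fit_station_regression(sim.table, st, "st0", var)
            for st in ("st1", "st2")
            for var in ("T", "P")
        ]
        filled = climate.fill_gaps(sim.table, regs)
        for _, true_row in sim.removed.iterrows():
            got = filled[
                (filled["station"] == true_row["station"])
                & (filled["year"] == true_row["year"])
                & (filled["month"] == true_row["month"])
            ].iloc[0]
            assert got["T"] == pytest.approx(true_row["T"], abs=1e-8)
            assert got["P"] == pytest.approx(true_row["P"], abs=1e-8)
            assert got["T_filled"] and got["P_filled"]

    def test_observed_values_never_altered(self, climate_sim):
        table = climate_sim.table
        regs = [
            climate.fit_station_regression(table, st, "st0", var)
            for st in ("st1", "st2")
            for var in ("T", "P")
        ]
        filled = climate.fill_gaps(table, regs)
        observed = table["P"].notna()
        np.testing.assert_array_equal(
            filled.loc[observed, "P"].to_numpy(), table.loc[observed, "P"].to_numpy()
        )
        observed_t = table["T"].notna()
        np.testing.assert_array_equal(
            filled.loc[observed_t, "T"].to_numpy(), table.loc[observed_t, "T"].to_numpy()
        )

    def test_noisy_fill_error_bounded_by_twice_noise_sd(self):
        spec = synth.ClimateSimSpec(gap_fraction=0.1, seed=13)
        sim = synth.simulate_climate(spec)
        regs = [
            climate.fit_station_regression(sim.table, st, "st0", var)
            for st in ("st1", "st2")
            for var in ("T", "P")
        ]
        filled = climate.fill_gaps(sim.table, regs).set_index(["station", "year", "month"])
        removed = sim.removed.set_index(["station", "year", "month"])
        errs_p = (filled.loc[removed.index, "P"] - removed["P"]).abs()
        errs_t = (filled.loc[removed.index, "T"] - removed["T"]).abs()
        assert errs_p.mean() < 2 * spec.noise_sd_p
        assert errs_t.mean() < 2 * spec.noise_sd_t

    def test_gap_with_missing_predictor_stays_missing(self):
        rows = [("ref", 2000, m, float(m), 30.0) for m in range(1, 13)]
        rows += [("sat", 2000, m, m + 1.0, 30.0) for m in range(1, 13)]
        table = _make_table(rows)
        table.loc[(table["station"] == "ref") & (table["month"] == 6), "T"] = np.nan
        table.loc[(table["station"] == "sat") & (table["month"].isin([5, 6])), "T"] = np.nan
        reg = climate.fit_station_regression(table, "sat", "ref", "T")
        with pytest.warns(UserWarning, match="remain missing"):
            filled = climate.fill_gaps(table, [reg])
        sat = filled[filled["station"] == "sat"].set_index("month")
        assert sat.at[5, "T"] == pytest.approx(6.0)
        assert np.isnan(sat.at[6, "T"]) and not sat.at[6, "T_filled"]


class TestAnnualSummary:
    def test_sum_and_mean(self):
        rows = [("a", 2001, m, 11.8, 50.0) for m in range(1, 13)]
        p, t = climate.annual_summary(_make_table(rows), "a", 2001)
        assert p == pytest.approx(600.0)
        assert t == pytest.approx(11.8)

    def test_missing_month_named_in_error(self):
        rows = [("a", 2001, m, 10.0, 50.0) for m in range(1, 12)]
        with pytest.raises(ValueError, match=r"\[12\]"):
            climate.annual_summary(_make_table(rows), "a", 2001)

    def test_matches_hand_sum_on_synthetic_year(self, climate_sim):
        sub = climate_sim.table.query("station == 'st0' and year == 1975")
        p, t = climate.annual_summary(climate_sim.table, "st0", 1975)
        assert p == pytest.approx(sub["P"].to_numpy().sum())
        assert t == pytest.approx(sub["T"].to_numpy().mean())


class TestDeMartonne:
    def test_zero_precipitation(self):
        assert climate.de_martonne(0.0, 15.0) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            climate.de_martonne(500.0, -10.0)

    @given(
        p=st.floats(0, 2000),
        t=st.floats(-9.5, 35),
        dp=st.floats(0.1, 100),
        dt=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p_and_t(self, p, t, dp, dt):
        base = climate.de_martonne(p, t)
        assert climate.de_martonne(p + dp, t) > base
        assert climate.de_martonne(p, t + dt) < base or base == 0


class TestThornthwaite:
    def test_all_freezing_months_zero_pet(self):
        with pytest.warns(UserWarning, match="zero"):
            pet = climate.thornthwaite_pet(np.full(12, -2.0), 44.0)
        assert np.all(pet == 0)

    def test_constant_20c_unadjusted_matches_independent_evaluation(self):
        pet = climate.thornthwaite_pet(np.full(12, 20.0), 44.0, apply_day_length=False)
        oracle = _thornthwaite_oracle([20.0] * 12)
        np.testing.assert_allclose(pet, oracle, atol=0.1)
        assert pet[0] == pytest.approx(73.9, abs=0.1)

    @pytest.mark.parametrize(
        "monthly_t",
        [
            [-2.5, -0.5, 4.5, 11.0, 16.5, 20.5, 22.5, 22.0, 17.5, 11.5, 5.0, 0.0],
            [5.0, 6.0, 9.0, 14.0, 19.0, 24.0, 28.0, 27.5, 22.0, 15.0, 9.0, 5.5],
        ],
    )
    def test_seasonal_cycle_matches_independent_evaluation(self, monthly_t):
        pet = climate.thornthwaite_pet(np.array(monthly_t), 44.0)
        oracle = _thornthwaite_oracle(monthly_t, latitude=44.0)
        np.testing.assert_allclose(pet, oracle, atol=0.1)

    def test_day_length_correction_july_above_one_december_below(self):
        assert climate.day_length_correction(44.0, 7) > 1.0
        assert climate.day_length_correction(44.0, 12) < 1.0

    def test_monotone_in_monthly_temperature(self):
        base = np.array([-2.5, -0.5, 4.5, 11.0, 16.5, 20.5, 22.5, 22.0, 17.5, 11.5, 5.0, 0.0])
        pet0 = climate.thornthwaite_pet(base, 44.0)
        warmer = base.copy()
        warmer[6] += 2.0
        pet1 = climate.thornthwaite_pet(warmer, 44.0)
        assert pet1[6] > pet0[6]
        assert np.all(pet0 >= 0)


class TestUnepAndClasses:
    def test_ratio(self):
        assert climate.unep_index(750.0, 750.0) == 1.0
        assert climate.unep_index(300.0, 750.0) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            climate.unep_index(300.0, 0.0)

    @pytest.mark.parametrize(
        "value, scheme, expected",
        [
            (0.35, "UNEP", "semi-arid (0.2–0.5)"),
            (0.80, "UNEP", "humid (≥0.65)"),
            (0.5, "UNEP", "dry sub-humid (0.5–0.65)"),  # half-open boundary
            (17.0, "DM", "semi-arid/steppe (15–20)"),
            (9.9, "DM", "arid (<10)"),
            (15.0, "DM", "semi-arid/steppe (15–20)"),  # half-open boundary
        ],
    )
    def test_classification_schemes(self, value, scheme, expected):
        assert climate.classify_aridity(value, scheme) == expected

    def test_synthetic_warm_dry_year_in_semi_arid_band(self):
        monthly_t = np.array([0.0, 2.0, 7.0, 13.0, 19.0, 23.0, 26.0, 25.5, 20.0, 13.0, 6.0, 1.0])
        pet = float(climate.thornthwaite_pet(monthly_t, 44.0).sum())
        i_unep = climate.unep_index(280.0, pet)
        assert 0.2 <= i_unep <= 0.5


class TestLinearTrend:
    def test_exact_negative_trend(self):
        years = np.arange(1961, 2010)
        fit = climate.linear_trend(years, years * -0.1 + 30)
        assert fit.slope == pytest.approx(-0.1)
        assert fit.r == pytest.approx(-1.0)

    def test_constant_series(self):
        fit = climate.linear_trend([2000, 2001, 2002], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            climate.linear_trend([2000, 2001], [1.0, 2.0])

    def test_noisy_declining_series_within_three_se(self, rng):
        years = np.arange(1961, 2010)
        values = 20.0 - 0.05 * (years - 1961) + rng.normal(0, 0.5, len(years))
        fit = climate.linear_trend(years, values)
        se = stats.linregress(years, values).stderr
        assert abs(fit.slope + 0.05) < 3 * se
        assert fit.slope < 0


class TestEndToEnd:
    def test_filled_series_reproduces_uncut_de_martonne_exactly(self):
        spec = synth.ClimateSimSpec(
            noise_sd_t=0.0, noise_sd_p=0.0, intercepts_p=(4.0, 5.0),
            gap_fraction=0.12, seed=29,
        )
        uncut = synth.simulate_climate(
            synth.ClimateSimSpec(
                noise_sd_t=0.0, noise_sd_p=0.0, intercepts_p=(4.0, 5.0),
                gap_fraction=0.0, seed=29,
            )
        )
        gappy = synth.simulate_climate(spec)
        regs = [
            climate.fit_station_regression(gappy.table, st, "st0", var)
            for st in ("st1", "st2")
            for var in ("T", "P")
        ]
        filled = climate.fill_gaps(gappy.table, regs)
        a = climate.aridity_table(filled, 44.0)
        b = climate.aridity_table(uncut.table, 44.0)
        np.testing.assert_allclose(a["I_DM"], b["I_DM"], atol=1e-8)

    def test_aridity_table_columns_and_classes(self, climate_sim):
        regs = [
            climate.fit_station_regression(climate_sim.table, st, "st0", var)
            for st in ("st1", "st2")
            for var in ("T", "P")
        ]
        filled = climate.fill_gaps(climate_sim.table, regs)
        out = climate.aridity_table(filled, 44.0)
        assert {"I_DM", "I_UNEP", "PET_annual", "class_DM", "class_UNEP"} <= set(out.columns)
        assert (out["PET_annual"] > 0).all()
        assert (out["I_DM"] >= 0).all() and (out["I_UNEP"] >= 0).all()
        # reference station covers every simulated year
        assert len(out.query("station == 'st0'")) == 49
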