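"""Cohort cascade: stage handling, progression pooling, LOT counts, engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import lungpcm as lp
from lungpcm.cascade import EARLY_STAGES, HISTOLOGIES

from conftest import make_series
from oracles import cascade_oracle


class TestRedistributeUnknown:
    def test_france_pro_rata(self, france_params):
        d = lp.redistribute_unknown_stage(france_params.stage_dist)
        assert d["I"] == pytest.approx(7.5 * 100 / 93.5, abs=1e-9)
        assert d["I"] == pytest.approx(8.021, abs=5e-4)
        assert d["IV"] == pytest.approx(56.578, abs=5e-4)
        assert sum(d.values()) == pytest.approx(100.0, abs=1e-9)

    def test_no_unknown_is_identity(self):
        d = lp.redistribute_unknown_stage({"I": 10, "II": 20, "III": 30, "IV": 40, "unknown": 0})
        assert d == {"I": 10, "II": 20, "III": 30, "IV": 40}

    def test_symmetric_example(self):
        d = lp.redistribute_unknown_stage({"I": 25, "II": 25, "III": 25, "IV": 20, "unknown": 5})
        assert d["I"] == pytest.approx(26.316, abs=5e-4)
        assert d["IV"] == pytest.approx(21.053, abs=5e-4)

    def test_drop_mode_keeps_known_mass(self):
        d = lp.redistribute_unknown_stage(
            {"I": 25, "II": 25, "III": 25, "IV": 20, "unknown": 5}, mode="drop")
        assert d == {"I": 25, "II": 25, "III": 25, "IV": 20}

    def test_all_unknown_degenerate(self):
        with pytest.raises(lp.DomainError):
            lp.redistribute_unknown_stage({"I": 0, "II": 0, "III": 0, "IV": 0, "unknown": 100})


class TestSplitCohort:
    def test_france_morphology_split(self, france_params):
        cs = lp.split_cohort(1000.0, france_params)
        assert cs.nsclc == pytest.approx(831.0, rel=1e-12)
        assert cs.sclc_excluded == pytest.approx(169.0, rel=1e-12)

    def test_france_advanced_at_diagnosis(self, france_params):
        cs = lp.split_cohort(1000.0, france_params)
        assert cs.advanced_at_dx / cs.nsclc == pytest.approx(0.56578 + 0.26952 * 0.496, abs=2e-5)
        assert cs.advanced_at_dx == pytest.approx(581.2, abs=0.1)

    def test_conservation(self, all_params):
        for params in all_params.values():
            cs = lp.split_cohort(12345.6, params)
            assert cs.sclc_excluded + cs.nsclc == pytest.approx(cs.total, rel=1e-12)
            assert cs.early_total + cs.advanced_at_dx == pytest.approx(cs.nsclc, rel=1e-9)

    def test_negative_cases_rejected(self, france_params):
        with pytest.raises(lp.DomainError):
            lp.split_cohort(-1.0, france_params)


class TestProgressedAdvanced:
    def _models(self, france_params):
        return france_params.progression_models()

    def test_empty_history_zero(self, france_params):
        assert lp.progressed_advanced({}, self._models(france_params), 2016) == 0.0

    def test_single_stage_one_cohort(self, france_params):
        models = self._models(france_params)
        out = lp.progressed_advanced({2015: {"I": 1000.0}}, models, 2016)
        assert out == pytest.approx(58.0, abs=0.1)

    def test_constant_history_telescopes(self, france_params):
        models = self._models(france_params)
        e = 500.0
        history = {y: {s: e for s in EARLY_STAGES} for y in range(2006, 2016)}
        out = lp.progressed_advanced(history, models, 2016)
        expected = e * sum(m.cdf(10) for m in models.values())
        assert out == pytest.approx(expected, rel=1e-12)

    def test_cohorts_beyond_window_cured(self, france_params):
        models = self._models(france_params)
        out = lp.progressed_advanced({2000: {"I": 1e6}}, models, 2016)
        assert out == 0.0


class TestLotCounts:
    def test_france_published_products(self, france_params):
        lc = lp.lot_counts(1000.0, france_params)
        assert lc[("squamous", "second")] == pytest.approx(96.72, abs=0.01)
        assert lc[("nonsquamous", "second")] == pytest.approx(254.98, abs=0.01)

    def test_zero_rate_zero_count(self, france_params):
        p = lp.CountryParams.from_dict("X", {**france_params.to_dict(), "lot_rates": {
            "squamous": {"first": 0.0, "second": 0.0, "third": 0.0},
            "nonsquamous": {"first": 0.0, "second": 0.0, "third": 0.0}}})
        assert all(v == 0.0 for v in lp.lot_counts(5000.0, p).values())

    def test_dominance_for_all_bundled_params(self, all_params):
        for params in all_params.values():
            lc = lp.lot_counts(1000.0, params)
            eligible = 1000.0 * params.pct_eligible / 100.0
            for h in HISTOLOGIES:
                pool = eligible * params.histology_share(h) / 100.0
                assert lc[(h, "third")] <= lc[(h, "second")] <= lc[(h, "first")] <= pool

    @given(adv=st.floats(0, 1e6))
    def test_linearity_in_advanced_pool(self, adv):
        params = lp.default_params("Italy")
        unit = lp.lot_counts(1.0, params)
        scaled = lp.lot_counts(adv, params)
        for k in unit:
            assert scaled[k] == pytest.approx(adv * unit[k], rel=1e-12)


class TestCountryParamsValidation:
    def test_bad_stage_sum_reported(self, france_params):
        d = france_params.to_dict()
        d["stage_dist"]["IV"] = 40.0
        with pytest.raises(lp.ValidationError, match="sum"):
            lp.CountryParams.from_dict("France", d)

    def test_bsc_eligible_complementarity(self, france_params):
        d = france_params.to_dict()
        d["pct_bsc"] = 20.0
        with pytest.raises(lp.ValidationError, match="pct_bsc"):
            lp.CountryParams.from_dict("France", d)

    def test_lot_ordering_enforced(self, france_params):
        d = france_params.to_dict()
        d["lot_rates"]["squamous"]["third"] = 99.0
        with pytest.raises(lp.ValidationError, match="third <= second <= first"):
            lp.CountryParams.from_dict("France", d)

    def test_all_errors_collected(self, france_params):
        d = france_params.to_dict()
        d["pct_nsclc"] = 150.0
        d["pct_bsc"] = 20.0
        try:
            lp.CountryParams.from_dict("France", d)
        except lp.ValidationError as e:
            msg = str(e)
        assert "pct_nsclc" in msg and "pct_bsc" in msg


# ---------------------------------------------------------------------------
# Deterministic engine

def _toy_inputs(apcs=(2.0, -1.0), base_rates=(200.0, 60.0), out_years=(2016, 2018)):
    """One country, two strata (M/F 60-64), noise-free data 2000-2012."""
    fits, truth = [], []
    for sex, apc, base, pop in zip(("M", "F"), apcs, base_rates, (300000.0, 320000.0)):
        series = make_series(apc=apc, base=base, years=(2000, 2012), sex=sex, cohort="60-64")
        fits.append(lp.select_joinpoints(series, max_joinpoints=0))
        truth.append(dict(base_rate=base, apc=apc, base_pop=pop, pop_growth=1.0))
    pop = lp.generate_population(
        {("France", "M", "60-64"): 300000.0, ("France", "F", "60-64"): 320000.0},
        1.0, (2000, out_years[1]))
    return {"France": fits}, pop, truth


def test_run_deterministic_matches_brute_force_oracle(france_params):
    fits, pop, truth = _toy_inputs()
    table = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    oracle = cascade_oracle(truth, france_params.to_dict(), range(2016, 2019))
    for (year, h, lot), expected in oracle.items():
        got = table.cells.query(
            "year == @year and histology == @h and lot == @lot")["count"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-9), (year, h, lot)


def test_doubling_population_doubles_counts(france_params):
    fits, pop, _ = _toy_inputs()
    base = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    pop2 = pop.copy()
    pop2["population"] *= 2.0
    doubled = lp.run_deterministic(fits, pop2, {"France": france_params}, years=(2016, 2018))
    np.testing.assert_allclose(doubled.cells["count"], 2.0 * base.cells["count"], rtol=1e-12)


def test_linearity_in_incidence_scale(france_params):
    fits, pop, _ = _toy_inputs()
    base = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    scaled = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018),
                                  rate_scale=3.5)
    np.testing.assert_allclose(scaled.cells["count"], 3.5 * base.cells["count"], rtol=1e-12)


def test_zero_lot_rates_give_zero_counts(france_params):
    fits, pop, _ = _toy_inputs()
    d = france_params.to_dict()
    d["lot_rates"] = {h: {"first": 0.0, "second": 0.0, "third": 0.0} for h in HISTOLOGIES}
    params = lp.CountryParams.from_dict("France", d)
    table = lp.run_deterministic(fits, pop, {"France": params}, years=(2016, 2018))
    assert (table.cells["count"] == 0.0).all()


def test_raising_one_lot_rate_moves_only_matching_cells(france_params):
    fits, pop, _ = _toy_inputs()
    base = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    d = france_params.to_dict()
    d["lot_rates"]["squamous"]["second"] += 5.0
    bumped = lp.run_deterministic(fits, pop, {"France": lp.CountryParams.from_dict("France", d)},
                                  years=(2016, 2018))
    merged = base.cells.merge(bumped.cells, on=["country", "year", "histology", "lot"],
                              suffixes=("_a", "_b"))
    touched = (merged["histology"] == "squamous") & (merged["lot"] == "second")
    assert (merged.loc[touched, "count_b"] > merged.loc[touched, "count_a"]).all()
    np.testing.assert_allclose(merged.loc[~touched, "count_b"],
                               merged.loc[~touched, "count_a"], rtol=1e-12)


def test_missing_country_params_named(france_params):
    fits, pop, _ = _toy_inputs()
    with pytest.raises(lp.ConfigurationError, match="France"):
        lp.run_deterministic(fits, pop, {}, years=(2016, 2018))


def test_survival_lag_mode_shifts_mass_forward(france_params):
    fits, pop, _ = _toy_inputs()
    base = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    lagged = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018),
                                  survival_lag=True)
    # survival weighting strictly reduces every count
    assert (lagged.cells["count"] < base.cells["count"]).all()


def test_totals_aggregate_cells(france_params):
    fits, pop, _ = _toy_inputs()
    table = lp.run_deterministic(fits, pop, {"France": france_params}, years=(2016, 2018))
    totals = table.totals()
    for _, row in totals.iterrows():
        cell_sum = table.cells.query(
            "year == @row.year and lot == @row.lot")["count"].sum()
        assert row["count"] == pytest.approx(cell_sum, rel=1e-12)
    assert (totals["count_rounded"] % 100 == 0).all()


def test_cagr_published_arithmetic():
    assert lp.cagr_pct(11600, 13900, 4) == pytest.approx(4.62, abs=0.01)
    with pytest.raises(lp.DomainError):
        lp.cagr_pct(0, 100, 4)
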