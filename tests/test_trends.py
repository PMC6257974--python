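"""Joinpoint trend fitting, APC conversion, projection, incident counts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import lungpcm as lp

from conftest import make_series
from oracles import ols_slope


class TestLogLinearFit:
    def test_exact_exponential(self):
        s = lp.IncidenceSeries("F", "M", "55-59", [0, 1, 2], [100.0, 105.0, 110.25])
        slope, intercept, se = lp.fit_loglinear(s)
        assert slope == pytest.approx(math.log(1.05), abs=1e-12)
        assert se == 0.0

    def test_constant_series_zero_slope(self):
        s = lp.IncidenceSeries("F", "M", "55-59", [2000, 2001, 2002, 2003], [50.0] * 4)
        slope, _, _ = lp.fit_loglinear(s)
        assert slope == pytest.approx(0.0, abs=1e-14)

    def test_published_apc_recovered_exactly(self):
        """Noise-free 8.6%/yr series (a published female APC) gives slope
        ln(1.086) to 1e-9."""
        s = make_series(apc=8.6, years=(2000, 2012))
        slope, _, _ = lp.fit_loglinear(s)
        assert slope == pytest.approx(math.log(1.086), abs=1e-9)

    def test_matches_brute_force_ols_on_noisy_data(self):
        s = make_series(apc=3.0, noise_cv=0.1, seed=5)
        slope, intercept, se = lp.fit_loglinear(s)
        o_slope, o_intercept, o_se = ols_slope(list(s.years), list(np.log(s.rates)))
        assert slope == pytest.approx(o_slope, rel=1e-12)
        assert intercept == pytest.approx(o_intercept, rel=1e-12)
        assert se == pytest.approx(o_se, rel=1e-9)

    def test_too_few_points(self):
        s = lp.IncidenceSeries("F", "M", "55-59", [2000, 2001], [1.0, 2.0])
        with pytest.raises(lp.InsufficientDataError):
            lp.fit_loglinear(s)

    def test_nonpositive_rate(self):
        s = lp.IncidenceSeries("F", "M", "55-59", [0, 1, 2], [1.0, 0.0, 2.0])
        with pytest.raises(lp.DomainError):
            lp.fit_loglinear(s)


class TestAPCConversion:
    @pytest.mark.parametrize("slope,apc", [
        (0.0, 0.0), (math.log(2), 100.0), (0.0824696, 8.597), (math.log(1.05), 5.0),
    ])
    def test_closed_form(self, slope, apc):
        assert lp.apc_from_slope(slope) == pytest.approx(apc, abs=5e-4)

    def test_nonfinite_rejected(self):
        with pytest.raises(lp.DomainError):
            lp.apc_from_slope(float("nan"))

    @given(st.floats(-0.5, 0.5))
    def test_roundtrip_with_slope_from_apc(self, slope):
        assert lp.slope_from_apc(lp.apc_from_slope(slope)) == pytest.approx(slope, abs=1e-12)


class TestJoinpointSelection:
    def test_noise_free_single_segment_selects_zero(self):
        s = make_series(apc=4.0, years=(2000, 2012))
        fit = lp.select_joinpoints(s, max_joinpoints=2, seed=0)
        assert fit.joinpoint_years == ()
        assert fit.last_segment.apc == pytest.approx(4.0, abs=1e-6)

    def test_noise_free_two_segments_recovered(self):
        spec = lp.TrendSpec("France", "F", "60-64", 100.0,
                            ((2000, 5.0), (2006, -3.0)), 0.0, (2000, 2011))
        s = lp.generate_registry_series(spec, 0)
        fit = lp.select_joinpoints(s, max_joinpoints=2, seed=1)
        assert fit.joinpoint_years == (2006,)
        assert fit.segments[0].apc == pytest.approx(5.0, abs=1e-6)
        assert fit.segments[1].apc == pytest.approx(-3.0, abs=1e-6)
        assert fit.fitted_last_rate == pytest.approx(s.rates[-1], rel=1e-9)

    def test_short_series_reduces_max_with_warning(self):
        s = make_series(years=(2000, 2003))
        fit = lp.select_joinpoints(s, max_joinpoints=1, seed=0)
        assert fit.joinpoint_years == ()
        assert any("too short" in w for w in fit.warnings)

    def test_n_perm_validated(self):
        s = make_series()
        with pytest.raises(lp.ValidationError):
            lp.select_joinpoints(s, max_joinpoints=1, n_perm=50)

    def test_seeded_reproducibility(self):
        s = make_series(apc=1.0, noise_cv=0.08, seed=3)
        a = lp.select_joinpoints(s, seed=11)
        b = lp.select_joinpoints(s, seed=11)
        assert a.joinpoint_years == b.joinpoint_years
        assert a.last_segment.apc == b.last_segment.apc

    def test_zero_joinpoints_matches_closed_form_ols(self):
        s = make_series(apc=2.0, noise_cv=0.1, seed=9)
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        o_slope, _, o_se = ols_slope(list(s.years), list(np.log(s.rates)))
        assert fit.last_segment.slope == pytest.approx(o_slope, rel=1e-10)
        assert fit.last_segment.slope_se == pytest.approx(o_se, rel=1e-9)
        assert fit.last_segment.apc == pytest.approx(lp.apc_from_slope(o_slope), rel=1e-10)


class TestProjection:
    def test_published_apc_compounding(self):
        """A published 8.6%/yr APC projected two years from a last fitted
        rate of 100."""
        s = make_series(apc=8.6, base=100.0 / 1.086 ** 12, years=(2000, 2012))
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        assert fit.fitted_last_rate == pytest.approx(100.0, rel=1e-9)
        np.testing.assert_allclose(lp.project_rates(fit, 2), [108.6, 117.9396], rtol=1e-6)

    def test_declining_apc_one_step(self):
        s = make_series(apc=-4.8, base=100.0 / 0.952 ** 12, years=(2000, 2012))
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        assert lp.project_rates(fit, 1)[0] == pytest.approx(95.2, rel=1e-6)

    def test_zero_apc_constant_projection(self):
        s = make_series(apc=0.0, base=77.0)
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        np.testing.assert_allclose(lp.project_rates(fit, 5), np.full(5, 77.0), rtol=1e-9)

    def test_constant_growth_ratio(self):
        s = make_series(apc=3.3)
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        proj = lp.project_rates(fit, 8)
        np.testing.assert_allclose(proj[1:] / proj[:-1], 1.033, rtol=1e-9)

    def test_rate_at_backcasts_by_reverse_compounding(self):
        s = make_series(apc=5.0, base=100.0, years=(2000, 2010))
        fit = lp.select_joinpoints(s, max_joinpoints=0)
        assert fit.rate_at(1999) == pytest.approx(100.0 / 1.05, rel=1e-9)

    def test_invalid_horizon(self):
        fit = lp.select_joinpoints(make_series(), max_joinpoints=0)
        with pytest.raises(lp.DomainError):
            lp.project_rates(fit, 0)


class TestIncidentCounts:
    def _frames(self, rate, pop):
        rates = pd.DataFrame([("France", "M", "55-59", 2016, rate)],
                             columns=["country", "sex", "age_group", "year", "rate_per_100k"])
        popdf = pd.DataFrame([("France", "M", "55-59", 2016, pop)],
                             columns=["country", "sex", "age_group", "year", "population"])
        return rates, popdf

    def test_rate_times_population(self):
        counts = lp.incident_counts(*self._frames(500.0, 200000.0))
        assert counts["count"].iloc[0] == pytest.approx(1000.0, rel=1e-12)

    def test_zero_rate_zero_cases(self):
        counts = lp.incident_counts(*self._frames(0.0, 1e6))
        assert counts["count"].iloc[0] == 0.0

    def test_strata_additivity(self):
        rates = pd.DataFrame(
            [("France", "M", "55-59", 2016, 500.0), ("France", "F", "55-59", 2016, 250.0)],
            columns=["country", "sex", "age_group", "year", "rate_per_100k"])
        pop = pd.DataFrame(
            [("France", "M", "55-59", 2016, 200000.0), ("France", "F", "55-59", 2016, 200000.0)],
            columns=["country", "sex", "age_group", "year", "population"])
        counts = lp.incident_counts(rates, pop)
        assert counts["count"].sum() == pytest.approx(1500.0, rel=1e-12)

    def test_missing_stratum_named_in_error(self):
        rates, pop = self._frames(500.0, 200000.0)
        pop["year"] = 2017
        with pytest.raises(KeyError, match="France/M/55-59"):
            lp.incident_counts(rates, pop)


def test_fit_summary_frame_schema_and_significance():
    fits = [lp.select_joinpoints(make_series(apc=8.6, noise_cv=0.02, seed=i), seed=i)
            for i in range(3)]
    from lungpcm.trends import fit_summary_frame
    df = fit_summary_frame(fits)
    assert {"country", "sex", "age_group", "n_joinpoints", "last_segment_APC",
            "APC_CI_low", "APC_CI_high", "p_value", "significant",
            "fitted_last_rate"} <= set(df.columns)
    assert df["significant"].all()  # strong trend, tiny noise
    assert ((df["APC_CI_low"] <= df["last_segment_APC"])
            & (df["last_segment_APC"] <= df["APC_CI_high"])).all()
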