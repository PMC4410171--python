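"""The aging-out prevalence recursion, CI propagation and summaries.

The central oracle is the brute-force cohort sum in conftest: prevalence at
year n equals the sum over diagnosis cohorts of incidence times the product
of in-population survival factors.  Frozen national-series values were
computed independently with that oracle and plain arithmetic.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cohort_sum
from incprev.prevalence import (
    GSchedule,
    build_g_schedule,
    cross_model_summary,
    propagate_ci,
    rate_to_count,
    run_recursion,
)
from incprev.trends import IncidenceSeries, PlateauStats, plateau_stats

# Cohort-sum oracle values on the national series, per scenario, year 2012.
ORACLE_P2012 = {
    "raw": 721.8927767928184,
    "model1_linear": 721.8176714688757,
    "model2_exp1987": 765.7645323188941,
    "model3_exp1980": 770.8696811502361,
}


def flat_series(start, end, value, model_id="raw"):
    return IncidenceSeries(
        model_id=model_id, start_year=start, rates={y: value for y in range(start, end + 1)}
    )


def const_g(start, end, g):
    return GSchedule(values={y: g for y in range(start, end + 1)}, fill_before=g)


small_instances = st.tuples(
    st.lists(st.floats(min_value=0.0, max_value=200.0), min_size=1, max_size=12),
    st.lists(st.floats(min_value=0.0, max_value=0.5), min_size=12, max_size=12),
)


class TestGSchedule:
    def test_observed_values(self, table1):
        g = build_g_schedule(table1)
        assert g.g(2005) == pytest.approx(0.0614, abs=5e-5)
        assert g.g(2013) == pytest.approx(0.0513, abs=5e-5)

    def test_pre_observation_years_use_first_observed_value(self, table1):
        g = build_g_schedule(table1)
        assert g.g(1985) == g.g(1997)
        assert g.g(1980) == pytest.approx(0.0609, abs=5e-5)

    def test_post_span_year_requires_extension(self, table1):
        g = build_g_schedule(table1)
        with pytest.raises(KeyError, match="2015"):
            g.g(2015)
        assert g.extended(2020, 0.05).g(2015) == 0.05

    def test_rejects_proportion_outside_unit_interval(self):
        with pytest.raises(ValueError):
            GSchedule(values={2000: 1.2}, fill_before=0.05)


class TestRecursion:
    @pytest.mark.parametrize("model_id,expected", sorted(ORACLE_P2012.items()))
    def test_national_series_matches_cohort_oracle(self, analysis, model_id, expected):
        assert analysis.prevalence[model_id].rates[2012] == pytest.approx(
            expected, rel=1e-12
        )

    def test_initial_condition_is_start_year_incidence(self, analysis):
        for m, series in analysis.prevalence.items():
            inc = analysis.incidence[m]
            assert series.rates[inc.start_year] == inc.rates[inc.start_year]

    @given(data=small_instances)
    @settings(max_examples=100, deadline=None)
    def test_recursion_equals_brute_force_cohort_sum(self, data):
        rates, gs = data
        start = 2000
        end = start + len(rates) - 1
        inc = IncidenceSeries(
            model_id="raw", start_year=start,
            rates={start + i: r for i, r in enumerate(rates)},
        )
        g = GSchedule(
            values={start + i: gs[i] for i in range(len(rates))}, fill_before=gs[0]
        )
        series = run_recursion(inc, g, end)
        for n in range(start, end + 1):
            expected = cohort_sum(inc.rate, g.g, start, n)
            assert series.rates[n] == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_constant_input_converges_monotonically_to_fixed_point(self):
        i_const, g_const = 77.0, 0.06
        series = run_recursion(
            flat_series(2000, 2200, i_const), const_g(2000, 2200, g_const), 2200
        )
        fixed = i_const / g_const
        gaps = [fixed - series.rates[y] for y in range(2000, 2201)]
        assert all(g > 0 for g in gaps)            # approaches from below
        assert all(b < a for a, b in zip(gaps, gaps[1:]))  # monotone
        # geometric contraction with factor (1 - G)
        for a, b in zip(gaps, gaps[1:]):
            assert b == pytest.approx(a * (1 - g_const), rel=1e-9)
        assert series.rates[2200] == pytest.approx(fixed, rel=1e-3)

    def test_zero_incidence_decays_geometrically(self):
        rates = {2000: 100.0} | {y: 0.0 for y in range(2001, 2011)}
        inc = IncidenceSeries(model_id="raw", start_year=2000, rates=rates)
        series = run_recursion(inc, const_g(2000, 2010, 0.1), 2010)
        for y in range(2001, 2011):
            assert series.rates[y] == pytest.approx(100.0 * 0.9 ** (y - 2000), rel=1e-12)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_recursion_is_linear_in_incidence(self, scale, analysis):
        inc = analysis.incidence["raw"]
        g = GSchedule(
            values={y: 0.06 for y in range(1997, 2013)}, fill_before=0.06
        )
        base = run_recursion(inc, g, 2012)
        scaled_inc = IncidenceSeries(
            model_id="raw", start_year=inc.start_year,
            rates={y: r * scale for y, r in inc.rates.items()},
        )
        scaled = run_recursion(scaled_inc, g, 2012)
        for y in base.rates:
            assert scaled.rates[y] == pytest.approx(base.rates[y] * scale, rel=1e-9)

    def test_pointwise_larger_incidence_never_lowers_prevalence(self, analysis):
        inc = analysis.incidence["raw"]
        g = const_g(1997, 2012, 0.06)
        bumped = IncidenceSeries(
            model_id="raw", start_year=inc.start_year,
            rates={y: r + (5.0 if y == 2003 else 0.0) for y, r in inc.rates.items()},
        )
        p0 = run_recursion(inc, g, 2012)
        p1 = run_recursion(bumped, g, 2012)
        assert all(p1.rates[y] >= p0.rates[y] for y in p0.rates)

    def test_sensitivity_to_pre_registry_g_fill_is_small(self, table1, analysis):
        """Pre-1997 cohorts are mostly aged out by 2012, so the choice of
        fill value for the unobserved aging-out proportion barely matters."""
        inc = analysis.incidence["model3_exp1980"]
        base = analysis.prevalence["model3_exp1980"].rates[2012]
        g0 = build_g_schedule(table1)
        for fill in (0.04, 0.08):
            g = GSchedule(values=g0.values, fill_before=fill)
            alt = run_recursion(inc, g, 2012).rates[2012]
            assert abs(alt - base) / base < 0.01

    def test_recursion_beyond_series_end_raises(self, analysis):
        inc = analysis.incidence["raw"]
        g = const_g(1997, 2030, 0.06)
        with pytest.raises(ValueError, match="2020"):
            run_recursion(inc, g, 2020)


class TestCiPropagation:
    def test_bounds_bracket_point_estimate_in_plateau_era(self, analysis):
        for series in analysis.prevalence.values():
            for y in range(2004, 2013):
                assert series.ci_lower[y] <= series.rates[y] <= series.ci_upper[y]

    def test_national_series_mean_bounds_at_2012(self, analysis):
        lo, hi = analysis.summary_target.ci_mean
        # published as 95% CI 660-840 per 100 000
        assert lo == pytest.approx(671.03, abs=0.01)
        assert hi == pytest.approx(812.06, abs=0.01)

    def test_degenerate_plateau_ci_collapses_bounds_onto_point(self):
        inc = flat_series(2000, 2012, 50.0)
        g = const_g(2000, 2012, 0.06)
        series = run_recursion(inc, g, 2012)
        plateau_like = PlateauStats(
            mean=50.0, sd=0.0, n=5, ci95=(50.0, 50.0), window=(2004, 2012)
        )
        with_ci = propagate_ci(series, inc, g, plateau_like)
        for y in series.rates:
            assert with_ci.ci_lower[y] == pytest.approx(series.rates[y])
            assert with_ci.ci_upper[y] == pytest.approx(series.rates[y])

    def test_pre_plateau_years_keep_point_incidence(self, analysis):
        # before the substitution era all three trajectories coincide
        for series in analysis.prevalence.values():
            for y in range(series.start_year, 2004):
                assert series.ci_lower[y] == pytest.approx(series.rates[y])
                assert series.ci_upper[y] == pytest.approx(series.rates[y])


class TestCrossModelSummary:
    def test_national_series_2012_summary(self, analysis):
        s = analysis.summary_target
        assert s.mean == pytest.approx(745.086, abs=0.001)
        assert s.relative_deviation_pct == pytest.approx(6.583, abs=0.001)
        assert s.per_model["model3_exp1980"] == max(s.per_model.values())

    def test_identical_series_have_zero_deviation(self, analysis):
        s0 = analysis.prevalence["raw"]
        summary = cross_model_summary([s0, s0], 2012)
        assert summary.relative_deviation_pct == 0.0
        assert summary.mean == s0.rates[2012]

    def test_missing_year_and_too_few_series_raise(self, analysis):
        series = list(analysis.prevalence.values())
        with pytest.raises(ValueError, match="1950"):
            cross_model_summary(series, 1950)
        with pytest.raises(ValueError, match="at least 2"):
            cross_model_summary(series[:1], 2012)


class TestRateToCount:
    def test_published_display_convention(self):
        c = rate_to_count(750.0, 394_681)
        assert c.exact == pytest.approx(2960.1, abs=0.1)
        assert c.display == 2950

    def test_zero_and_identity_scale(self):
        assert rate_to_count(0.0, 1000).exact == 0.0
        assert rate_to_count(100_000.0, 12_345).exact == pytest.approx(12_345)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            rate_to_count(100.0, 0)
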