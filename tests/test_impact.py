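import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmrproj.core_data import Intervention, ValidationError
from mmrproj.impact import (
    aggregate,
    aggregate_records,
    apply_interventions,
    project,
    propagate_ui,
    sensitivity_project,
    single_intervention_lives_saved,
    single_intervention_mmr,
    ui_from_se,
)
from mmrproj.scenarios import builtin_scenarios
from mmrproj.synthetic_panel import GeneratorConfig, generate_panel

from conftest import make_country

S0, S1, S2, S3 = builtin_scenarios()


class TestPrintedFormulas:
    def test_estimated_mmr_direct_substitution(self):
        assert single_intervention_mmr(200, 0.2, 0.5, 0.8, 1.0) == pytest.approx(184.0)

    def test_lives_saved_direct_substitution(self):
        assert single_intervention_lives_saved(100_000, 200, 0.2, 0.5, 0.8, 1.0) == pytest.approx(16.0)

    def test_zero_coverage_change_is_identity(self):
        assert single_intervention_mmr(321.0, 0.3, 0.0, 0.9, 1.0) == 321.0
        assert single_intervention_lives_saved(50_000, 321.0, 0.3, 0.0, 0.9, 1.0) == 0.0

    def test_full_effect_removes_whole_cause(self):
        assert single_intervention_mmr(200, 0.2, 1.0, 1.0, 1.0) == pytest.approx(160.0)

    @settings(derandomize=True, max_examples=300)
    @given(
        mmr=st.floats(1.0, 1000.0),
        births=st.floats(1000.0, 5e6),
        share=st.floats(0.0, 1.0),
        change=st.floats(0.0, 1.0),
        eff=st.floats(0.0, 1.0),
        aff=st.floats(0.0, 1.0),
    )
    def test_formulas_are_algebraically_linked(self, mmr, births, share, change, eff, aff):
        """lives saved == (MMR - estimated MMR) * births / 100,000."""
        est = single_intervention_mmr(mmr, share, change, eff, aff)
        saved = single_intervention_lives_saved(births, mmr, share, change, eff, aff)
        assert saved == pytest.approx((mmr - est) * births / 100_000.0, rel=1e-9, abs=1e-9)

    def test_factor_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            single_intervention_mmr(200, 0.2, 1.5, 0.8, 1.0)


def two_interventions():
    a = Intervention("a", "childbirth", {"sepsis": (0.8, 1.0)})
    b = Intervention("b", "childbirth", {"sepsis": (0.5, 1.0)})
    return [a, b]


class TestApplyInterventions:
    def test_residual_cascade_and_attribution(self):
        """Cause deaths 40 with effects 0.4 and 0.25: residual 18, total
        averted 22, independent savings 16 and 10 rescaled by 22/26."""
        country = make_country(
            mmr_2020=40.0 / 0.10,  # sepsis share 0.10 -> 40 sepsis deaths
            live_births=100_000,
        )
        registry = two_interventions()
        residual, saved = apply_interventions(
            country, registry, {"a": 0.5, "b": 0.5}  # e = 0.5*0.8 = 0.4, 0.5*0.5 = 0.25
        )
        assert residual["sepsis"] == pytest.approx(18.0)
        assert saved["a"] == pytest.approx(16 * 22 / 26, abs=1e-9)
        assert saved["b"] == pytest.approx(10 * 22 / 26, abs=1e-9)
        assert saved["a"] + saved["b"] == pytest.approx(22.0, abs=1e-9)

    def test_single_intervention_reduces_to_printed_formulas(self):
        country = make_country(mmr_2020=200.0, live_births=100_000)
        (a, _) = two_interventions()
        residual, saved = apply_interventions(country, [a], {"a": 0.5})
        share = country.causes["sepsis"]
        assert saved["a"] == pytest.approx(
            single_intervention_lives_saved(100_000, 200.0, share, 0.5, 0.8, 1.0)
        )
        est = sum(residual.values()) / 100_000 * 1e5
        assert est == pytest.approx(single_intervention_mmr(200.0, share, 0.5, 0.8, 1.0))

    def test_order_independent(self):
        country = make_country()
        registry = two_interventions()
        changes = {"a": 0.3, "b": 0.6}
        r1, s1 = apply_interventions(country, registry, changes)
        r2, s2 = apply_interventions(country, registry[::-1], changes)
        assert r1 == pytest.approx(r2)
        assert s1 == pytest.approx(s2)

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValidationError):
            Intervention("x", "childbirth", {"bad_cause": (0.5, 1.0)})


class TestProject:
    def test_scenario_0_is_identity(self, registry, intervention_ids):
        country = make_country(intervention_ids=intervention_ids)
        res = project(country, S0, registry)
        assert res.mmr == pytest.approx(country.mmr_2020)
        assert res.total_lives_saved == 0.0
        assert res.pct_reduction_vs_s0 == pytest.approx(0.0)

    def test_universal_equals_baseline_when_coverage_high(self, registry, intervention_ids):
        country = make_country(coverage=0.97, intervention_ids=intervention_ids)
        res0 = project(country, S0, registry)
        res3 = project(country, S3, registry)
        assert res3.mmr == pytest.approx(res0.mmr)
        assert res3.total_lives_saved == pytest.approx(0.0)

    def test_conservation_and_partial_ordering(self, registry, intervention_ids):
        records, _ = generate_panel(GeneratorConfig(seed=17, n_countries=30), intervention_ids)
        for rec in records:
            baseline_deaths = rec.live_births * rec.mmr_2020 / 1e5
            mmrs = {}
            for scen in (S0, S1, S2, S3):
                res = project(rec, scen, registry)
                assert res.total_residual_deaths + res.total_lives_saved == pytest.approx(
                    baseline_deaths, abs=1e-6
                )
                assert all(v >= 0 for v in res.lives_saved.values())
                assert 0 < res.mmr <= rec.mmr_2020 + 1e-9
                assert res.ui[0] <= res.mmr <= res.ui[1]
                mmrs[scen.id] = res.mmr
            assert mmrs[2] <= mmrs[1] <= mmrs[0] + 1e-9

    def test_monotone_in_coverage_change(self):
        country = make_country()
        (a, _) = two_interventions()
        est = [
            sum(apply_interventions(country, [a], {"a": c})[0].values())
            for c in (0.0, 0.2, 0.4, 0.8, 1.0)
        ]
        assert all(b <= a for a, b in zip(est, est[1:]))

    def test_cumulative_mode_sums_annual_savings(self, registry, intervention_ids):
        country = make_country(intervention_ids=intervention_ids)
        annual = project(country, S2, registry, lives_saved_mode="annual")
        cumulative = project(country, S2, registry, lives_saved_mode="cumulative")
        assert cumulative.total_lives_saved > annual.total_lives_saved
        by_hand = sum(
            project(country, S2, registry, year=y).total_lives_saved
            for y in range(2025, 2031)
        )
        assert cumulative.total_lives_saved == pytest.approx(by_hand, rel=1e-9)


class TestUncertainty:
    def test_proportional_scaling(self):
        assert propagate_ui(200.0, (150.0, 260.0), 100.0) == pytest.approx((75.0, 130.0))

    def test_identity_when_estimate_equals_baseline(self):
        assert propagate_ui(200.0, (150.0, 260.0), 200.0) == pytest.approx((150.0, 260.0))

    def test_zero_width_stays_zero_width(self):
        low, high = propagate_ui(200.0, (200.0, 200.0), 120.0)
        assert low == high == pytest.approx(120.0)

    def test_relative_width_preserved(self):
        low, high = propagate_ui(200.0, (150.0, 260.0), 87.3)
        assert high / low == pytest.approx(260.0 / 150.0, rel=1e-12)

    def test_ui_from_se_zero(self):
        assert ui_from_se(200.0, 0.0) == pytest.approx((200.0, 200.0))

    def test_ui_from_se_80pct_width(self):
        low, high = ui_from_se(200.0, 39.02)
        assert low == pytest.approx(150.0, abs=0.01)
        assert high == pytest.approx(250.0, abs=0.01)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(123)
        mmr, se = 200.0, 30.0
        low, high = ui_from_se(mmr, se)
        draws = mmr + se * rng.standard_normal(1000)
        inside = np.mean((draws >= low) & (draws <= high))
        assert abs(inside - 0.80) <= 0.03


class TestSensitivity:
    def test_zero_apc_is_constant(self):
        assert sensitivity_project(200.0, 0.0, 2030) == 200.0

    def test_ten_year_decline(self):
        assert sensitivity_project(200.0, -3.0, 2030) == pytest.approx(200 * 0.97**10)
        assert sensitivity_project(200.0, -3.0, 2030) == pytest.approx(147.48, abs=0.01)

    def test_closed_form_matches_iteration(self):
        value = 123.4
        for _ in range(10):
            value *= 1.0 + (-2.5) / 100.0
        assert sensitivity_project(123.4, -2.5, 2030) == pytest.approx(value, rel=1e-12)


class TestAggregate:
    def test_symmetric_average(self, registry):
        a = make_country(iso3="AAA", mmr_2020=100.0, live_births=50_000)
        b = make_country(iso3="BBB", mmr_2020=300.0, live_births=50_000)
        results = [project(c, S0, registry) for c in (a, b)]
        assert aggregate(results)["mmr"] == pytest.approx(200.0)

    def test_births_weighted_average(self, registry):
        a = make_country(iso3="AAA", mmr_2020=100.0, live_births=10_000)
        b = make_country(iso3="BBB", mmr_2020=300.0, live_births=90_000)
        results = [project(c, S0, registry) for c in (a, b)]
        assert aggregate(results)["mmr"] == pytest.approx(280.0)

    def test_single_country_group(self, registry):
        a = make_country(iso3="AAA", mmr_2020=137.0)
        assert aggregate([project(a, S0, registry)])["mmr"] == pytest.approx(137.0)

    def test_identical_countries_equal_any_member(self, registry, intervention_ids):
        countries = [
            make_country(iso3=f"C{i}", intervention_ids=intervention_ids) for i in range(3)
        ]
        results = [project(c, S2, registry) for c in countries]
        agg = aggregate(results, {c.iso3: c.mmr_2020 for c in countries})
        assert agg["mmr"] == pytest.approx(results[0].mmr)
        assert agg["pct_reduction_vs_s0"] == pytest.approx(results[0].pct_reduction_vs_s0)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            aggregate([])

    def test_records_aggregation(self):
        a = make_country(iso3="AAA", mmr_2020=100.0, live_births=10_000)
        b = make_country(iso3="BBB", mmr_2020=300.0, live_births=90_000)
        assert aggregate_records([a, b])["mmr"] == pytest.approx(280.0)
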