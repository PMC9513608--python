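"""Market decomposition, salt-density calibration, and scenario arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breadsalt import bread_market as bm


class TestTotalAnnualBread:
    @pytest.mark.parametrize(
        "g_day, pop, days, expected",
        [
            (100.3, 10_300_000, 365.25, 377_336.1),
            (100.3, 0, 365.25, 0.0),
            (0.0, 10_300_000, 365.25, 0.0),
        ],
    )
    def test_examples(self, g_day, pop, days, expected):
        assert bm.total_annual_bread(g_day, pop, days) == pytest.approx(
            expected, abs=0.5
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bm.total_annual_bread(-1.0, 1000, 365.25)


class TestDecomposeMarket:
    def test_reported_segments(self, policy_fixture, market_decomp):
        d = market_decomp
        assert d.national_prepackaged_t_yr == pytest.approx(18_276, abs=0.5)
        assert d.loose_bakery_t_yr == pytest.approx(336_178, abs=0.5)
        assert d.exempt_t_yr == pytest.approx(181_268, abs=0.5)
        assert d.exempt_share * 100 == pytest.approx(48.18, abs=0.005)
        assert d.traditional_t_yr / d.exempt_t_yr == pytest.approx(0.88, abs=0.005)

    def test_no_prepackaged_no_traditional(self):
        inputs = bm.MarketInputs(
            per_capita_bread_g_day=100.0,
            population=1_000_000,
            prepackaged_sold_t_yr=0.0,
            imported_t_yr=0.0,
            traditional_fraction_of_national=0.0,
            bakery_compliance_fraction=0.5,
        )
        d = bm.decompose_market(inputs)
        assert d.loose_bakery_t_yr == d.total_t_yr
        assert d.exempt_t_yr == 0.0
        assert d.regulated_t_yr == d.total_t_yr

    def test_prepackaged_exceeding_total_rejected(self):
        inputs = bm.MarketInputs(
            per_capita_bread_g_day=0.0,
            population=1000,
            prepackaged_sold_t_yr=100.0,
            imported_t_yr=0.0,
            traditional_fraction_of_national=0.0,
            bakery_compliance_fraction=0.5,
        )
        with pytest.raises(bm.MarketConsistencyError):
            bm.decompose_market(inputs, 50.0)

    def test_imports_exceeding_prepackaged_rejected(self):
        with pytest.raises(bm.MarketConsistencyError):
            bm.MarketInputs(
                per_capita_bread_g_day=100.0,
                population=1_000_000,
                prepackaged_sold_t_yr=10.0,
                imported_t_yr=20.0,
                traditional_fraction_of_national=0.0,
                bakery_compliance_fraction=0.5,
            )

    def test_divergent_total_warns(self):
        inputs = bm.MarketInputs(
            per_capita_bread_g_day=100.0,
            population=1_000_000,
            prepackaged_sold_t_yr=0.0,
            imported_t_yr=0.0,
            traditional_fraction_of_national=0.0,
            bakery_compliance_fraction=0.5,
        )
        with pytest.warns(UserWarning, match="differs"):
            bm.decompose_market(inputs, 20_000.0)


class TestImpliedSaltDensity:
    @pytest.mark.parametrize(
        "share, salt, bread, expected",
        [
            (0.182, 7.4, 100.3, 1.3428),
            (0.0, 7.4, 100.3, 0.0),
            (1.0, 7.4, 100.0, 7.4),
        ],
    )
    def test_examples(self, share, salt, bread, expected):
        assert bm.implied_salt_density(share, salt, bread) == pytest.approx(
            expected, abs=5e-5
        )

    def test_zero_bread_rejected(self):
        with pytest.raises(ValueError):
            bm.implied_salt_density(0.182, 7.4, 0.0)


class TestCalibration:
    def test_two_segment_closure(self):
        assert bm.solve_free_density([(0.5, 1.0)], 0.5, 1.2) == pytest.approx(1.4)

    def test_identity_closure(self):
        # all fixed segments at density d, free segment must also be d
        assert bm.solve_free_density([(0.7, 1.3)], 0.3, 1.3) == pytest.approx(1.3)

    def test_exempt_density_from_reported_market(
        self, market_decomp, implied_density
    ):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        assert seg.segments["exempt"][1] == pytest.approx(1.608, abs=5e-4)

    def test_closure_reproduces_mean(self, market_decomp, implied_density):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        assert seg.mean_density == pytest.approx(implied_density, abs=1e-9)

    @pytest.mark.parametrize("target", [0.3, 7.0])
    def test_implausible_closure_rejected(self, market_decomp, target):
        # targets forcing the exempt density below 0 or above 10 g/100 g
        with pytest.raises(bm.CalibrationError):
            bm.calibrate_segment_salt(market_decomp, target, 0.76)

    @settings(deadline=None, max_examples=50)
    @given(
        compliance=st.floats(0.0, 1.0),
        target=st.floats(1.0, 2.5),
    )
    def test_closure_property(self, market_decomp, compliance, target):
        try:
            seg = bm.calibrate_segment_salt(market_decomp, target, compliance)
        except bm.CalibrationError:
            return
        assert seg.mean_density == pytest.approx(target, abs=1e-9)


def _single_segment(density, tonnes_per_day):
    total = tonnes_per_day * bm.DAYS_PER_YEAR
    decomp = bm.MarketDecomposition(
        total_t_yr=total,
        imported_prepackaged_t_yr=0.0,
        national_prepackaged_t_yr=0.0,
        loose_bakery_t_yr=total,
        traditional_t_yr=0.0,
        exempt_t_yr=0.0,
        regulated_t_yr=total,
    )
    seg = bm.SegmentSalt({"regulated": (1.0, density, False)})
    return decomp, seg


class TestScenarioReduction:
    def test_below_threshold_no_reduction(self, market_decomp, implied_density):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        scenario = bm.SaltScenario(threshold_g_per_100g=5.0, label="lenient")
        res = bm.scenario_reduction(
            market_decomp, seg, scenario, 10_300_000, 100.3
        )
        assert res.salt_reduction_t_day == 0.0
        assert res.salt_reduction_g_capita_day == 0.0

    def test_single_segment_arithmetic(self):
        # 100 t/day of bread at 1.5 g/100 g capped at 1.4 loses 0.1 t/day of salt
        decomp, seg = _single_segment(1.5, 100.0)
        scenario = bm.SaltScenario(threshold_g_per_100g=1.4)
        population = 1_000_000
        per_capita = decomp.total_t_yr * bm.GRAMS_PER_TONNE / (
            population * bm.DAYS_PER_YEAR
        )
        res = bm.scenario_reduction(decomp, seg, scenario, population, per_capita)
        assert res.salt_reduction_t_day == pytest.approx(0.1, rel=1e-12)

    def test_universal_1g_cap(self, market_decomp, implied_density):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        scenario = bm.SaltScenario(threshold_g_per_100g=1.0)
        res = bm.scenario_reduction(
            market_decomp, seg, scenario, 10_300_000, 100.3, baseline_salt_g_day=7.4
        )
        assert res.salt_reduction_g_capita_day == pytest.approx(0.344, abs=5e-4)
        assert res.salt_reduction_t_day == pytest.approx(3.54, abs=0.01)
        assert res.counterfactual_intake_g_capita_day == pytest.approx(
            7.4 - res.salt_reduction_g_capita_day
        )

    def test_scope_excludes_exempt(self, market_decomp, implied_density):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        capped_all = bm.scenario_reduction(
            market_decomp,
            seg,
            bm.SaltScenario(threshold_g_per_100g=1.0, scope=bm.Scope.ALL_BREAD),
            10_300_000,
            100.3,
        )
        capped_reg = bm.scenario_reduction(
            market_decomp,
            seg,
            bm.SaltScenario(
                threshold_g_per_100g=1.0, scope=bm.Scope.NON_EXEMPT_ONLY
            ),
            10_300_000,
            100.3,
        )
        assert capped_reg.salt_reduction_g_capita_day < (
            capped_all.salt_reduction_g_capita_day
        )

    @settings(deadline=None, max_examples=50)
    @given(
        t_low=st.floats(0.5, 2.0),
        t_high_delta=st.floats(0.0, 2.0),
    )
    def test_lower_threshold_never_reduces_less(
        self, market_decomp, implied_density, t_low, t_high_delta
    ):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        lo = bm.scenario_reduction(
            market_decomp,
            seg,
            bm.SaltScenario(threshold_g_per_100g=t_low),
            10_300_000,
            100.3,
        )
        hi = bm.scenario_reduction(
            market_decomp,
            seg,
            bm.SaltScenario(threshold_g_per_100g=t_low + t_high_delta),
            10_300_000,
            100.3,
        )
        assert lo.salt_reduction_g_capita_day >= hi.salt_reduction_g_capita_day

    def test_idempotent_on_own_counterfactual(self, market_decomp, implied_density):
        seg = bm.calibrate_segment_salt(market_decomp, implied_density, 0.76)
        scenario = bm.SaltScenario(threshold_g_per_100g=1.0)
        capped = seg.capped(scenario.threshold_g_per_100g, scenario.scope)
        res = bm.scenario_reduction(
            market_decomp, capped, scenario, 10_300_000, 100.3
        )
        assert res.salt_reduction_g_capita_day == 0.0


class TestConversions:
    @pytest.mark.parametrize(
        "t_day, pop, expected",
        [
            (3.6, 10_300_000, 0.3495),
            (0.0, 10_300_000, 0.0),
            (10.3, 10_300_000, 1.0),
        ],
    )
    def test_examples(self, t_day, pop, expected):
        assert bm.tons_per_day_to_per_capita(t_day, pop) == pytest.approx(
            expected, abs=5e-5
        )

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            bm.tons_per_day_to_per_capita(1.0, 0)

    @given(t_day=st.floats(0.0, 100.0), pop=st.floats(1e3, 1e8))
    def test_round_trip(self, t_day, pop):
        g = bm.tons_per_day_to_per_capita(t_day, pop)
        assert g * pop / bm.GRAMS_PER_TONNE == pytest.approx(t_day, rel=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    per_capita=st.floats(10.0, 500.0),
    pop=st.floats(1e5, 5e7),
    prepack_frac=st.floats(0.0, 0.5),
    import_frac=st.floats(0.0, 1.0),
    trad_frac=st.floats(0.0, 1.0),
)
def test_decomposition_conserves_mass(
    per_capita, pop, prepack_frac, import_frac, trad_frac
):
    total = bm.total_annual_bread(per_capita, pop)
    prepack = prepack_frac * total
    inputs = bm.MarketInputs(
        per_capita_bread_g_day=per_capita,
        population=pop,
        prepackaged_sold_t_yr=prepack,
        imported_t_yr=import_frac * prepack,
        traditional_fraction_of_national=trad_frac,
        bakery_compliance_fraction=0.76,
    )
    d = bm.decompose_market(inputs)
    assert (
        d.imported_prepackaged_t_yr
        + d.national_prepackaged_t_yr
        + d.loose_bakery_t_yr
    ) == pytest.approx(d.total_t_yr, abs=0.5)
    assert d.exempt_t_yr + d.regulated_t_yr == pytest.approx(d.total_t_yr, abs=0.5)
    assert d.exempt_t_yr == pytest.approx(
        d.traditional_t_yr + d.imported_prepackaged_t_yr, abs=0.5
    )


def test_market_config_round_trip(tmp_path, policy_fixture):
    path = tmp_path / "market.yaml"
    path.write_text(
        "per_capita_bread_g_day: 100.3\n"
        "population: 10300000\n"
        "prepackaged_sold_t_yr: 40040\n"
        "imported_t_yr: 21764\n"
        "traditional_fraction_of_national: 0.45\n"
        "bakery_compliance_fraction: 0.76\n"
        "per_capita_salt_g_day: 7.4\n"
        "bread_share_of_salt: 0.182\n"
        "total_t_yr: 376218\n"
    )
    inputs, baseline, total = bm.load_market_config(path)
    assert inputs == policy_fixture.market_inputs
    assert baseline == policy_fixture.salt_baseline
    assert total == policy_fixture.total_t_yr
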