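"""Activity-based costing: annuities, per-hospital and national costs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssnc_invest.costing import (
    annuity_factor,
    equivalent_annual_cost,
    national_category_totals,
    national_rollout,
    running_cost,
    setup_cost,
    staff_count_from_ratio,
    staffing_cost,
)
from ssnc_invest.synthetic import GeneratorSpec, generate_bundle
from ssnc_invest.types import (
    CostItem,
    CostRules,
    HospitalArchetype,
    ScenarioSpec,
    StaffingEntry,
    ValidationError,
)


class TestAnnuity:
    @pytest.mark.parametrize(
        "rate,years,expected",
        [(0.03, 20, 14.8775), (0.0, 5, 5.0), (0.03, 5, 4.5797)],
    )
    def test_closed_form(self, rate, years, expected):
        assert annuity_factor(rate, years) == pytest.approx(expected, abs=5e-5)

    def test_matches_discount_factor_summation(self):
        rate, years = 0.03, 20
        brute = sum(1.0 / (1.0 + rate) ** t for t in range(1, years + 1))
        assert annuity_factor(rate, years) == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize(
        "one_off,rate,years,expected",
        [(358_000, 0.03, 20, 24_063), (0, 0.03, 5, 0), (40_000, 0.03, 5, 8_734)],
    )
    def test_equivalent_annual_cost(self, one_off, rate, years, expected):
        assert equivalent_annual_cost(one_off, rate, years) == pytest.approx(expected, abs=1)

    @settings(derandomize=True, max_examples=100)
    @given(
        x=st.floats(0.0, 1e9),
        rate=st.one_of(st.just(0.0), st.floats(1e-6, 0.2)),
        years=st.integers(1, 40),
    )
    def test_annuity_round_trip(self, x, rate, years):
        eac = equivalent_annual_cost(x, rate, years)
        assert eac * annuity_factor(rate, years) == pytest.approx(x, rel=1e-9, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            annuity_factor(0.03, 0)
        with pytest.raises(ValidationError):
            annuity_factor(-0.01, 5)
        with pytest.raises(ValidationError):
            equivalent_annual_cost(-1.0, 0.03, 5)


def _dh(tz):
    return next(a for a in tz.archetypes if a.level == "district")


class TestSetupCost:
    def test_district_all_new_sums_printed_components(self, tz):
        bd = setup_cost(_dh(tz), tz.catalogue, tz.scenarios["A"], tz.cost_rules)
        assert bd.per_category["infrastructure"] == pytest.approx(358_000)
        assert bd.per_category["furniture_fixtures"] == pytest.approx(50_000)
        assert bd.per_category["devices"] == pytest.approx(40_000)
        assert bd.total == pytest.approx(448_000)

    def test_district_halfway_blend(self, tz):
        bd = setup_cost(_dh(tz), tz.catalogue, tz.scenarios["B"], tz.cost_rules)
        # renovated half costs 20% of a new build; half the items acquired
        assert bd.total == pytest.approx(358_000 * 0.6 + 90_000 * 0.5)
        assert bd.total == pytest.approx(258_000, rel=0.01)

    def test_zero_cost_catalogue(self, tz):
        catalogue = [
            CostItem("a", "infrastructure", "setup", "district", 0.0, 1, 20.0),
            CostItem("b", "furniture_fixtures", "setup", "district", 0.0, 1, 5.0),
            CostItem("c", "devices", "setup", "district", 0.0, 1, 5.0),
        ]
        bd = setup_cost(_dh(tz), catalogue, tz.scenarios["A"])
        assert bd.total == 0.0
        assert bd.annualised_total == 0.0

    def test_missing_category_raises(self, tz):
        catalogue = [CostItem("a", "infrastructure", "setup", "district", 1.0, 1, 20.0)]
        with pytest.raises(ValidationError):
            setup_cost(_dh(tz), catalogue, tz.scenarios["A"])


class TestStaffingCost:
    def test_single_cadre_annualisation(self):
        policy = [StaffingEntry("nurse", "district", "A", 13, 100.0)]
        scen = ScenarioSpec("A", 1.0, 0.2, 1.0, staffing_policy="A")
        assert staffing_cost(policy, "district", scen) == pytest.approx(13 * 12 * 100.0)

    def test_empty_policy_is_free(self):
        scen = ScenarioSpec("A", 1.0, 0.2, 1.0, staffing_policy="A")
        assert staffing_cost([], "district", scen) == 0.0

    def test_scenario_b_reads_its_own_counts(self, tz):
        b_rows = [
            e for e in tz.staffing if e.level == "district" and e.scenario == "B" and e.cadre == "nurse"
        ]
        assert len(b_rows) == 1 and b_rows[0].count == 7
        a_cost = staffing_cost(tz.staffing, "district", tz.scenarios["A"])
        b_cost = staffing_cost(tz.staffing, "district", tz.scenarios["B"])
        assert b_cost < a_cost

    def test_negative_salary_rejected(self):
        with pytest.raises(ValidationError):
            StaffingEntry("nurse", "district", "A", 1, -5.0)

    def test_ratio_helper_is_explicit_about_uplift(self):
        # 40 cots at 1:4 over 3 shifts with 20% cover uplift
        assert staff_count_from_ratio(40, 0.25) == pytest.approx(36.0)
        with pytest.raises(ValidationError):
            staff_count_from_ratio(0, 0.25)


class TestRunningCost:
    def test_district_scenario_a_reproduces_printed_total(self, tz):
        dh = _dh(tz)
        setup = setup_cost(dh, tz.catalogue, tz.scenarios["A"], tz.cost_rules)
        bd = running_cost(dh, tz.catalogue, tz.scenarios["A"], tz.cost_rules, setup, tz.staffing)
        assert bd.total == pytest.approx(231_000)
        assert bd.per_category["maintenance"] == pytest.approx(0.03 * 448_000)  # 13,440
        # consumables mark-up applied to supplies only
        assert bd.per_category["supplies_consumables"] == pytest.approx(42_000 * 1.1)
        assert bd.per_category["medicines"] == pytest.approx(18_480)

    def test_human_resources_dominate(self, tz):
        dh = _dh(tz)
        setup = setup_cost(dh, tz.catalogue, tz.scenarios["A"], tz.cost_rules)
        bd = running_cost(dh, tz.catalogue, tz.scenarios["A"], tz.cost_rules, setup, tz.staffing)
        assert 0.55 <= bd.category_shares()["human_resources"] <= 0.65

    def test_all_zero_inputs_cost_nothing(self, tz):
        dh = _dh(tz)
        catalogue = [
            CostItem("a", "infrastructure", "setup", "district", 0.0, 0, 20.0),
            CostItem("b", "furniture_fixtures", "setup", "district", 0.0, 0, 5.0),
            CostItem("c", "devices", "setup", "district", 0.0, 0, 5.0),
        ]
        setup = setup_cost(dh, catalogue, tz.scenarios["A"])
        bd = running_cost(dh, catalogue, tz.scenarios["A"], tz.cost_rules, setup, [])
        assert bd.total == 0.0


class TestNationalRollout:
    def test_district_annualised_total_near_printed(self, tz):
        nat = national_rollout(tz.archetypes, tz.catalogue, tz.staffing, tz.scenarios["A"], tz.cost_rules)
        per_dh = nat.per_level["district"].annualised_per_hospital
        # running 231,000 + annualised setup components at 3%
        expected = 231_000 + 358_000 / annuity_factor(0.03, 20) + 90_000 / annuity_factor(0.03, 5)
        assert per_dh == pytest.approx(expected, rel=1e-12)
        assert per_dh == pytest.approx(274_000, rel=0.005)

    def test_scenario_b_district_annualised_total(self, tz):
        nat = national_rollout(tz.archetypes, tz.catalogue, tz.staffing, tz.scenarios["B"], tz.cost_rules)
        assert nat.per_level["district"].annualised_per_hospital == pytest.approx(130_000, rel=0.10)

    def test_zero_hospitals_zero_totals(self, tz):
        archetypes = [HospitalArchetype("district", 40, 0), HospitalArchetype("regional", 80, 0)]
        nat = national_rollout(archetypes, tz.catalogue, tz.staffing, tz.scenarios["A"], tz.cost_rules)
        assert nat.setup_total == 0.0
        assert nat.running_total == 0.0
        assert nat.annualised_total == 0.0

    def test_additivity_over_levels(self, tz):
        nat = national_rollout(tz.archetypes, tz.catalogue, tz.staffing, tz.scenarios["A"], tz.cost_rules)
        assert nat.setup_total == pytest.approx(
            sum(lc.setup.total * lc.archetype.count_in_rollout for lc in nat.per_level.values())
        )
        for kind in ("setup", "running"):
            cats = national_category_totals(nat, kind)
            ref = nat.setup_total if kind == "setup" else nat.running_total
            assert sum(cats.values()) == pytest.approx(ref)

    @pytest.mark.parametrize("scenario", ["A", "B"])
    def test_fixture_cost_driver_shares(self, tz, scenario):
        """Infrastructure ~83% of setup; human resources ~60% of running."""
        nat = national_rollout(tz.archetypes, tz.catalogue, tz.staffing, tz.scenarios[scenario], tz.cost_rules)
        setup_cats = national_category_totals(nat, "setup")
        run_cats = national_category_totals(nat, "running")
        assert 0.80 <= setup_cats["infrastructure"] / nat.setup_total <= 0.86
        assert 0.55 <= run_cats["human_resources"] / nat.running_total <= 0.65

    def test_scenario_b_never_costs_more_than_a(self):
        for seed in range(25):
            b = generate_bundle(GeneratorSpec(seed=seed))
            nats = {
                s: national_rollout(b.archetypes, b.catalogue, b.staffing, b.scenarios[s], b.cost_rules)
                for s in ("A", "B")
            }
            assert nats["B"].setup_total <= nats["A"].setup_total + 1e-9
            assert nats["B"].running_total <= nats["A"].running_total + 1e-9
            assert nats["B"].annualised_total <= nats["A"].annualised_total + 1e-9
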