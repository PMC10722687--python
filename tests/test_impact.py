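"""Lives-saved projection: trajectories, cause reductions, projections."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssnc_invest.impact import (
    build_trajectory,
    cause_mortality_reduction,
    halve_effectiveness,
    percent_deaths_averted,
    project_impact,
    sequential_reduction_oracle,
)
from ssnc_invest.types import (
    CauseProfile,
    CountryProfile,
    ImpactProjection,
    InterventionSpec,
    ValidationError,
)


def _iv(name="x", cause="prematurity", eff=0.5, af=1.0, base=0.1, target=0.85):
    return InterventionSpec(name, cause, eff, af, base, target)


def _profile(births=2.15e6, nmr=20.0):
    return CountryProfile(
        population=61.5e6,
        annual_births=births,
        baseline_nmr=nmr,
        life_expectancy=66.0,
        gdp_per_capita=1099.0,
        the_per_capita=40.62,
    )


class TestBuildTrajectory:
    def test_endpoints_and_linear_midpoint(self):
        traj = build_trajectory(0.10, 0.85, 2021, 2025)
        assert traj.coverage(2021) == pytest.approx(0.10)
        assert traj.coverage(2025) == pytest.approx(0.85)
        assert traj.coverage(2023) == pytest.approx(0.475)

    def test_constant_when_target_equals_baseline(self):
        traj = build_trajectory(0.10, 0.10, 2021, 2030)
        assert all(traj.coverage(y) == pytest.approx(0.10) for y in range(2021, 2031))

    def test_holds_flat_outside_window(self):
        traj = build_trajectory(0.10, 0.85, 2021, 2025)
        assert traj.coverage(2019) == pytest.approx(0.10)
        assert traj.coverage(2030) == pytest.approx(0.85)

    @pytest.mark.parametrize(
        "baseline,target,start,end",
        [(0.85, 0.10, 2021, 2025), (0.10, 0.85, 2025, 2021), (0.10, 0.85, 2021, 2021)],
    )
    def test_invalid_inputs_raise(self, baseline, target, start, end):
        with pytest.raises(ValidationError):
            build_trajectory(baseline, target, start, end)


class TestCauseMortalityReduction:
    def test_single_intervention_residual_form(self):
        iv = _iv(eff=0.9, af=1.0)
        r = cause_mortality_reduction([iv], {"x": 0.85}, {"x": 0.10})
        assert r == pytest.approx(1.0 - 0.235 / 0.91)  # 0.74176

    def test_no_coverage_change_means_no_reduction(self):
        ivs = [_iv("a", eff=0.9), _iv("b", eff=0.4)]
        cov = {"a": 0.3, "b": 0.6}
        assert cause_mortality_reduction(ivs, cov, cov) == 0.0

    def test_product_form_never_double_counts(self):
        ivs = [_iv("a", eff=0.5, base=0.0, target=1.0), _iv("b", eff=0.5, base=0.0, target=1.0)]
        r = cause_mortality_reduction(ivs, {"a": 1.0, "b": 1.0}, {"a": 0.0, "b": 0.0})
        assert r == pytest.approx(0.75)
        assert r < 1.0  # strictly below the additive 1.0

    def test_saturated_intervention_rejected(self):
        iv = _iv(eff=1.0, af=1.0, target=1.0)
        with pytest.raises(ValidationError):
            cause_mortality_reduction([iv], {"x": 1.0}, {"x": 0.0})

    def test_mixed_causes_rejected(self):
        with pytest.raises(ValidationError):
            cause_mortality_reduction(
                [_iv("a", cause="prematurity"), _iv("b", cause="congenital")],
                {"a": 0.5, "b": 0.5},
                {"a": 0.1, "b": 0.1},
            )

    @settings(derandomize=True, max_examples=200)
    @given(
        effs=st.lists(st.floats(0.01, 0.95), min_size=1, max_size=3),
        afs=st.lists(st.floats(0.1, 1.0), min_size=3, max_size=3),
        cov0=st.floats(0.0, 0.5),
        cov1=st.floats(0.5, 0.99),
    )
    def test_matches_sequential_oracle_and_additive_bound(self, effs, afs, cov0, cov1):
        ivs = [_iv(f"i{k}", eff=e, af=afs[k], base=cov0, target=cov1) for k, e in enumerate(effs)]
        ct = {iv.name: cov1 for iv in ivs}
        c0 = {iv.name: cov0 for iv in ivs}
        combined = cause_mortality_reduction(ivs, ct, c0)
        sequential = sequential_reduction_oracle(ivs, ct, c0)
        assert combined == pytest.approx(sequential, abs=1e-12)
        individual_sum = sum(cause_mortality_reduction([iv], ct, c0) for iv in ivs)
        assert combined <= individual_sum + 1e-12
        assert combined < 1.0


class TestProjectImpact:
    def _causes(self):
        return CauseProfile({"prematurity": 0.3, "neonatal_infections": 0.3, "other": 0.4})

    def test_zero_change_identity(self):
        profile = _profile()
        ivs = [_iv("a", eff=0.9, base=0.1, target=0.1)]
        trajs = {"a": build_trajectory(0.1, 0.1, 2021, 2030)}
        proj = project_impact(profile, self._causes(), ivs, trajs, 2030)
        assert all(v == pytest.approx(0.0) for v in proj.annual_deaths_averted.values())
        assert all(
            v == pytest.approx(profile.baseline_nmr) for v in proj.nmr_by_year.values()
        )

    def test_baseline_deaths_from_births_and_nmr(self):
        profile = _profile(births=2.15e6, nmr=20.0)
        assert profile.baseline_annual_deaths == pytest.approx(43_000)
        ivs = [_iv("a")]
        trajs = {"a": build_trajectory(0.1, 0.85, 2021, 2030)}
        proj = project_impact(profile, self._causes(), ivs, trajs, 2030)
        first = proj.years[0]
        assert proj.annual_deaths[first] + proj.annual_deaths_averted[first] == pytest.approx(43_000)

    def test_nmr_conservation(self):
        profile = _profile()
        ivs = [_iv("a", eff=0.9)]
        trajs = {"a": build_trajectory(0.1, 0.85, 2021, 2030)}
        proj = project_impact(profile, self._causes(), ivs, trajs, 2030)
        for y in proj.years:
            assert proj.nmr_by_year[y] == pytest.approx(
                proj.annual_deaths[y] / profile.annual_births * 1000.0, abs=1e-9
            )

    def test_missing_cause_mapping_raises(self):
        with pytest.raises(ValidationError):
            project_impact(
                _profile(),
                CauseProfile({"other": 1.0}),
                [_iv("a", cause="prematurity")],
                {"a": build_trajectory(0.1, 0.85, 2021, 2030)},
                2030,
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        eff=st.floats(0.05, 0.9),
        base=st.floats(0.0, 0.3),
        bump=st.floats(0.01, 0.3),
        target=st.floats(0.35, 0.65),
    )
    def test_raising_target_coverage_never_loses_lives(self, eff, base, bump, target):
        profile = _profile()
        causes = self._causes()

        def cumulative(tgt):
            ivs = [_iv("a", eff=eff, base=base, target=tgt)]
            trajs = {"a": build_trajectory(base, tgt, 2021, 2030)}
            proj = project_impact(profile, causes, ivs, trajs, 2030)
            return proj.cumulative_lives_saved[2030]

        assert cumulative(target + bump) >= cumulative(target) - 1e-9


class TestPercentDeathsAverted:
    def _proj(self, deaths, averted):
        return ImpactProjection(
            annual_deaths={2025: deaths},
            annual_deaths_averted={2025: averted},
            cumulative_lives_saved={2025: averted},
            nmr_by_year={2025: deaths / 2.15e6 * 1000},
            lives_saved_by_cause={"prematurity": 1.0} if averted else {"prematurity": 0.0},
        )

    def test_ratio_of_averted_to_counterfactual(self):
        proj = self._proj(43_000 - 15_050, 15_050)
        assert percent_deaths_averted(proj, 2025) == pytest.approx(0.35)

    def test_bounds(self):
        assert percent_deaths_averted(self._proj(43_000, 0.0), 2025) == 0.0
        assert percent_deaths_averted(self._proj(0.0, 43_000), 2025) == pytest.approx(1.0)

    def test_year_out_of_range(self):
        with pytest.raises(ValidationError):
            percent_deaths_averted(self._proj(1.0, 0.0), 1999)


class TestHalveEffectiveness:
    def test_halves_non_exempt_only(self):
        ivs = [_iv("cpap", eff=0.90), _iv("intrapartum care", cause="intrapartum", eff=0.10)]
        out = halve_effectiveness(ivs, exempt=["intrapartum care"])
        assert out[0].effectiveness == pytest.approx(0.45)
        assert out[1].effectiveness == pytest.approx(0.10)
        # every other field untouched
        assert out[0].affected_fraction == ivs[0].affected_fraction
        assert out[0].target_coverage == ivs[0].target_coverage

    def test_zero_effectiveness_stays_zero(self):
        (out,) = halve_effectiveness([_iv("z", eff=0.0)], exempt=[])
        assert out.effectiveness == 0.0
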