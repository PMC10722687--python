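"""Return on investment, monetised health benefits and budget impact.

Cost side: equivalent annual capital costs are committed for every year of
the analysis period, and running costs phase in with an implementation
schedule (a fraction of the steady-state annual running cost per year).
"Costs to horizon" follow the undiscounted annualised-cost convention; NPV
helpers are provided for discounted views.

Benefit side: averted deaths are converted to years of life lost averted
(lives × life expectancy), valued per life-year either at a GDP-per-capita
multiple or at a value-of-statistical-life year, and discounted back as a
lump sum over the benefit horizon (default: one life expectancy).
"""

from __future__ import annotations

from typing import Mapping

from .bundle import Bundle
from .impact import halve_effectiveness, project_impact
from .types import (
    CountryProfile,
    ImplementationSchedule,
    MonetisationSpec,
    ROIResult,
    ValidationError,
)

__all__ = [
    "setup_stream",
    "running_stream",
    "npv",
    "value_per_life_year",
    "monetise_lives",
    "productivity_gains",
    "present_value_of_benefit",
    "compute_roi",
    "budget_impact",
    "roi_analysis",
    "sensitivity_suite",
]


def setup_stream(annualised_setup: float, years: int) -> float:
    """Total annualised capital cost committed over ``years`` years."""
    if years < 0:
        raise ValidationError("years must be >= 0")
    return annualised_setup * years


def running_stream(
    full_annual_running: float,
    schedule: ImplementationSchedule,
) -> tuple[dict[int, float], float]:
    """Phase running costs in: year value = fraction × full annual cost."""
    if full_annual_running < 0:
        raise ValidationError("full_annual_running must be >= 0")
    stream = {y: f * full_annual_running for y, f in schedule.fraction_by_year.items()}
    return stream, sum(stream.values())


def npv(stream: Mapping[int, float], rate: float, base_year: int) -> float:
    """Net present value with end-of-year convention: the base-year flow is
    undiscounted and year t is discounted by (1+rate)^(t - base_year)."""
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    return sum(v / (1.0 + rate) ** (y - base_year) for y, v in stream.items())


def value_per_life_year(spec: MonetisationSpec, years_of_growth: float = 0.0) -> float:
    """USD value of one averted life-year under the chosen method.

    ``years_of_growth`` optionally compounds GDP growth into the
    GDP-multiplier value (the constant-GDP default uses 0).
    """
    if spec.method == "gdp_multiplier":
        base = spec.gdp_multiplier * spec.gdp_per_capita
        return base * (1.0 + spec.gdp_growth) ** years_of_growth
    return spec.vsl_year


def monetise_lives(
    lives: float, life_expectancy: float, value_year: float
) -> tuple[float, float]:
    """(years of life lost averted, future monetary value)."""
    if min(lives, life_expectancy, value_year) < 0:
        raise ValidationError("lives, life expectancy and value must be non-negative")
    yll = lives * life_expectancy
    return yll, yll * value_year


def productivity_gains(lives: float, productive_years: float, value_year: float) -> float:
    """Future value of productive life-years gained by survivors."""
    if min(lives, productive_years, value_year) < 0:
        raise ValidationError("inputs must be non-negative")
    return lives * productive_years * value_year


def present_value_of_benefit(future_value: float, rate: float, horizon_years: float) -> float:
    """Discount a lump-sum future benefit back over ``horizon_years``."""
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    return future_value / (1.0 + rate) ** horizon_years


def compute_roi(costs_pv: float, social_pv: float, productivity_pv: float) -> float:
    """Benefit-cost ratio: (social + productivity benefits) / costs."""
    if costs_pv <= 0:
        raise ValidationError("costs must be strictly positive")
    return (social_pv + productivity_pv) / costs_pv


def budget_impact(annual_cost: float, profile: CountryProfile) -> dict[str, float]:
    """Cost per capita, per live birth, and as a share of total health
    expenditure per capita."""
    cost_per_capita = annual_cost / profile.population
    return {
        "cost_per_capita": cost_per_capita,
        "cost_per_birth": annual_cost / profile.annual_births,
        "share_of_the": cost_per_capita / profile.the_per_capita,
    }


def _coverage_fractions(bundle: Bundle, horizon: int) -> dict[int, float]:
    """Mean intervention coverage by year, used as an alternative phase-in."""
    trajs = bundle.trajectories()
    years = range(bundle.start_year, horizon + 1)
    return {
        y: sum(t.coverage(y) for t in trajs.values()) / len(trajs) for y in years
    }


def roi_analysis(
    bundle: Bundle,
    horizon: int | None = None,
    method: str | None = None,
    running_mode: str = "schedule",
    interventions=None,
) -> ROIResult:
    """End-to-end ROI for one bundle.

    ``running_mode="schedule"`` phases running costs with the
    implementation schedule; ``"coverage"`` scales them with the coverage
    trajectory instead (sensitivity analysis).  ``method`` overrides the
    bundle's monetisation method; ``interventions`` overrides the
    intervention set (e.g. halved effectiveness).
    """
    horizon = bundle.end_year if horizon is None else horizon
    spec = bundle.monetisation
    if method is not None:
        from dataclasses import replace

        spec = replace(spec, method=method)

    n_years = horizon - bundle.start_year + 1
    setup_total = setup_stream(bundle.roi_inputs.annualised_setup_total, n_years)
    if running_mode == "schedule":
        stream = {
            y: f * bundle.roi_inputs.full_annual_running
            for y, f in bundle.schedule.fraction_by_year.items()
            if y <= horizon
        }
    elif running_mode == "coverage":
        stream = {
            y: c * bundle.roi_inputs.full_annual_running
            for y, c in _coverage_fractions(bundle, horizon).items()
        }
    else:
        raise ValidationError(f"unknown running_mode {running_mode!r}")
    running_total = sum(stream.values())
    total_costs = setup_total + running_total

    ivs = bundle.interventions if interventions is None else interventions
    projection = project_impact(
        bundle.country, bundle.causes, ivs, bundle.trajectories(end_year=horizon), horizon
    )
    lives = projection.cumulative_lives_saved[horizon]

    value_year = value_per_life_year(spec)
    yll, social_fv = monetise_lives(lives, bundle.country.life_expectancy, value_year)
    prod_fv = productivity_gains(lives, spec.productive_years, value_year)
    benefit_horizon = (
        spec.benefit_horizon_years
        if spec.benefit_horizon_years is not None
        else bundle.country.life_expectancy
    )
    social_pv = present_value_of_benefit(social_fv, spec.discount_rate, benefit_horizon)
    prod_pv = present_value_of_benefit(prod_fv, spec.discount_rate, benefit_horizon)
    roi = compute_roi(total_costs, social_pv, prod_pv)

    return ROIResult(
        setup_costs_to_horizon=setup_total,
        running_costs_to_horizon=running_total,
        total_costs_pv=total_costs,
        yll_averted=yll,
        social_benefit_fv=social_fv,
        social_benefit_pv=social_pv,
        productivity_fv=prod_fv,
        productivity_pv=prod_pv,
        roi_total=roi,
        cost_per_death_averted=total_costs / lives if lives > 0 else 0.0,
    )


def sensitivity_suite(bundle: Bundle, horizon: int | None = None) -> dict:
    """The three published sensitivity analyses plus the base case.

    (i) value benefits with the VSL year instead of the GDP multiple;
    (ii) phase running costs with the coverage trajectory instead of the
    implementation schedule; (iii) halve the effectiveness of the
    high-impact interventions (supportive care for intrapartum and
    congenital conditions is exempt) and report the NMR the country would
    be stuck at by the national-target year.
    """
    horizon = bundle.end_year if horizon is None else horizon
    base = roi_analysis(bundle, horizon=horizon, method="gdp_multiplier")
    vsl = roi_analysis(bundle, horizon=horizon, method="vsl")
    coverage_costs = roi_analysis(
        bundle, horizon=horizon, method="gdp_multiplier", running_mode="coverage"
    )

    exempt = [iv.name for iv in bundle.interventions if iv.cause in ("intrapartum", "congenital")]
    halved = halve_effectiveness(bundle.interventions, exempt=exempt)
    target_year = min(bundle.start_year + 4, horizon)
    halved_proj = project_impact(
        bundle.country,
        bundle.causes,
        halved,
        bundle.trajectories(end_year=target_year),
        target_year,
    )

    return {
        "base": base,
        "vsl": vsl,
        "coverage_scaled_running": coverage_costs,
        "halved_effectiveness": {
            "target_year": target_year,
            "nmr": halved_proj.nmr_by_year[target_year],
            "cumulative_lives_saved": halved_proj.cumulative_lives_saved[target_year],
        },
        "cost_per_death_averted": base.cost_per_death_averted,
    }
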