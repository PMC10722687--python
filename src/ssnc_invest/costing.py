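"""Activity-based incremental costing of hospital newborn units.

Setup costs (infrastructure, ward furniture and fixtures, neonatal devices)
are one-off capital costs annualised with a standard annuity factor at the
catalogue discount rate over each item's useful life.  Running costs
(human resources, supplies, medicines, data/QI, maintenance) recur
annually; maintenance is charged as a fixed fraction of the setup cost.

Scenario rules scale the all-new catalogue: a scenario that renovates part
of the fleet pays ``renovation_cost_fraction`` of a new build for that part
(expected-cost blend over the fleet, so no integer hospital split is
needed) and acquires only ``item_acquisition_fraction`` of non-infrastructure
items.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .types import (
    CostBreakdown,
    CostItem,
    CostRules,
    HospitalArchetype,
    LevelCosts,
    NationalCosts,
    ScenarioSpec,
    StaffingEntry,
    ValidationError,
    RUNNING_CATEGORIES,
    SETUP_CATEGORIES,
)

__all__ = [
    "annuity_factor",
    "equivalent_annual_cost",
    "setup_cost",
    "staffing_cost",
    "staff_count_from_ratio",
    "running_cost",
    "national_rollout",
]


def annuity_factor(rate: float, years: float) -> float:
    """Present value of 1/year for ``years`` years at ``rate``.

    (1 - (1+rate)^-years) / rate, with the zero-rate limit equal to
    ``years``.
    """
    if years < 1:
        raise ValidationError("years must be >= 1")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if rate == 0:
        return float(years)
    return (1.0 - (1.0 + rate) ** (-years)) / rate


def equivalent_annual_cost(one_off: float, rate: float, years: float) -> float:
    """Spread a one-off capital cost over its useful life at ``rate``."""
    if one_off < 0:
        raise ValidationError("one_off must be >= 0")
    return one_off / annuity_factor(rate, years)


def _scenario_factor(category: str, scenario: ScenarioSpec) -> float:
    if category == "infrastructure":
        return scenario.infrastructure_cost_fraction
    return scenario.item_acquisition_fraction


def setup_cost(
    archetype: HospitalArchetype,
    catalogue: Sequence[CostItem],
    scenario: ScenarioSpec,
    rules: CostRules = CostRules(),
) -> CostBreakdown:
    """Expected one-off setup cost per hospital of this archetype."""
    items = [
        it for it in catalogue if it.kind == "setup" and it.level == archetype.level
    ]
    present = {it.category for it in items}
    missing = set(SETUP_CATEGORIES) - present
    if missing:
        raise ValidationError(
            f"setup catalogue for level {archetype.level!r} missing categories: {sorted(missing)}"
        )
    per_category = {c: 0.0 for c in SETUP_CATEGORIES}
    annualised = 0.0
    for it in items:
        amount = it.unit_cost * it.quantity * _scenario_factor(it.category, scenario)
        per_category[it.category] += amount
        annualised += equivalent_annual_cost(amount, rules.discount_rate, it.useful_life)
    return CostBreakdown(
        per_category=per_category,
        total=sum(per_category.values()),
        annualised_total=annualised,
    )


def staffing_cost(
    policy: Sequence[StaffingEntry],
    level: str,
    scenario: ScenarioSpec,
) -> float:
    """Annual incremental salary bill per hospital: sum count × 12 × salary.

    Counts come straight from the scenario's policy table ("not charged"
    cells are zero rows or simply absent).
    """
    rows = [e for e in policy if e.level == level and e.scenario == scenario.staffing_policy]
    return sum(e.count * 12.0 * e.monthly_salary for e in rows)


def staff_count_from_ratio(
    cots: int,
    staff_to_cot_ratio: float,
    shifts_per_day: float = 3.0,
    leave_uplift: float = 1.2,
) -> float:
    """Derive a ward staff count from a staff:cot ratio, shift coverage and
    a leave/maternity-cover uplift.

    Provided as a planning helper; the packaged Tanzania policy tables use
    the published per-hospital counts directly, which this formula does not
    reproduce.
    """
    if cots <= 0 or staff_to_cot_ratio <= 0:
        raise ValidationError("cots and ratio must be positive")
    return cots * staff_to_cot_ratio * shifts_per_day * leave_uplift


def running_cost(
    archetype: HospitalArchetype,
    catalogue: Sequence[CostItem],
    scenario: ScenarioSpec,
    rules: CostRules,
    setup_ref: CostBreakdown,
    staffing: Sequence[StaffingEntry] = (),
) -> CostBreakdown:
    """Annual running cost per hospital.

    Human resources from the staffing policy; supplies with the consumables
    mark-up; medicines and data/QI straight from the catalogue; maintenance
    as ``maintenance_rate`` × the (scenario-adjusted) setup total.  Non-HR
    consumable categories are scaled by the scenario's acquisition fraction.
    """
    per_category = {c: 0.0 for c in RUNNING_CATEGORIES}
    per_category["human_resources"] = staffing_cost(staffing, archetype.level, scenario)
    for it in catalogue:
        if it.kind != "running" or it.level != archetype.level:
            continue
        if it.category == "maintenance":
            raise ValidationError("maintenance is derived from setup cost, not a catalogue line")
        amount = it.unit_cost * it.quantity * scenario.item_acquisition_fraction
        if it.category == "supplies_consumables":
            amount *= 1.0 + rules.markup_consumables
        per_category[it.category] += amount
    per_category["maintenance"] = rules.maintenance_rate * setup_ref.total
    total = sum(per_category.values())
    return CostBreakdown(per_category=per_category, total=total, annualised_total=total)


def national_rollout(
    archetypes: Sequence[HospitalArchetype],
    catalogue: Sequence[CostItem],
    staffing: Sequence[StaffingEntry],
    scenario: ScenarioSpec,
    rules: CostRules = CostRules(),
) -> NationalCosts:
    """Roll per-hospital costs up to the national fleet."""
    per_level: dict[str, LevelCosts] = {}
    for arch in archetypes:
        setup = setup_cost(arch, catalogue, scenario, rules)
        running = running_cost(arch, catalogue, scenario, rules, setup, staffing)
        per_hospital = running.total + setup.annualised_total
        n = arch.count_in_rollout
        per_level[arch.level] = LevelCosts(
            archetype=arch,
            setup=setup,
            running=running,
            annualised_per_hospital=per_hospital,
            setup_total=setup.total * n,
            running_total=running.total * n,
            annualised_total=per_hospital * n,
        )
    return NationalCosts(
        per_level=per_level,
        setup_total=sum(lc.setup_total for lc in per_level.values()),
        running_total=sum(lc.running_total for lc in per_level.values()),
        annualised_total=sum(lc.annualised_total for lc in per_level.values()),
    )


def national_category_totals(
    national: NationalCosts, kind: str
) -> Mapping[str, float]:
    """Fleet-wide per-category totals for ``kind`` in {"setup", "running"}."""
    if kind not in ("setup", "running"):
        raise ValidationError("kind must be 'setup' or 'running'")
    out: dict[str, float] = {}
    for lc in national.per_level.values():
        bd = lc.setup if kind == "setup" else lc.running
        n = lc.archetype.count_in_rollout
        for cat, v in bd.per_category.items():
            out[cat] = out.get(cat, 0.0) + v * n
    return out
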