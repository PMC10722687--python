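"""Domain types for the SSNC investment-case pipeline.

All types are plain dataclasses that validate their invariants on
construction and raise :class:`ValidationError` with a message naming the
offending field.  Monetary amounts are constant-price US dollars; rates and
coverages are decimal proportions; years are calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Mapping, Optional

__all__ = [
    "ValidationError",
    "SETUP_CATEGORIES",
    "RUNNING_CATEGORIES",
    "CATEGORIES",
    "CAUSES",
    "CountryProfile",
    "CauseProfile",
    "InterventionSpec",
    "CoverageTrajectory",
    "ImpactProjection",
    "HospitalArchetype",
    "CostItem",
    "ScenarioSpec",
    "StaffingEntry",
    "CostBreakdown",
    "CostRules",
    "LevelCosts",
    "NationalCosts",
    "ImplementationSchedule",
    "MonetisationSpec",
    "ROIInputs",
    "ROIResult",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


#: capital (one-off) cost categories, annualised over their useful life
SETUP_CATEGORIES = ("infrastructure", "furniture_fixtures", "devices")
#: annually recurring cost categories
RUNNING_CATEGORIES = (
    "human_resources",
    "supplies_consumables",
    "medicines",
    "data_qi",
    "maintenance",
)
CATEGORIES = SETUP_CATEGORIES + RUNNING_CATEGORIES

#: canonical neonatal cause-of-death labels
CAUSES = (
    "prematurity",
    "neonatal_infections",
    "intrapartum",
    "congenital",
    "other",
)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class CountryProfile:
    """Demography and macro-economic constants read by every stage.

    ``ssnc_need_fraction`` is the proportion of live births requiring
    inpatient small-and-sick-newborn care; ``mean_admission_days`` the
    average inpatient stay.  Both inform unit planning rather than the
    mortality model itself.
    """

    population: float
    annual_births: float
    baseline_nmr: float  # deaths per 1000 live births
    life_expectancy: float  # years
    gdp_per_capita: float  # USD / year
    the_per_capita: float  # total health expenditure, USD / year
    ssnc_need_fraction: float = 0.10
    mean_admission_days: float = 7.0

    def __post_init__(self) -> None:
        for name in (
            "population",
            "annual_births",
            "baseline_nmr",
            "life_expectancy",
            "gdp_per_capita",
            "the_per_capita",
            "ssnc_need_fraction",
            "mean_admission_days",
        ):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.ssnc_need_fraction <= 1, "ssnc_need_fraction must be in (0, 1]")
        _require(0 < self.baseline_nmr < 1000, "baseline_nmr must be in (0, 1000)")

    @property
    def baseline_annual_deaths(self) -> float:
        return self.annual_births * self.baseline_nmr / 1000.0


@dataclass(frozen=True)
class CauseProfile:
    """Cause-of-death composition of baseline neonatal mortality.

    ``shares`` maps cause label to its share of all neonatal deaths; shares
    must sum to one.  Causes without any mapped intervention simply see no
    mortality reduction.
    """

    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        _require(len(self.shares) > 0, "cause profile must not be empty")
        for cause, s in self.shares.items():
            _require(0.0 <= s <= 1.0, f"share for cause {cause!r} must be in [0, 1]")
        total = sum(self.shares.values())
        _require(abs(total - 1.0) <= 1e-9, f"cause shares must sum to 1 (got {total!r})")
        object.__setattr__(self, "shares", dict(self.shares))


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention acting on one cause of death.

    ``effectiveness`` is the proportional cause-specific mortality reduction
    at full coverage; ``affected_fraction`` the share of cause deaths the
    intervention can plausibly act on.
    """

    name: str
    cause: str
    effectiveness: float
    affected_fraction: float
    baseline_coverage: float
    target_coverage: float

    def __post_init__(self) -> None:
        for f in ("effectiveness", "affected_fraction", "baseline_coverage", "target_coverage"):
            v = getattr(self, f)
            _require(0.0 <= v <= 1.0, f"{f} must be in [0, 1] for {self.name!r}")
        _require(
            self.target_coverage >= self.baseline_coverage,
            f"target_coverage < baseline_coverage for {self.name!r}",
        )

    @property
    def potency(self) -> float:
        """Effectiveness × affected fraction: cause-death reduction at cov=1."""
        return self.effectiveness * self.affected_fraction


@dataclass(frozen=True)
class CoverageTrajectory:
    """Coverage by calendar year, non-decreasing from baseline to target."""

    start_year: int
    end_year: int
    coverage_by_year: Mapping[int, float]

    def __post_init__(self) -> None:
        _require(self.end_year > self.start_year, "end_year must be after start_year")
        years = sorted(self.coverage_by_year)
        _require(
            years == list(range(self.start_year, self.end_year + 1)),
            "coverage_by_year must cover every year from start_year to end_year",
        )
        covs = [self.coverage_by_year[y] for y in years]
        for c in covs:
            _require(0.0 <= c <= 1.0, "coverage values must be in [0, 1]")
        _require(
            all(b >= a - 1e-12 for a, b in zip(covs, covs[1:])),
            "coverage must be non-decreasing over years",
        )
        object.__setattr__(self, "coverage_by_year", dict(self.coverage_by_year))

    def coverage(self, year: int) -> float:
        """Coverage at ``year``, held flat outside [start_year, end_year]."""
        if year <= self.start_year:
            return self.coverage_by_year[self.start_year]
        if year >= self.end_year:
            return self.coverage_by_year[self.end_year]
        return self.coverage_by_year[year]


@dataclass(frozen=True)
class ImpactProjection:
    """Deterministic mortality projection under coverage scale-up."""

    annual_deaths: Mapping[int, float]
    annual_deaths_averted: Mapping[int, float]
    cumulative_lives_saved: Mapping[int, float]
    nmr_by_year: Mapping[int, float]
    lives_saved_by_cause: Mapping[str, float]

    def __post_init__(self) -> None:
        years = sorted(self.annual_deaths)
        _require(len(years) > 0, "projection must cover at least one year")
        for m in (self.annual_deaths_averted, self.cumulative_lives_saved, self.nmr_by_year):
            _require(sorted(m) == years, "all per-year series must share the same years")
        running = 0.0
        for y in years:
            _require(self.annual_deaths_averted[y] >= -1e-9, "deaths averted must be >= 0")
            running += self.annual_deaths_averted[y]
            _require(
                abs(self.cumulative_lives_saved[y] - running) <= 1e-6 * max(1.0, running),
                "cumulative_lives_saved must be the running sum of annual_deaths_averted",
            )
        by_cause = sum(self.lives_saved_by_cause.values())
        _require(
            abs(by_cause - 1.0) <= 1e-9 or abs(by_cause) <= 1e-12,
            "lives_saved_by_cause must sum to 1 (or all zero when nothing is averted)",
        )

    @property
    def years(self) -> list[int]:
        return sorted(self.annual_deaths)


@dataclass(frozen=True)
class HospitalArchetype:
    level: str  # "district" | "regional"
    bed_capacity: int  # cots
    count_in_rollout: int

    def __post_init__(self) -> None:
        _require(self.bed_capacity > 0, "bed_capacity must be positive")
        _require(self.count_in_rollout >= 0, "count_in_rollout must be >= 0")


@dataclass(frozen=True)
class CostItem:
    """One catalogue line: unit cost × quantity per hospital of ``level``."""

    name: str
    category: str
    kind: str  # "setup" | "running"
    level: str
    unit_cost: float  # USD
    quantity: float  # per hospital
    useful_life: Optional[float] = None  # years; required for setup items

    def __post_init__(self) -> None:
        _require(self.category in CATEGORIES, f"unknown category {self.category!r}")
        _require(self.kind in ("setup", "running"), f"kind must be setup|running, got {self.kind!r}")
        _require(self.unit_cost >= 0, f"unit_cost must be >= 0 for {self.name!r}")
        _require(self.quantity >= 0, f"quantity must be >= 0 for {self.name!r}")
        if self.kind == "setup":
            _require(
                self.useful_life is not None and self.useful_life > 0,
                f"setup item {self.name!r} needs useful_life > 0",
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """Scale-up scenario rules.

    Scenario A builds everything new (new_fraction=1, acquire all items);
    scenario B builds half new and renovates the rest at
    ``renovation_cost_fraction`` of a new build, acquiring half of the items.
    """

    name: str
    new_fraction: float
    renovation_cost_fraction: float
    item_acquisition_fraction: float
    staffing_policy: str

    def __post_init__(self) -> None:
        for f in ("new_fraction", "renovation_cost_fraction", "item_acquisition_fraction"):
            v = getattr(self, f)
            _require(0.0 <= v <= 1.0, f"{f} must be in [0, 1]")

    @property
    def infrastructure_cost_fraction(self) -> float:
        """Expected infrastructure cost as a fraction of an all-new build."""
        return self.new_fraction + (1.0 - self.new_fraction) * self.renovation_cost_fraction


@dataclass(frozen=True)
class StaffingEntry:
    """Incremental staffing for one cadre at one hospital level and scenario."""

    cadre: str
    level: str
    scenario: str
    count: float  # persons per hospital ("not charged" cells are 0)
    monthly_salary: float  # USD

    def __post_init__(self) -> None:
        _require(self.count >= 0, f"count must be >= 0 for {self.cadre!r}")
        _require(self.monthly_salary >= 0, f"negative salary for {self.cadre!r}")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category costs with the equivalent-annual view.

    For setup breakdowns ``annualised_total`` is the sum of per-category
    equivalent annual costs; running costs are already annual and pass
    through unchanged.
    """

    per_category: Mapping[str, float]
    total: float
    annualised_total: float

    def __post_init__(self) -> None:
        s = sum(self.per_category.values())
        _require(abs(s - self.total) <= 1e-6 * max(1.0, abs(s)), "total must equal sum of categories")
        object.__setattr__(self, "per_category", dict(self.per_category))

    def category_shares(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in self.per_category}
        return {c: v / self.total for c, v in self.per_category.items()}


@dataclass(frozen=True)
class CostRules:
    discount_rate: float = 0.03  # per year, for capital annualisation
    markup_consumables: float = 0.10  # over economic order quantity, supplies only
    maintenance_rate: float = 0.03  # of setup cost, per year

    def __post_init__(self) -> None:
        _require(self.discount_rate >= 0, "discount_rate must be >= 0")
        _require(self.markup_consumables >= 0, "markup_consumables must be >= 0")
        _require(self.maintenance_rate >= 0, "maintenance_rate must be >= 0")


@dataclass(frozen=True)
class LevelCosts:
    """Per-hospital and fleet costs for one hospital level."""

    archetype: HospitalArchetype
    setup: CostBreakdown  # per hospital
    running: CostBreakdown  # per hospital, per year
    annualised_per_hospital: float  # running + annualised setup
    setup_total: float
    running_total: float
    annualised_total: float


@dataclass(frozen=True)
class NationalCosts:
    per_level: Mapping[str, LevelCosts]
    setup_total: float
    running_total: float
    annualised_total: float


@dataclass(frozen=True)
class ImplementationSchedule:
    """Fraction of the full annual running cost incurred in each year."""

    fraction_by_year: Mapping[int, float]

    def __post_init__(self) -> None:
        years = sorted(self.fraction_by_year)
        _require(len(years) > 0, "schedule must not be empty")
        fr = [self.fraction_by_year[y] for y in years]
        for f in fr:
            _require(0.0 < f <= 1.0, "schedule fractions must be in (0, 1]")
        _require(all(b >= a for a, b in zip(fr, fr[1:])), "schedule must be non-decreasing")
        _require(abs(fr[-1] - 1.0) <= 1e-12, "final schedule year must be 1.0")
        object.__setattr__(self, "fraction_by_year", dict(self.fraction_by_year))

    @property
    def years(self) -> list[int]:
        return sorted(self.fraction_by_year)


@dataclass(frozen=True)
class MonetisationSpec:
    """How averted life-years are valued.

    ``gdp_multiplier`` method values a life-year at multiplier × GDP per
    capita; ``vsl`` uses a value-of-statistical-life year directly.
    ``benefit_horizon_years`` is the lump-sum discounting horizon for future
    benefits (defaults to life expectancy when None).
    """

    method: str  # "gdp_multiplier" | "vsl"
    gdp_per_capita: float
    gdp_multiplier: float = 2.3
    vsl_year: float = 0.0
    gdp_growth: float = 0.03
    discount_rate: float = 0.03
    labour_entry_age: float = 20.0
    productive_years: float = 46.0
    benefit_horizon_years: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.method in ("gdp_multiplier", "vsl"), f"unknown method {self.method!r}")
        _require(self.discount_rate >= 0, "discount_rate must be >= 0")
        _require(self.gdp_per_capita > 0, "gdp_per_capita must be > 0")


@dataclass(frozen=True)
class ROIInputs:
    """Cost-side inputs to the ROI stage.

    ``annualised_setup`` gives equivalent annual capital costs by category;
    ``full_annual_running`` the steady-state annual running cost once every
    unit operates.
    """

    annualised_setup: Mapping[str, float]
    full_annual_running: float

    def __post_init__(self) -> None:
        for c, v in self.annualised_setup.items():
            _require(v >= 0, f"annualised setup for {c!r} must be >= 0")
        _require(self.full_annual_running >= 0, "full_annual_running must be >= 0")
        object.__setattr__(self, "annualised_setup", dict(self.annualised_setup))

    @property
    def annualised_setup_total(self) -> float:
        return sum(self.annualised_setup.values())


@dataclass(frozen=True)
class ROIResult:
    setup_costs_to_horizon: float
    running_costs_to_horizon: float
    total_costs_pv: float
    yll_averted: float
    social_benefit_fv: float
    social_benefit_pv: float
    productivity_fv: float
    productivity_pv: float
    roi_total: float
    cost_per_death_averted: float

    def __post_init__(self) -> None:
        for f in (
            "setup_costs_to_horizon",
            "running_costs_to_horizon",
            "total_costs_pv",
            "yll_averted",
            "social_benefit_fv",
            "social_benefit_pv",
            "productivity_fv",
            "productivity_pv",
            "roi_total",
            "cost_per_death_averted",
        ):
            _require(getattr(self, f) >= 0, f"{f} must be non-negative")
        expected = (self.social_benefit_pv + self.productivity_pv) / self.total_costs_pv
        _require(
            abs(self.roi_total - expected) <= 1e-9 * max(1.0, expected),
            "roi_total must equal (social_pv + productivity_pv) / total_costs_pv",
        )
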