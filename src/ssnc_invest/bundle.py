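"""Configuration bundle: everything one country/scenario analysis needs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .impact import build_trajectory
from .types import (
    CauseProfile,
    CostItem,
    CostRules,
    CountryProfile,
    CoverageTrajectory,
    HospitalArchetype,
    ImplementationSchedule,
    InterventionSpec,
    MonetisationSpec,
    ROIInputs,
    ScenarioSpec,
    StaffingEntry,
    ValidationError,
)

__all__ = ["Bundle", "validate_bundle", "check_bundle", "BundleValidationError"]


class BundleValidationError(ValidationError):
    """Raised with the full list of invariant failures in a bundle."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("bundle validation failed:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass(frozen=True)
class Bundle:
    """One country configuration: demography, interventions, catalogues,
    scenario rules, implementation schedule and monetisation parameters.

    ``start_year``/``end_year`` delimit the coverage scale-up window;
    analyses may evaluate any horizon inside it.
    """

    name: str
    country: CountryProfile
    causes: CauseProfile
    interventions: Sequence[InterventionSpec]
    archetypes: Sequence[HospitalArchetype]
    scenarios: Mapping[str, ScenarioSpec]
    cost_rules: CostRules
    catalogue: Sequence[CostItem]
    staffing: Sequence[StaffingEntry]
    schedule: ImplementationSchedule
    monetisation: MonetisationSpec
    roi_inputs: ROIInputs
    start_year: int = 2021
    end_year: int = 2030

    def __post_init__(self) -> None:
        object.__setattr__(self, "interventions", tuple(self.interventions))
        object.__setattr__(self, "archetypes", tuple(self.archetypes))
        object.__setattr__(self, "catalogue", tuple(self.catalogue))
        object.__setattr__(self, "staffing", tuple(self.staffing))
        object.__setattr__(self, "scenarios", dict(self.scenarios))

    def trajectories(
        self, start_year: int | None = None, end_year: int | None = None
    ) -> dict[str, CoverageTrajectory]:
        """Linear coverage ramps for every intervention over the scale-up
        window (or an override window, e.g. the shorter national-target one).
        """
        s = self.start_year if start_year is None else start_year
        e = self.end_year if end_year is None else end_year
        return {
            iv.name: build_trajectory(iv.baseline_coverage, iv.target_coverage, s, e)
            for iv in self.interventions
        }


def validate_bundle(bundle: Bundle) -> list[str]:
    """Cross-object invariant checks; returns a list of failure messages.

    Per-object invariants are enforced at construction time, so this
    focuses on references between parts of the bundle.
    """
    errors: list[str] = []
    causes = set(bundle.causes.shares)
    for iv in bundle.interventions:
        if iv.cause not in causes:
            errors.append(f"intervention {iv.name!r} references unknown cause {iv.cause!r}")
    levels = {a.level for a in bundle.archetypes}
    for it in bundle.catalogue:
        if it.level not in levels:
            errors.append(f"cost item {it.name!r} references unknown level {it.level!r}")
    policies = {s.staffing_policy for s in bundle.scenarios.values()}
    staffing_keys = {(e.level, e.scenario) for e in bundle.staffing}
    for level in levels:
        for pol in policies:
            if (level, pol) not in staffing_keys:
                errors.append(f"no staffing rows for level {level!r} under policy {pol!r}")
    if bundle.end_year <= bundle.start_year:
        errors.append("end_year must be after start_year")
    sched_years = bundle.schedule.years
    if sched_years[0] < bundle.start_year:
        errors.append("implementation schedule starts before the scale-up window")
    return errors


def check_bundle(bundle: Bundle) -> Bundle:
    """Raise :class:`BundleValidationError` listing every failed invariant."""
    errors = validate_bundle(bundle)
    if errors:
        raise BundleValidationError(errors)
    return bundle
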