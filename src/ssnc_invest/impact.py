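"""Deterministic lives-saved projection under intervention coverage scale-up.

The model follows the logic of cause-specific mortality tools such as the
Lives Saved Tool: baseline neonatal deaths are split across causes, each
intervention reduces the deaths of its cause in proportion to
effectiveness × affected fraction × coverage, and interventions sharing a
cause are combined multiplicatively on the residual mortality so that no
death is averted twice.  Births and the cause structure are held constant
over the projection horizon; only coverage changes.

For one cause with interventions i the mortality reduction at time t,
relative to baseline coverage c_i(t0), is

    R(t) = 1 - prod_i(1 - e_i * AF_i * c_i(t)) / prod_i(1 - e_i * AF_i * c_i(t0))

clipped to [0, 1).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

from .types import (
    CauseProfile,
    CountryProfile,
    CoverageTrajectory,
    ImpactProjection,
    InterventionSpec,
    ValidationError,
)

__all__ = [
    "build_trajectory",
    "cause_mortality_reduction",
    "project_impact",
    "percent_deaths_averted",
    "halve_effectiveness",
]


def build_trajectory(
    baseline: float,
    target: float,
    start_year: int,
    end_year: int,
    shape: str = "linear",
) -> CoverageTrajectory:
    """Interpolate coverage from ``baseline`` at ``start_year`` to ``target``
    at ``end_year``.

    Only ``shape="linear"`` is implemented; the argument exists so other
    ramp shapes can be added without changing call sites.
    """
    if shape != "linear":
        raise ValidationError(f"unsupported trajectory shape {shape!r}")
    if end_year <= start_year:
        raise ValidationError("end_year must be after start_year")
    if target < baseline:
        raise ValidationError("target coverage must be >= baseline coverage")
    span = end_year - start_year
    coverage = {
        y: baseline + (target - baseline) * (y - start_year) / span
        for y in range(start_year, end_year + 1)
    }
    return CoverageTrajectory(start_year=start_year, end_year=end_year, coverage_by_year=coverage)


def _residual(interventions: Sequence[InterventionSpec], coverage: Mapping[str, float]) -> float:
    """prod_i (1 - potency_i * coverage_i); errors if any factor <= 0."""
    res = 1.0
    for iv in interventions:
        load = iv.potency * coverage[iv.name]
        if load >= 1.0:
            raise ValidationError(
                f"effectiveness x affected_fraction x coverage >= 1 for {iv.name!r} "
                "(implies negative residual mortality)"
            )
        res *= 1.0 - load
    return res


def cause_mortality_reduction(
    interventions_on_cause: Sequence[InterventionSpec],
    coverage_at_t: Mapping[str, float],
    coverage_at_baseline: Mapping[str, float],
) -> float:
    """Combined proportional mortality reduction for one cause.

    Residual-mortality product form relative to baseline coverage; the
    multiplicative combination guarantees the joint reduction never exceeds
    the sum of individual reductions (no double counting) and stays < 1.
    """
    causes = {iv.cause for iv in interventions_on_cause}
    if len(causes) > 1:
        raise ValidationError(f"interventions must share one cause, got {sorted(causes)}")
    for cov in (coverage_at_t, coverage_at_baseline):
        for iv in interventions_on_cause:
            c = cov[iv.name]
            if not 0.0 <= c <= 1.0:
                raise ValidationError(f"coverage for {iv.name!r} must be in [0, 1]")
    num = _residual(interventions_on_cause, coverage_at_t)
    den = _residual(interventions_on_cause, coverage_at_baseline)
    return min(max(1.0 - num / den, 0.0), 1.0 - 1e-15)


def project_impact(
    profile: CountryProfile,
    causes: CauseProfile,
    interventions: Sequence[InterventionSpec],
    trajectories: Mapping[str, CoverageTrajectory],
    horizon: int,
) -> ImpactProjection:
    """Project annual deaths, deaths averted and NMR to ``horizon``.

    Baseline-year cause deaths are held constant (constant births, no
    secular mortality trend); all change comes from coverage scale-up.
    """
    for iv in interventions:
        if iv.cause not in causes.shares:
            raise ValidationError(f"intervention {iv.name!r} maps to unknown cause {iv.cause!r}")
        if iv.name not in trajectories:
            raise ValidationError(f"no coverage trajectory for intervention {iv.name!r}")

    start_year = min(t.start_year for t in trajectories.values()) if trajectories else horizon
    if horizon < start_year:
        raise ValidationError("horizon precedes the first trajectory year")

    base_deaths = profile.baseline_annual_deaths
    by_cause: dict[str, list[InterventionSpec]] = {}
    for iv in interventions:
        by_cause.setdefault(iv.cause, []).append(iv)

    cov0 = {iv.name: trajectories[iv.name].coverage(start_year) for iv in interventions}

    annual_deaths: dict[int, float] = {}
    annual_averted: dict[int, float] = {}
    cumulative: dict[int, float] = {}
    nmr: dict[int, float] = {}
    averted_by_cause: dict[str, float] = {c: 0.0 for c in by_cause}

    running = 0.0
    for year in range(start_year, horizon + 1):
        cov_t = {iv.name: trajectories[iv.name].coverage(year) for iv in interventions}
        averted = 0.0
        for cause, ivs in by_cause.items():
            r = cause_mortality_reduction(ivs, cov_t, cov0)
            a = base_deaths * causes.shares[cause] * r
            averted += a
            averted_by_cause[cause] += a
        deaths = base_deaths - averted
        running += averted
        annual_deaths[year] = deaths
        annual_averted[year] = averted
        cumulative[year] = running
        nmr[year] = deaths / profile.annual_births * 1000.0

    total = sum(averted_by_cause.values())
    if total > 0:
        lives_by_cause = {c: v / total for c, v in averted_by_cause.items()}
        # normalise away accumulated float error
        s = sum(lives_by_cause.values())
        lives_by_cause = {c: v / s for c, v in lives_by_cause.items()}
    else:
        lives_by_cause = {c: 0.0 for c in averted_by_cause}

    return ImpactProjection(
        annual_deaths=annual_deaths,
        annual_deaths_averted=annual_averted,
        cumulative_lives_saved=cumulative,
        nmr_by_year=nmr,
        lives_saved_by_cause=lives_by_cause,
    )


def percent_deaths_averted(projection: ImpactProjection, year: int) -> float:
    """Deaths averted in ``year`` as a proportion of counterfactual deaths."""
    if year not in projection.annual_deaths:
        raise ValidationError(f"year {year} outside projection horizon")
    baseline = projection.annual_deaths[year] + projection.annual_deaths_averted[year]
    if baseline == 0:
        return 0.0
    return projection.annual_deaths_averted[year] / baseline


def halve_effectiveness(
    interventions: Iterable[InterventionSpec],
    exempt: Iterable[str] = (),
) -> list[InterventionSpec]:
    """Multiply effectiveness by 0.5 except for ``exempt`` intervention names.

    Used for the lower-quality-of-care sensitivity scenario, where
    low-impact supportive-care interventions keep their effectiveness.
    """
    exempt_set = set(exempt)
    out = []
    for iv in interventions:
        if iv.name in exempt_set:
            out.append(iv)
        else:
            out.append(replace(iv, effectiveness=iv.effectiveness * 0.5))
    return out


def sequential_reduction_oracle(
    interventions_on_cause: Sequence[InterventionSpec],
    coverage_at_t: Mapping[str, float],
    coverage_at_baseline: Mapping[str, float],
) -> float:
    """Brute-force sequential application, one intervention at a time.

    Each intervention scales the residual deaths of its cause by
    (1 - potency*cov_t) / (1 - potency*cov_t0); the surviving fraction after
    all interventions gives the combined reduction.  Kept separate from
    :func:`cause_mortality_reduction` as an independent cross-check.
    """
    surviving = 1.0
    for iv in interventions_on_cause:
        surviving *= (1.0 - iv.potency * coverage_at_t[iv.name]) / (
            1.0 - iv.potency * coverage_at_baseline[iv.name]
        )
    return 1.0 - surviving


def required_cots(profile: CountryProfile, occupancy: float = 0.85) -> float:
    """Rough national cot requirement implied by need and admission length.

    births × need fraction × mean stay / (365 × occupancy).  Informational
    planning aid; not used by the mortality or cost engines.
    """
    if not 0 < occupancy <= 1:
        raise ValidationError("occupancy must be in (0, 1]")
    admissions = profile.annual_births * profile.ssnc_need_fraction
    return admissions * profile.mean_admission_days / (365.0 * occupancy)
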