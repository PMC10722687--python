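"""Five-step pipeline driver: impact → costing → ROI → budget impact.

``run_pipeline`` validates a bundle, runs every stage for one scenario and
writes the result tables (impact CSV, cost CSVs, ROI and budget-impact
JSON, plus a human-readable summary).  Outputs are written at full
precision and with sorted keys, so re-running an identical configuration
produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bundle import Bundle, check_bundle
from .costing import national_category_totals, national_rollout
from .impact import percent_deaths_averted, project_impact
from .io import projection_frame, read_bundle
from .roi import budget_impact, roi_analysis, sensitivity_suite
from .types import NationalCosts, ROIResult, ValidationError

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "compare_scenarios"]


@dataclass(frozen=True)
class RunConfig:
    bundle_path: str | Path
    scenario: str = "A"
    horizon: int | None = None
    monetisation_method: str | None = None
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class PipelineReport:
    bundle: Bundle
    scenario: str
    horizon: int
    projection: object
    national: NationalCosts
    roi: ROIResult
    budget: dict
    sensitivity: dict


def _load(config: RunConfig) -> Bundle:
    bundle = (
        config.bundle_path
        if isinstance(config.bundle_path, Bundle)
        else read_bundle(config.bundle_path)
    )
    return check_bundle(bundle)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage and (optionally) write the report bundle."""
    bundle = _load(config)
    horizon = config.horizon if config.horizon is not None else bundle.end_year
    scenario = bundle.scenarios[config.scenario]

    projection = project_impact(
        bundle.country,
        bundle.causes,
        bundle.interventions,
        bundle.trajectories(end_year=horizon),
        horizon,
    )
    national = national_rollout(
        bundle.archetypes, bundle.catalogue, bundle.staffing, scenario, bundle.cost_rules
    )
    roi = roi_analysis(bundle, horizon=horizon, method=config.monetisation_method)
    budget = budget_impact(national.annualised_total, bundle.country)
    sensitivity = sensitivity_suite(bundle, horizon=horizon)

    report = PipelineReport(
        bundle=bundle,
        scenario=config.scenario,
        horizon=horizon,
        projection=projection,
        national=national,
        roi=roi,
        budget=budget,
        sensitivity=sensitivity,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def _roi_dict(roi: ROIResult) -> dict:
    return {
        "setup_costs_to_horizon": roi.setup_costs_to_horizon,
        "running_costs_to_horizon": roi.running_costs_to_horizon,
        "total_costs_to_horizon": roi.total_costs_pv,
        "yll_averted": roi.yll_averted,
        "social_benefit_fv": roi.social_benefit_fv,
        "social_benefit_pv": roi.social_benefit_pv,
        "productivity_fv": roi.productivity_fv,
        "productivity_pv": roi.productivity_pv,
        "roi_total": roi.roi_total,
        "cost_per_death_averted": roi.cost_per_death_averted,
    }


def write_report(report: PipelineReport, output_dir: str | Path) -> Path:
    """Write impact CSV, cost CSVs, ROI/budget JSON and a text summary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    projection_frame(report.projection).to_csv(out / "impact_projection.csv", index=False)

    rows = []
    for level, lc in sorted(report.national.per_level.items()):
        for kind, bd in (("setup", lc.setup), ("running", lc.running)):
            for cat, value in sorted(bd.per_category.items()):
                rows.append(
                    {
                        "level": level,
                        "kind": kind,
                        "category": cat,
                        "per_hospital_usd": value,
                        "national_usd": value * lc.archetype.count_in_rollout,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "cost_breakdown.csv", index=False)

    roi_payload = {
        "scenario": report.scenario,
        "horizon": report.horizon,
        "roi": _roi_dict(report.roi),
        "sensitivity": {
            "vsl": _roi_dict(report.sensitivity["vsl"]),
            "coverage_scaled_running": _roi_dict(report.sensitivity["coverage_scaled_running"]),
            "halved_effectiveness": report.sensitivity["halved_effectiveness"],
        },
    }
    (out / "roi.json").write_text(json.dumps(roi_payload, indent=2, sort_keys=True) + "\n")
    (out / "budget_impact.json").write_text(
        json.dumps(report.budget, indent=2, sort_keys=True) + "\n"
    )
    (out / "summary.txt").write_text(render_summary(report))
    return out


def render_summary(report: PipelineReport) -> str:
    """Human-readable account mirroring the published result tables."""
    b = report.bundle
    horizon = report.horizon
    proj = report.projection
    roi = report.roi
    lines = [
        f"SSNC investment case — bundle {b.name!r}, scenario {report.scenario}, "
        f"horizon {horizon}",
        "",
        "Impact",
        f"  Baseline annual neonatal deaths: {b.country.baseline_annual_deaths:,.0f}",
        f"  Cumulative lives saved by {horizon}: {proj.cumulative_lives_saved[horizon]:,.0f}",
        f"  NMR {b.start_year}: {proj.nmr_by_year[b.start_year]:.1f}  ->  "
        f"{horizon}: {proj.nmr_by_year[horizon]:.1f} per 1000 live births",
        f"  Deaths averted in {horizon}: {percent_deaths_averted(proj, horizon):.1%}",
        "",
        "Costs (national)",
        f"  One-off setup: {report.national.setup_total:,.0f}",
        f"  Annual running (steady state): {report.national.running_total:,.0f}",
        f"  Total annualised: {report.national.annualised_total:,.0f}",
    ]
    for level, lc in sorted(report.national.per_level.items()):
        lines.append(
            f"    {level}: setup {lc.setup.total:,.0f}/hospital, "
            f"running {lc.running.total:,.0f}/yr, "
            f"annualised {lc.annualised_per_hospital:,.0f}/yr "
            f"x {lc.archetype.count_in_rollout} hospitals"
        )
    lines += [
        "",
        "Return on investment (setup + phased running, to horizon)",
        f"  Annualised setup costs: {b.roi_inputs.annualised_setup_total:,.0f}/yr  "
        f"-> {roi.setup_costs_to_horizon:,.0f}",
        f"  Phased running costs: {roi.running_costs_to_horizon:,.0f}",
        f"  Total costs: {roi.total_costs_pv:,.0f}",
        f"  Years of life saved: {roi.yll_averted:,.0f}",
        f"  Monetised benefit (future value): {roi.social_benefit_fv:,.0f}",
        f"  Monetised benefit (present value): {roi.social_benefit_pv:,.2f}",
        f"  Productivity gains (present value): {roi.productivity_pv:,.2f}",
        f"  ROI: {roi.roi_total:.2f} per dollar invested",
        f"  Cost per death averted: {roi.cost_per_death_averted:,.0f}",
        "",
        "Budget impact",
        f"  Cost per capita: {report.budget['cost_per_capita']:.2f}",
        f"  Cost per live birth: {report.budget['cost_per_birth']:.2f}",
        f"  Share of total health expenditure per capita: "
        f"{report.budget['share_of_the']:.1%}",
        "",
    ]
    return "\n".join(lines)


def compare_scenarios(config_a: RunConfig, config_b: RunConfig) -> dict:
    """Side-by-side national cost deltas between two scenarios of one bundle.

    Returns per-category and total (A − B) deltas for setup and running
    costs; raises if the two configs point at different bundles.
    """
    if str(config_a.bundle_path) != str(config_b.bundle_path) and not (
        isinstance(config_a.bundle_path, Bundle)
        and isinstance(config_b.bundle_path, Bundle)
        and config_a.bundle_path is config_b.bundle_path
    ):
        raise ValidationError("scenario comparison requires the same bundle")
    bundle = _load(config_a)
    nat = {
        key: national_rollout(
            bundle.archetypes,
            bundle.catalogue,
            bundle.staffing,
            bundle.scenarios[cfg.scenario],
            bundle.cost_rules,
        )
        for key, cfg in (("a", config_a), ("b", config_b))
    }
    delta: dict[str, dict] = {"scenario_a": config_a.scenario, "scenario_b": config_b.scenario}
    for kind in ("setup", "running"):
        cats_a = national_category_totals(nat["a"], kind)
        cats_b = national_category_totals(nat["b"], kind)
        delta[kind] = {
            "a": dict(sorted(cats_a.items())),
            "b": dict(sorted(cats_b.items())),
            "delta": {c: cats_a[c] - cats_b.get(c, 0.0) for c in sorted(cats_a)},
        }
    delta["totals"] = {
        "setup": {"a": nat["a"].setup_total, "b": nat["b"].setup_total},
        "running": {"a": nat["a"].running_total, "b": nat["b"].running_total},
        "annualised": {"a": nat["a"].annualised_total, "b": nat["b"].annualised_total},
        "one_off_plus_first_year_running": {
            "a": nat["a"].setup_total + nat["a"].running_total,
            "b": nat["b"].setup_total + nat["b"].running_total,
        },
    }
    return delta
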