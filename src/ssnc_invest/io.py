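"""Reading and writing configuration bundles and result tables.

A bundle on disk is a directory of CSV catalogues plus one structured
``config.yaml`` and a ``manifest.json`` listing every file with its SHA-256
content hash.  Floats are written at full precision so a written bundle
re-reads equal to the original.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .bundle import Bundle
from .types import (
    CauseProfile,
    CostItem,
    CostRules,
    CountryProfile,
    HospitalArchetype,
    ImplementationSchedule,
    InterventionSpec,
    MonetisationSpec,
    ROIInputs,
    ScenarioSpec,
    StaffingEntry,
    ValidationError,
)

__all__ = ["write_bundle", "read_bundle", "projection_frame"]

_BUNDLE_FILES = (
    "config.yaml",
    "interventions.csv",
    "cause_shares.csv",
    "cost_catalogue.csv",
    "staffing.csv",
    "rollout.csv",
    "schedule.csv",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: Bundle, path: str | Path) -> Path:
    """Serialise ``bundle`` into directory ``path``; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    config = {
        "name": bundle.name,
        "start_year": bundle.start_year,
        "end_year": bundle.end_year,
        "country": {
            "population": bundle.country.population,
            "annual_births": bundle.country.annual_births,
            "baseline_nmr": bundle.country.baseline_nmr,
            "life_expectancy": bundle.country.life_expectancy,
            "gdp_per_capita": bundle.country.gdp_per_capita,
            "the_per_capita": bundle.country.the_per_capita,
            "ssnc_need_fraction": bundle.country.ssnc_need_fraction,
            "mean_admission_days": bundle.country.mean_admission_days,
        },
        "cost_rules": {
            "discount_rate": bundle.cost_rules.discount_rate,
            "markup_consumables": bundle.cost_rules.markup_consumables,
            "maintenance_rate": bundle.cost_rules.maintenance_rate,
        },
        "scenarios": {
            key: {
                "new_fraction": s.new_fraction,
                "renovation_cost_fraction": s.renovation_cost_fraction,
                "item_acquisition_fraction": s.item_acquisition_fraction,
                "staffing_policy": s.staffing_policy,
            }
            for key, s in sorted(bundle.scenarios.items())
        },
        "monetisation": {
            "method": bundle.monetisation.method,
            "gdp_per_capita": bundle.monetisation.gdp_per_capita,
            "gdp_multiplier": bundle.monetisation.gdp_multiplier,
            "vsl_year": bundle.monetisation.vsl_year,
            "gdp_growth": bundle.monetisation.gdp_growth,
            "discount_rate": bundle.monetisation.discount_rate,
            "labour_entry_age": bundle.monetisation.labour_entry_age,
            "productive_years": bundle.monetisation.productive_years,
            "benefit_horizon_years": bundle.monetisation.benefit_horizon_years,
        },
        "roi_inputs": {
            "annualised_setup": dict(sorted(bundle.roi_inputs.annualised_setup.items())),
            "full_annual_running": bundle.roi_inputs.full_annual_running,
        },
    }
    (path / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    pd.DataFrame(
        [
            {
                "name": iv.name,
                "cause": iv.cause,
                "effectiveness": iv.effectiveness,
                "affected_fraction": iv.affected_fraction,
                "baseline_coverage": iv.baseline_coverage,
                "target_coverage": iv.target_coverage,
            }
            for iv in bundle.interventions
        ]
    ).to_csv(path / "interventions.csv", index=False)

    pd.DataFrame(
        [{"cause": c, "share_of_deaths": s} for c, s in sorted(bundle.causes.shares.items())]
    ).to_csv(path / "cause_shares.csv", index=False)

    pd.DataFrame(
        [
            {
                "item": it.name,
                "category": it.category,
                "kind": it.kind,
                "level": it.level,
                "unit_cost_usd": it.unit_cost,
                "quantity": it.quantity,
                "useful_life_years": it.useful_life,
            }
            for it in bundle.catalogue
        ]
    ).to_csv(path / "cost_catalogue.csv", index=False)

    pd.DataFrame(
        [
            {
                "cadre": e.cadre,
                "level": e.level,
                "scenario": e.scenario,
                "count": e.count,
                "monthly_salary_usd": e.monthly_salary,
            }
            for e in bundle.staffing
        ]
    ).to_csv(path / "staffing.csv", index=False)

    pd.DataFrame(
        [
            {"level": a.level, "bed_capacity": a.bed_capacity, "count": a.count_in_rollout}
            for a in bundle.archetypes
        ]
    ).to_csv(path / "rollout.csv", index=False)

    pd.DataFrame(
        [{"year": y, "fraction": f} for y, f in sorted(bundle.schedule.fraction_by_year.items())]
    ).to_csv(path / "schedule.csv", index=False)

    manifest = {name: _sha256(path / name) for name in _BUNDLE_FILES}
    (path / "manifest.json").write_text(json.dumps({"files": manifest}, indent=2, sort_keys=True) + "\n")
    return path


def read_bundle(path: str | Path) -> Bundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    missing = [n for n in _BUNDLE_FILES if not (path / n).exists()]
    if missing:
        raise ValidationError(f"bundle at {path} is missing files: {missing}")

    config = yaml.safe_load((path / "config.yaml").read_text())
    country = CountryProfile(**config["country"])
    rules = CostRules(**config["cost_rules"])
    scenarios = {
        key: ScenarioSpec(name=key, **fields) for key, fields in config["scenarios"].items()
    }
    monetisation = MonetisationSpec(**config["monetisation"])
    roi_inputs = ROIInputs(**config["roi_inputs"])

    iv_df = pd.read_csv(path / "interventions.csv", float_precision="round_trip")
    interventions = [
        InterventionSpec(
            row["name"],
            row["cause"],
            float(row["effectiveness"]),
            float(row["affected_fraction"]),
            float(row["baseline_coverage"]),
            float(row["target_coverage"]),
        )
        for _, row in iv_df.iterrows()
    ]

    shares_df = pd.read_csv(path / "cause_shares.csv", float_precision="round_trip")
    causes = CauseProfile(dict(zip(shares_df["cause"], shares_df["share_of_deaths"].astype(float))))

    cat_df = pd.read_csv(path / "cost_catalogue.csv", float_precision="round_trip")
    catalogue = [
        CostItem(
            row["item"],
            row["category"],
            row["kind"],
            row["level"],
            float(row["unit_cost_usd"]),
            float(row["quantity"]),
            None if math.isnan(row["useful_life_years"]) else float(row["useful_life_years"]),
        )
        for _, row in cat_df.iterrows()
    ]

    staff_df = pd.read_csv(path / "staffing.csv", float_precision="round_trip")
    staffing = [
        StaffingEntry(
            row["cadre"],
            row["level"],
            row["scenario"],
            float(row["count"]),
            float(row["monthly_salary_usd"]),
        )
        for _, row in staff_df.iterrows()
    ]

    roll_df = pd.read_csv(path / "rollout.csv", float_precision="round_trip")
    archetypes = [
        HospitalArchetype(row["level"], int(row["bed_capacity"]), int(row["count"]))
        for _, row in roll_df.iterrows()
    ]

    sched_df = pd.read_csv(path / "schedule.csv", float_precision="round_trip")
    schedule = ImplementationSchedule(
        dict(zip(sched_df["year"].astype(int), sched_df["fraction"].astype(float)))
    )

    return Bundle(
        name=config["name"],
        country=country,
        causes=causes,
        interventions=interventions,
        archetypes=archetypes,
        scenarios=scenarios,
        cost_rules=rules,
        catalogue=catalogue,
        staffing=staffing,
        schedule=schedule,
        monetisation=monetisation,
        roi_inputs=roi_inputs,
        start_year=int(config["start_year"]),
        end_year=int(config["end_year"]),
    )


def projection_frame(projection) -> pd.DataFrame:
    """Tidy per-year table: year, deaths, deaths_averted, cumulative, NMR."""
    years = projection.years
    return pd.DataFrame(
        {
            "year": years,
            "deaths": [projection.annual_deaths[y] for y in years],
            "deaths_averted": [projection.annual_deaths_averted[y] for y in years],
            "cumulative_lives_saved": [projection.cumulative_lives_saved[y] for y in years],
            "nmr": [projection.nmr_by_year[y] for y in years],
        }
    )
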