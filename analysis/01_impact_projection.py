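"""Project lives saved from scaling level-2 newborn care in Tanzania.

Runs the deterministic cause-specific mortality model on the packaged
Tanzania configuration for both scale-up windows (2021-2025 national
target, 2021-2030 SDG) and writes the per-year projections to results/.
"""

from pathlib import Path

from ssnc_invest.impact import percent_deaths_averted, project_impact
from ssnc_invest.io import projection_frame
from ssnc_invest.synthetic import tanzania_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = tanzania_fixture()
    OUT.mkdir(exist_ok=True)
    print(f"Baseline: {bundle.country.baseline_annual_deaths:,.0f} neonatal deaths/year "
          f"(NMR {bundle.country.baseline_nmr:.0f}, {bundle.country.annual_births/1e6:.2f}M births)")

    for end in (2025, 2030):
        proj = project_impact(
            bundle.country,
            bundle.causes,
            bundle.interventions,
            bundle.trajectories(end_year=end),
            end,
        )
        frame = projection_frame(proj)
        frame.to_csv(OUT / f"impact_projection_{end}.csv", index=False)
        print(f"\nScale-up 2021-{end} (coverage 10% -> 85%):")
        print(f"  cumulative lives saved by {end}: {proj.cumulative_lives_saved[end]:,.0f}")
        print(f"  NMR by {end}: {proj.nmr_by_year[end]:.1f} per 1000 live births")
        print(f"  deaths averted in {end}: {percent_deaths_averted(proj, end):.0%}")
        shares = ", ".join(f"{c} {s:.0%}" for c, s in sorted(proj.lives_saved_by_cause.items(),
                                                             key=lambda kv: -kv[1]) if s > 0)
        print(f"  lives saved by cause: {shares}")


if __name__ == "__main__":
    main()
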