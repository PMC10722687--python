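"""Return on investment for scenario A to 2030: phased cost streams,
monetised life-years and the published sensitivity analyses.
Writes the ROI report to results/roi.json.
"""

import json
from pathlib import Path

from ssnc_invest.roi import sensitivity_suite
from ssnc_invest.synthetic import tanzania_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = tanzania_fixture()
    OUT.mkdir(exist_ok=True)
    suite = sensitivity_suite(bundle)
    base = suite["base"]

    print("Scenario A, 2021-2030, GDP-multiple monetisation:")
    print(f"  setup costs to 2030: {base.setup_costs_to_horizon:,.0f}")
    print(f"  phased running costs to 2030: {base.running_costs_to_horizon:,.0f}")
    print(f"  total costs: {base.total_costs_pv:,.0f}")
    print(f"  years of life saved: {base.yll_averted:,.0f}")
    print(f"  monetised benefit FV: {base.social_benefit_fv:,.0f}  "
          f"PV: {base.social_benefit_pv:,.2f}")
    print(f"  productivity gains PV: {base.productivity_pv:,.2f}")
    print(f"  ROI: {base.roi_total:.2f} per dollar; "
          f"cost per death averted: {base.cost_per_death_averted:,.0f}")
    print("\nSensitivity:")
    print(f"  VSL monetisation benefit FV: {suite['vsl'].social_benefit_fv:,.0f} "
          f"(ROI {suite['vsl'].roi_total:.2f})")
    print(f"  coverage-phased running costs total: "
          f"{suite['coverage_scaled_running'].total_costs_pv:,.0f}")
    halved = suite["halved_effectiveness"]
    print(f"  halved effectiveness: NMR stalls at {halved['nmr']:.1f} "
          f"per 1000 in {halved['target_year']}")

    payload = {
        "base": {k: getattr(base, k) for k in base.__dataclass_fields__},
        "vsl": {k: getattr(suite["vsl"], k) for k in base.__dataclass_fields__},
        "coverage_scaled_running": {
            k: getattr(suite["coverage_scaled_running"], k) for k in base.__dataclass_fields__
        },
        "halved_effectiveness": halved,
    }
    (OUT / "roi.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
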