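"""Budget impact of the annualised scale-up cost: cost per capita, per
birth, and as a share of total health expenditure per capita.
Writes results/budget_impact.json.
"""

import json
from pathlib import Path

from ssnc_invest.costing import national_rollout
from ssnc_invest.roi import budget_impact
from ssnc_invest.synthetic import tanzania_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = tanzania_fixture()
    OUT.mkdir(exist_ok=True)
    payload = {}
    for name, scenario in sorted(bundle.scenarios.items()):
        nat = national_rollout(
            bundle.archetypes, bundle.catalogue, bundle.staffing, scenario, bundle.cost_rules
        )
        out = budget_impact(nat.annualised_total, bundle.country)
        payload[name] = {"annual_cost": nat.annualised_total, **out}
        print(f"Scenario {name}: annualised cost {nat.annualised_total/1e6:,.1f}M/yr -> "
              f"{out['cost_per_capita']:.2f}/capita, {out['cost_per_birth']:.2f}/birth, "
              f"{out['share_of_the']:.1%} of health expenditure per capita")
    (OUT / "budget_impact.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
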