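"""Activity-based costing of the 146 district + 25 regional hospital
scale-up under scenario A (all new) and scenario B (half new, half
upgraded).  Writes per-hospital and national cost breakdowns to results/.
"""

from pathlib import Path

import pandas as pd

from ssnc_invest.costing import national_category_totals, national_rollout
from ssnc_invest.synthetic import tanzania_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = tanzania_fixture()
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, scenario in sorted(bundle.scenarios.items()):
        nat = national_rollout(
            bundle.archetypes, bundle.catalogue, bundle.staffing, scenario, bundle.cost_rules
        )
        print(f"\nScenario {name}:")
        for level, lc in sorted(nat.per_level.items()):
            print(f"  {level}: setup {lc.setup.total:,.0f}/hospital, "
                  f"running {lc.running.total:,.0f}/yr, "
                  f"annualised {lc.annualised_per_hospital:,.0f}/yr")
            rows.append({"scenario": name, "level": level,
                         "setup_per_hospital": lc.setup.total,
                         "running_per_hospital": lc.running.total,
                         "annualised_per_hospital": lc.annualised_per_hospital,
                         "hospitals": lc.archetype.count_in_rollout})
        infra = national_category_totals(nat, "setup")["infrastructure"]
        hr = national_category_totals(nat, "running")["human_resources"]
        print(f"  national: one-off setup {nat.setup_total/1e6:,.1f}M "
              f"(infrastructure {infra/nat.setup_total:.0%}), "
              f"running {nat.running_total/1e6:,.1f}M/yr "
              f"(human resources {hr/nat.running_total:.0%}), "
              f"annualised {nat.annualised_total/1e6:,.1f}M/yr")
    pd.DataFrame(rows).to_csv(OUT / "costing_scenarios.csv", index=False)


if __name__ == "__main__":
    main()
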