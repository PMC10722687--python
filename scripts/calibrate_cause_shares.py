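"""One-off calibration of the Tanzania fixture's cause-of-death shares.

The cause structure behind the published lives-saved projection is not
printed, so the fixture calibrates it once against two published anchors:

1. the composition of lives saved by cause — prematurity 48%, neonatal
   sepsis 34% + pneumonia 16% (folded into neonatal infections, since the
   sepsis interventions are the only ones acting on that cause), congenital
   conditions 3% and intrapartum complications 3%; the printed percentages
   sum to 104% and are renormalised;
2. 80,000 cumulative lives saved by 2030 under the 2021-2030 linear
   scale-up from 10% to 85% coverage.

Closed-form solution: with cumulative per-cause reduction
S_c = sum_t R_c(t) over 2021-2030, the share of baseline deaths for cause c
is  share_c = (L / D) * w_c / S_c,  where w_c is the normalised target
composition, L = 80,000 target lives and D the baseline annual deaths.
The remainder goes to "other" (causes untouched by the package).  This
hits both anchors exactly whenever the resulting shares are a valid
sub-simplex.

Run manually; paste the printed literals into
``ssnc_invest.synthetic.TANZANIA_CAUSE_SHARES``.  Never run at import time.
"""

from __future__ import annotations

import json

from ssnc_invest.impact import build_trajectory, cause_mortality_reduction
from ssnc_invest.synthetic import tanzania_fixture

TARGET_LIVES_2030 = 80_000.0
#: published lives-saved composition, pneumonia folded into infections
TARGET_COMPOSITION = {
    "prematurity": 0.48,
    "neonatal_infections": 0.34 + 0.16,
    "intrapartum": 0.03,
    "congenital": 0.03,
}


def main() -> dict[str, float]:
    fixture = tanzania_fixture()
    start, end = fixture.start_year, fixture.end_year
    baseline_deaths = fixture.country.baseline_annual_deaths

    total_w = sum(TARGET_COMPOSITION.values())
    weights = {c: w / total_w for c, w in TARGET_COMPOSITION.items()}

    by_cause: dict[str, list] = {}
    for iv in fixture.interventions:
        by_cause.setdefault(iv.cause, []).append(iv)

    trajectories = {
        iv.name: build_trajectory(iv.baseline_coverage, iv.target_coverage, start, end)
        for iv in fixture.interventions
    }
    cov0 = {name: t.coverage(start) for name, t in trajectories.items()}

    summed_reduction = {}
    for cause, ivs in by_cause.items():
        summed_reduction[cause] = sum(
            cause_mortality_reduction(
                ivs, {name: t.coverage(y) for name, t in trajectories.items()}, cov0
            )
            for y in range(start, end + 1)
        )

    shares = {
        c: (TARGET_LIVES_2030 / baseline_deaths) * weights[c] / summed_reduction[c]
        for c in weights
    }
    total = sum(shares.values())
    if total >= 1.0:
        raise SystemExit(f"infeasible: intervention causes need {total:.3f} of all deaths")
    shares["other"] = 1.0 - total

    print(json.dumps(shares, indent=2))
    return shares


if __name__ == "__main__":
    main()
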