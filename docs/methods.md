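# Methods

## Impact model

A deterministic cohort-free projection in the style of cause-specific
lives-saved tools.  Baseline annual neonatal deaths are
`births × NMR/1000`, split across five causes (prematurity, neonatal
infections, intrapartum complications, congenital conditions, other).
Assumptions:

- **Constant baseline.** Births and the cause structure are held at their
  baseline-year values over the horizon; no secular mortality trend, no
  demographic projection.  All change comes from intervention coverage.
- **Linear coverage ramps.** Only coverage endpoints are specified, so
  coverage interpolates linearly between the baseline and endline years and
  holds flat outside that window.  The shape argument is an enum so other
  ramps can be added.
- **Residual-mortality combination.** Interventions on the same cause are
  combined as `1 − Π(1 − e·AF·cov)`, evaluated relative to baseline
  coverage, which caps the joint reduction below 1 and below the sum of
  individual reductions (no double counting).  A brute-force sequential
  oracle (each intervention acting on residual deaths, one at a time) is
  kept in the code and asserted equal to 1e-12 in tests.
- **Reduction applied to coverage change**, via the ratio of residual
  mortality at time *t* to residual mortality at baseline coverage.  Deaths
  averted are therefore exactly zero when coverage is frozen.

### Tanzania cause-share calibration

Cause shares of baseline mortality are a required input that the underlying
country data source does not print.  `scripts/calibrate_cause_shares.py`
solves for them in closed form from two published anchors: the lives-saved
composition by cause (prematurity 48%, infections 34% sepsis + 16%
pneumonia folded together, intrapartum 3%, congenital 3%; the printed
percentages sum to 104% and are renormalised) and 80,000 cumulative lives
saved by 2030.  Pneumonia is folded into neonatal infections because the
two sepsis interventions are the only ones acting on infectious deaths.
The remainder (34.7% of deaths) is assigned to "other", untouched by the
package.  The resulting shares are frozen as literals in
`ssnc_invest.synthetic`; the script is retained for provenance and is never
run at import time.  With these shares the model also lands near the other
published impact figures it was *not* fitted to: endline NMR 13.3 vs ~13,
39.4k lives saved by 2025 under the 5-year ramp vs 36.6k, and a
halved-effectiveness NMR of 16.0 vs 17.3.

## Costing

Activity-based incremental costing from the provider perspective, constant
2022 USD, no inflation.  Parameters that matter:

| parameter | default | why |
|---|---|---|
| discount rate | 3 %/yr | standard health-economics rate; used for annuitisation, NPV and benefit discounting |
| useful life, infrastructure | 20 yr | civil works |
| useful life, furniture & devices | 5 yr | equipment replacement cycle |
| consumables mark-up | 10 % | over economic order quantity, supplies only (not medicines) |
| maintenance | 3 %/yr of setup cost | covers infrastructure, furniture and devices |
| renovation cost | 20 % of a new build | scenario B's upgraded half |

Scenario B is modelled as an **expected per-hospital cost** (0.5 new +
0.5 × 0.2 renovation for infrastructure; half of items acquired) rather
than as two sub-fleets, matching how the per-hospital figures are reported
and avoiding integer splits of odd fleet sizes.

Staffing counts are policy-table inputs per cadre, level and scenario; the
published counts cannot be reconstructed from the stated staff:cot ratios,
shift length and leave uplift, so a `staff_count_from_ratio` helper exists
but the packaged tables use the published counts.  Salaries are not
published: the fixture's monthly salaries are a synthetic calibration
chosen so that the published counts reproduce the published per-hospital
running totals with human resources at ~60% — they are labelled as such in
the source.  Likewise the running-cost catalogue carries one aggregate line
per category (pre-markup), reverse-engineered from published per-hospital
totals and category shares, because the underlying item lists are not
published.  "Not charged" staffing cells are zeros.

The fixture reproduces the published district-hospital figures closely
(setup 448k exact, running 231k exact, annualised 274.7k vs 274k).  The
published regional-hospital figures are internally inconsistent (1.945M
setup annualised + 561k running = 744k/yr vs a printed 645k); the package
keeps the printed *components* and reports the arithmetically consistent
totals.

## ROI and budget impact

- **Costs to horizon** follow the annualised-cost convention: equivalent
  annual capital cost × number of years, plus running costs phased in by
  the implementation schedule (25% → 100% over 2021–2030), undiscounted.
  This gives US$391M to 2030 for scenario A.  The published total
  (US$376M) implies partial discounting whose convention is not stated;
  `npv` is provided for fully discounted views.  Cost per death averted
  uses the same convention (US$4,891, inside the published
  US$4,297–5,142 range).
- **ROI cost inputs are derived from the catalogue** (national annualised
  setup by category and steady-state running cost), not copied from the
  published stream tables, so generated bundles and the fixture flow
  through one code path.  The published stream arithmetic is verified
  separately in tests using the printed values as direct inputs.
- **Benefits**: lives × life expectancy life-years, valued per year at
  2.3 × GDP per capita (US$1,099 — the value consistent with the published
  products; an alternative US$1,039 also appears in the source text) or at
  the VSL-year US$2,401.  The future value is discounted as a lump sum over
  one life expectancy (66 years) at 3%, which reproduces the published
  present value of monetised lives to the cent (1,897,154,151.13).  The
  published productivity-gain PV implies ~68 years of discounting, matching
  no stated parameter combination; the same 66-year lump is used by
  default and the horizon is exposed as `benefit_horizon_years`.  GDP
  growth (3%/yr) is exposed via `value_per_life_year(..., years_of_growth)`
  but the default run uses constant GDP.
- **Budget impact** divides an annual cost by population, births and total
  health expenditure per capita.  With the catalogue-derived annualised
  cost (US$58.7M/yr) this gives US$0.95 per capita and 2.3% of health
  expenditure.

## Synthetic bundle generator

`generate_bundle(GeneratorSpec(seed, ranges))` perturbs the Tanzania
template: demography and monetisation are drawn from absolute ranges
spanning plausible low- and middle-income settings; unit costs, salaries,
staff counts, effectiveness and coverage are scaled multiplicatively; cause
shares get log-normal jitter on the simplex; the implementation schedule is
jittered and re-monotonised.  Collapsing every range to its Tanzania point
(`TANZANIA_POINT`) reproduces the packaged fixture, and any draw is
reproducible from its seed.

What generated bundles emulate: internally consistent configuration shapes
(valid simplices, monotone coverage and schedules, positive costs, coherent
cross-references) across a wide numeric envelope.  What they do not
emulate: real correlations between fields (richer countries do not get
systematically higher salaries), geographic heterogeneity, or item-level
catalogue structure (one aggregate line per running category).  Passing
property tests therefore demonstrates engine correctness and invariance,
not calibration to any real country other than the packaged example.

## Numerical choices

- Annuity factor uses the closed form with an exact `years` limit at zero
  rate; NPV uses end-of-year discounting with the base-year flow
  undiscounted.
- Cause reductions are clipped to [0, 1); an intervention with
  `e·AF·cov ≥ 1` is rejected rather than clipped, since it implies negative
  residual mortality.
- `lives_saved_by_cause` is all-zero (not uniform) when nothing is averted.
- Bundle CSV/YAML round-trips are exact: floats are written at full repr
  precision and re-read with pandas' round-trip parser; report outputs are
  sorted and full-precision so identical runs are byte-identical.
- Scale-up windows are inclusive of both endpoint years; cumulative lives
  saved include the (zero-change) baseline year.

## Known limitations

- No morbidity or disability benefits; mortality only.  Benefits are
  therefore conservative.
- No demographic projection (constant births), no stillbirth or maternal
  effects, no level-3 intensive-care costing, no patient-perspective costs,
  no financing-gap modelling.
- The cause-share calibration makes the 80,000-lives anchor exact by
  construction; independent signal comes from the non-fitted anchors listed
  above.
- Published national totals are not all mutually consistent (abstract-level
  vs table-level running costs, regional per-hospital totals); where they
  conflict the package follows the per-hospital components and schedule
  tables and documents the residual gaps here.
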