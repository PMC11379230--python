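# Methods

## Decision problem and model structure

The package evaluates sequences of up to three active therapies for
moderate-to-severe plaque psoriasis, followed by best supportive care
(BSC), from a healthcare-system perspective over a lifetime horizon. The
cohort is homogeneous and enters at age 35 (the average adult onset age in
the Malaysian registry population the fixture describes) in the first
line's induction state.

Each sequence unrolls into its own state space — an induction and a
maintenance state per line, plus BSC and death. Induction is a one-cycle
tunnel: the response assessment (PASI75 at 16 weeks) either admits the
patient to maintenance or moves them down the sequence. Maintenance is left
through discontinuation (loss of efficacy or tolerability, pooled into one
annual all-cause risk) or death; there is no re-trial of a failed line, no
dose escalation and no adverse-event states. BSC is absorbing until death.

Event order within a cycle is death first; response and discontinuation are
conditional on survival. This is the standard competing-risk decomposition;
the alternative orderings differ only at second order in the (small)
per-cycle probabilities.

## Time, discounting, within-cycle correction

* Cycle length: 16 weeks; a cycle is 16/52 ≈ 0.3077 years.
* Horizon: cycles run from age 35 until the first cycle at or beyond age
  100, in which death is certain (survivorship beyond 100 is negligible at
  the fixture's mortality).
* Discounting: 3% a year on both costs and QALYs; the factor
  `(1+d)^(−t·16/52)` is indexed by elapsed years at cycle start, so cycle 0
  is undiscounted.
* Within-cycle correction: everyone leaving a state mid-cycle — induction
  failures, maintenance discontinuers and decedents — accrues half a cycle
  of person-time and cost in the origin state and nothing in the
  destination that cycle. The induction-success transition accrues the full
  induction cycle (treatment was actually delivered for the whole cycle).
  The fixture's source describes the half-cycle assumption for induction
  failures; extending it to discontinuers and deaths is the conventional
  generalisation and is a deliberate assumption here. Setting
  `half_cycle_costs: false` charges full cycles instead (this also makes
  induction failures bear the full induction drug cost).

## Probability inputs

Annual probabilities (discontinuation; adjusted mortality) convert to the
cycle with the constant-rate identity `1 − (1−p)^(16/52)`. Mortality uses a
general-population life table `q(a)` under a relative risk of 1.52 for
severe psoriasis applied on the annual survival scale
(`q_adj = 1 − (1−q)^1.52`) before cycle conversion. The relative risk is
applied in every alive state, including BSC, because the whole cohort has
severe disease; `rr_in_bsc: false` restricts it to active treatment. The
life table is queried at the integer year of age containing the cohort's
(continuously advancing) age; abridged bands expand as constant-`q` years.

## Cost model

Per state-cycle cost = drug + administration + monitoring.

* Biologic acquisition follows the label schedules (secukinumab 300 mg at
  weeks 0–4 then every 4 weeks; ustekinumab 45 mg at weeks 0 and 4 then
  every 12 weeks; adalimumab 80 mg then 40 mg fortnightly) priced per
  indivisible vial (`ceil(dose/vial)`), so the 80 mg loading dose consumes
  two 40 mg vials. Induction events are enumerated inside the first cycle;
  maintenance cycles carry the long-run average `16/interval` doses
  (fractional for ustekinumab, 16/12), because a cohort model tracks
  expectations and a calendar-aligned integer count would only add
  artificial phase oscillation.
* Systemic therapy and phototherapy are costed as flat per-cycle
  acquisition amounts (1,183 and 1,427 USD) in both phases — the model's
  only costing clock is the cycle.
* Administration: one outpatient visit (71 USD) per injection event for
  provider-administered biologics; a single visit for self-administered
  adalimumab and its biosimilar, charged in the induction cycle; two
  narrowband-UVB sessions per week (2×16 visits/cycle) for phototherapy;
  nothing for oral systemic therapy.
* Monitoring per cycle: 168 (biologics), 299 (systemic), 185 (photo).
* BSC carries a single per-cycle cost and no drug/administration split.

All monetary inputs are consumed as US dollars exactly as tabulated; no
currency-conversion chain is re-executed.

## Utilities

Annual utilities by response state: 0.85/0.62 (biologic responder /
non-responder), 0.89/0.64 (systemic), BSC 0.11. No utilities are tabulated
for phototherapy, so the systemic values are reused — both are non-biologic
first-line modalities; this is an assumption, not source data. Induction
cycles use the non-responder utility (response is only established at the
cycle's end), maintenance the responder utility.

## The two synthesised inputs

**Life table.** The national abridged life table is not redistributable, so
mortality is a Gompertz–Makeham hazard `μ(x) = a + b·cˣ` with a = 3.0e−4,
b = 3.88e−5, c = 1.10, integrated to annual `q(x)`. These values were
calibrated once so period life expectancy at birth is ≈75 years
(Malaysia-like); the fixture ships the generated single-year table and
`psorseq.synthetic` regenerates it. A real abridged table can be dropped in
as `lifetable.csv` at any time. What this synthetic table cannot represent:
infant/young-adult mortality structure and any cohort (generational)
improvement — immaterial here because the model starts at 35 and the
discounted horizon is dominated by ages 35–75.

**BSC cycle cost.** Cited but never published. It is recovered by
one-parameter calibration: the BSC cost is the root of
`total_cost(SYS→UST→ADA; c) = 149,721` (the comparator's published total),
a strictly increasing map solved by bisection to 0.01 USD. With the fixture
inputs the comparator's minimum achievable total (BSC cost = 0) already
exceeds that anchor, so the calibration is infeasible; `fit()` then pins
the BSC cost at the boundary (zero) and records the shortfall in
`calibration_note` (`fit(calibration="strict")` raises instead). Every
other sequence's total is a genuine model output either way.

Because of these two substitutions the published tables are treated as a
validation surface with tolerances, not as ground truth the package is
tuned to; the binding quality gate is the property suite (mass
conservation to 1e−12, agreement with an independent 200,000-person
microsimulation within 3 Monte-Carlo SEs, exact degenerate closed forms,
monotonicity in response/price/discount, byte-exact seeded determinism).

## Sensitivity analyses

* **One-way (tornado):** each parameter is set to its tabulated
  deterministic range ends (±20% of baseline where no range exists), the
  full model re-runs both arms, and the entry reports the ICER at each end
  and the spread. The state utilities move as one grouped bar (each to its
  own range end jointly) because the utility evidence enters the model as a
  block; per-parameter mode is available. The discount rate varies over
  1%–5% per the source text (its tabulated "0.00–0.01" range is a printing
  error). The phototherapy response range (0.18–0.26) does not bracket its
  baseline (0.32); it is used as printed and reported by
  `validate_dsa_ranges`.
* **Scenarios:** originator vial prices (SEC, UST, ADA) scaled by 1−f for
  f ∈ {0.2, 0.3, 0.4, 0.5}; biosimilar, systemic and phototherapy prices
  untouched; comparators re-run too since they contain UST and ADA.
* **PSA:** gamma for costs, beta for probabilities and utilities, both
  moment-matched with SE = 10% of the baseline; 10,000 iterations by
  default (analyses in this repository use 2,000, which brackets the CEAC
  crossover to well under the WTP grid step). One parameter gets one draw
  per iteration shared across all strategies (common random parameters); a
  biosimilar aliases its originator's response/discontinuation draws and
  utilities are drawn per block (biologic vs non-biologic), so biosimilar
  pairs differ only in cost draws. The life table and discount rate stay
  fixed (a gamma-distributed discount rate is not meaningful). Draw order
  follows the sorted parameter registry, so a seed fixes the ensemble
  byte-for-byte. Infeasible beta moments (se² ≥ m(1−m)) abort with the
  parameter's name rather than silently truncating.
* **CEAC/ELC:** at each willingness-to-pay value, the probability of
  attaining maximal net benefit (ties split equally) and the expected
  foregone net benefit; the expected-loss argmin provably coincides with
  the mean-net-benefit argmax, and the suite asserts it on every run.

## Numerical choices and degenerate inputs

* Cohort propagation is exact linear algebra on the 8-state space; row
  sums are checked every cycle (drift > 1e−9 is an internal error).
* Calibration bisection tolerance: 0.01 USD/cycle.
* Vial counts use `ceil(dose/vial − 1e−12)` to absorb float noise in
  exact-multiple doses.
* `p = 0` and `p = 1` probabilities, zero prices, zero SE (degenerate PSA)
  and zero hazards are all valid inputs with the obvious limits; ages at or
  beyond `max_age` force death within the cycle.
* ICER dominance cases are returned as flags (`dominant`, `dominated`,
  `undefined` at ΔE = 0) rather than signed ratios.

## Known limitations

* Homogeneous cohort: no heterogeneity in weight-based dosing, baseline
  severity or response durability; PASI75 is the single response level.
* Discontinuation pools all causes at a constant annual risk; real-world
  persistence falls with time on drug.
* The incremental analysis is pairwise against a common comparator, as the
  decision problem poses it; a fully incremental frontier (with extended
  dominance) is provided as `CEAFitResults.frontier_table` but is not the
  headline output.
* With the fixture's printed inputs the published base-case totals are not
  reachable (see the calibration note above); the package reports its own
  computed values rather than adjusting inputs to force agreement.
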