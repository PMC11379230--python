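# psorseq

A lifetime Markov cohort cost-effectiveness model for **sequential biologic
therapy in moderate-to-severe psoriasis**, written for health-economics
analysts who need a transparent, testable implementation of a
treatment-sequencing decision model: three lines of active therapy
(secukinumab, ustekinumab, adalimumab and its biosimilar, or first-line
systemic therapy / phototherapy), each tried for a 16-week induction cycle
and continued while tolerated, followed by best supportive care (BSC) until
death.

## The model

A cohort enters at age 35 in the first line's induction state. Each 16-week
cycle, with states `L1_ind, L1_mnt, L2_ind, L2_mnt, L3_ind, L3_mnt, BSC,
DEAD`:

- death is resolved first, from a general-population life table `q(a)`
  under a psoriasis mortality relative risk RR, on the annual survival
  scale: `q_adj(a) = 1 − (1 − q(a))^RR`, then converted to the cycle,
- induction survivors respond (PASI75) with probability `p` and move to the
  line's maintenance state; failures move to the next line's induction (or
  BSC after line 3),
- maintenance survivors discontinue with the cycle-converted annual risk
  `1 − (1 − p_annual)^(16/52)` and move down the sequence, otherwise remain.

Costs per state-cycle are drug acquisition (label dosing schedules priced
per indivisible vial), administration (outpatient visits per injection, one
visit for self-administered adalimumab, two UVB sessions per week for
phototherapy) and monitoring. QALYs weight person-time by state utilities
(responder / non-responder / BSC). Totals are discounted at 3% a year with
half-cycle accrual for everyone leaving a state mid-cycle. Strategies are
compared as ICER = ΔC/ΔE against the systemic-first and phototherapy-first
comparator sequences, with net monetary benefit `λ·ΔE − ΔC` at the
willingness-to-pay threshold λ = US$104,337.19/QALY, biosimilar savings
`(C_orig − C_bios)/C_orig × 100`, tornado-style one-way sensitivity
analysis, originator price-reduction scenarios, and a probabilistic
sensitivity analysis (gamma for costs, beta for probabilities/utilities,
moment-matched with SE = 10% of the mean) summarised as cost-effectiveness
acceptability and expected-loss curves.

Two inputs have no published value and are synthesised, which is why
published totals are a *validation* target rather than a reproduction
guarantee: the life table (replaced by a Gompertz–Makeham table calibrated
to life expectancy 75 at birth) and the BSC cycle cost (calibrated so the
systemic-first comparator hits its published total — pinned at the feasible
boundary when the anchor is unreachable; see `docs/methods.md`).

## Worked example

```python
from psorseq import PsoriasisCEModel

res = PsoriasisCEModel.default().fit()     # bundled fixture, BSC calibration
r = res.compare("SEC→UST→ADA", "SYS→UST→ADA")
print(f"ΔC = {r.delta_cost:,.0f} USD, ΔE = {r.delta_qaly:.3f} QALY, "
      f"ICER = {r.icer:,.0f} USD/QALY")
print(res.savings_table()[["biosimilar", "cost_difference", "saving_pct"]]
      .to_string(index=False))
```

prints

```
ΔC = 305,484 USD, ΔE = 1.312 QALY, ICER = 232,917 USD/QALY
    biosimilar  cost_difference  saving_pct
ADA_BS→UST→SEC     44711.514441    8.845384
ADA_BS→SEC→UST     44711.514441    8.560646
UST→ADA_BS→SEC     40021.858281    7.878592
SEC→ADA_BS→UST     39578.358320    7.298466
UST→SEC→ADA_BS     35245.509766    6.693357
SEC→UST→ADA_BS     35245.509766    6.471889
```

So under this fixture the secukinumab-first sequence buys 1.31 extra QALYs
over systemic-first care at about $233k per QALY — above the $104k
threshold — and swapping the adalimumab originator for its biosimilar saves
6.5–8.8% of lifetime cost with no QALY loss. Everything above is also
available from the shell:

```sh
psorseq validate                 # input checks + DSA-range report
psorseq base-case --out out/     # incremental tables, NMB, savings
psorseq owsa --out out/          # tornado table
psorseq scenario --out out/      # 20–50% originator price cuts
psorseq psa --iterations 2000 --seed 7 --out out/   # CEAC + ELC grids
```

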