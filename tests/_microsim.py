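"""Individual-level microsimulation oracle for the cohort engine.

Re-implements the event logic person by person with Monte-Carlo draws:
death resolved first each cycle, induction response / maintenance
discontinuation conditional on survival, half-cycle accrual for every
mid-cycle leaver.  Shares only the per-state cost/utility vectors and the
cycle mortality schedule with the cohort engine -- the state propagation
path is entirely independent, so agreement of the discounted totals (within
Monte-Carlo error) checks the expectation computed by the matrix engine.
"""

from __future__ import annotations

import numpy as np

from psorseq.dosing import cycle_cost
from psorseq.markov import StateSpace, annual_to_cycle_prob, cycle_mortality
from psorseq.params import ParameterSet, Sequence


def microsim_totals(
    sequence: Sequence,
    params: ParameterSet,
    n_people: int,
    seed: int,
) -> tuple[float, float, float, float]:
    """(mean cost, SE cost, mean QALY, SE QALY) over simulated individuals."""
    cfg = params.config
    space = StateSpace(sequence)
    n_states = len(space)
    T = cfg.n_cycles
    yf = cfg.cycle_years

    p_resp = np.zeros(n_states)
    p_disc = np.zeros(n_states)
    nxt_fail = np.zeros(n_states, dtype=int)
    state_cost = np.zeros(n_states)
    state_util = np.zeros(n_states)
    for j, st in enumerate(space.states):
        if st.phase in ("induction", "maintenance"):
            t = params.treatment(st.treatment)
            k = j // 2
            nxt_fail[j] = space.next_on_failure(k)
            state_cost[j] = cycle_cost(t, st.phase, params.outpatient, cfg).total
            if st.phase == "induction":
                p_resp[j] = t.p_response
                state_util[j] = t.u_nonresponder
            else:
                p_disc[j] = annual_to_cycle_prob(
                    t.annual_discontinuation, cfg.cycle_weeks, cfg.weeks_per_year)
                state_util[j] = t.u_responder
        elif st.phase == "bsc":
            state_cost[j] = params.bsc.cost_cycle
            state_util[j] = params.bsc.utility
    p_die = cycle_mortality(params, cfg)
    disc = (1.0 + cfg.discount_annual) ** (-(np.arange(T) * yf))
    is_ind = np.array([st.phase == "induction" for st in space.states])
    is_mnt = np.array([st.phase == "maintenance" for st in space.states])

    rng = np.random.default_rng(seed)
    state = np.zeros(n_people, dtype=int)
    cost = np.zeros(n_people)
    qaly = np.zeros(n_people)
    half = 0.5 if cfg.half_cycle_costs else 0.0
    for t in range(T):
        alive = state != space.dead
        if not alive.any():
            break
        dies = alive & (rng.random(n_people) < p_die[t])
        u = rng.random(n_people)
        responds = u < p_resp[state]
        discont = u < p_disc[state]  # independent of response (disjoint states)
        in_ind = alive & is_ind[state]
        in_mnt = alive & is_mnt[state]
        leaver = dies | (in_ind & ~responds) | (in_mnt & discont)
        w = np.where(alive, np.where(leaver, 1.0 - half, 1.0), 0.0)
        cost += w * state_cost[state] * disc[t]
        qaly += w * state_util[state] * yf * disc[t]
        # transitions
        new = state.copy()
        surv_ind = in_ind & ~dies
        new[surv_ind & responds] = state[surv_ind & responds] + 1
        new[surv_ind & ~responds] = nxt_fail[state[surv_ind & ~responds]]
        surv_mnt = in_mnt & ~dies
        new[surv_mnt & discont] = nxt_fail[state[surv_mnt & discont]]
        new[dies] = space.dead
        state = new
    n = float(n_people)
    return (cost.mean(), cost.std(ddof=1) / np.sqrt(n),
            qaly.mean(), qaly.std(ddof=1) / np.sqrt(n))
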