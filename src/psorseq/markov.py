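"""Sequence-specific cohort state-transition engine.

A sequence of up to three active lines unrolls into the ordered state space
``[L1_ind, L1_mnt, L2_ind, L2_mnt, ..., BSC, DEAD]``.  Induction states are
one-cycle tunnels: survivors either respond (move to the line's maintenance
state) or fail (move to the next line's induction, or BSC after the last
line).  Maintenance survivors discontinue with the cycle-converted annual
risk, otherwise remain.  BSC is left only through death; DEAD is absorbing.
Within each cycle death is resolved first and all clinical transitions are
conditional on survival.

Anyone leaving a state mid-cycle -- induction failures, maintenance
discontinuers and decedents -- accrues half a cycle of person-time (and
cost) in the origin state and nothing in the destination that cycle; the
induction-success transition accrues the full induction cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosing import cycle_cost
from .params import LifeTable, ModelConfig, ParameterSet, Sequence

__all__ = [
    "annual_to_cycle_prob",
    "mortality_cycle_prob",
    "StateSpace",
    "transition_matrix",
    "CohortTrace",
    "Totals",
    "run_cohort",
    "accrue_totals",
]

_MASS_TOL = 1e-9


def annual_to_cycle_prob(p_annual: float, cycle_weeks: float, weeks_per_year: float) -> float:
    """Convert an annual event probability to one model cycle.

    Uses the constant-rate identity ``1 - (1 - p)**(cycle_weeks / weeks_per_year)``.
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"annual probability {p_annual!r} outside [0, 1]")
    out = 1.0 - (1.0 - p) ** (cycle_weeks / weeks_per_year)
    return float(out) if np.isscalar(p_annual) else out


def mortality_cycle_prob(
    age: float,
    lifetable: LifeTable,
    rr: float,
    config: ModelConfig,
) -> float:
    """Per-cycle death probability at ``age`` under mortality relative risk ``rr``.

    The relative risk acts on the annual survival scale,
    ``q_adj = 1 - (1 - q(age))**rr``, before cycle conversion.  At or beyond
    ``max_age`` death within the cycle is certain.
    """
    if age >= config.max_age:
        return 1.0
    q = lifetable.annual_q(age)
    q_adj = 1.0 - (1.0 - q) ** rr
    return annual_to_cycle_prob(q_adj, config.cycle_weeks, config.weeks_per_year)


@dataclass(frozen=True)
class State:
    label: str
    treatment: str | None  # None for BSC / DEAD
    phase: str             # induction | maintenance | bsc | dead


class StateSpace:
    """Ordered states of one treatment sequence (2 per line + BSC + DEAD)."""

    def __init__(self, sequence: Sequence):
        self.sequence = sequence
        states: list[State] = []
        for k, name in enumerate(sequence.lines, start=1):
            states.append(State(f"L{k}_ind[{name}]", name, "induction"))
            states.append(State(f"L{k}_mnt[{name}]", name, "maintenance"))
        states.append(State("BSC", None, "bsc"))
        states.append(State("DEAD", None, "dead"))
        self.states = tuple(states)
        self.n_lines = len(sequence.lines)
        self.bsc = 2 * self.n_lines
        self.dead = self.bsc + 1

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def next_on_failure(self, line_index: int) -> int:
        """Destination of induction failure / discontinuation from line ``line_index``."""
        return 2 * (line_index + 1) if line_index + 1 < self.n_lines else self.bsc


def _survivor_matrix(space: StateSpace, params: ParameterSet) -> np.ndarray:
    """Transition matrix among alive states, conditional on surviving the cycle."""
    cfg = params.config
    n = len(space)
    A = np.zeros((n, n))
    for k, name in enumerate(space.sequence.lines):
        t = params.treatment(name)
        i, m = 2 * k, 2 * k + 1
        nxt = space.next_on_failure(k)
        A[i, m] = t.p_response
        A[i, nxt] += 1.0 - t.p_response
        p_disc = annual_to_cycle_prob(t.annual_discontinuation, cfg.cycle_weeks, cfg.weeks_per_year)
        A[m, nxt] += p_disc
        A[m, m] = 1.0 - p_disc
    A[space.bsc, space.bsc] = 1.0
    A[space.dead, space.dead] = 1.0
    return A


def transition_matrix(
    sequence: Sequence,
    age: float,
    params: ParameterSet,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at the given cohort age."""
    cfg = config or params.config
    space = StateSpace(sequence)
    A = _survivor_matrix(space, params)
    p_die = mortality_cycle_prob(age, params.lifetable, cfg.rr_mortality, cfg)
    P = A * (1.0 - p_die)
    P[:, space.dead] += p_die
    P[space.dead, :] = 0.0
    P[space.dead, space.dead] = 1.0
    if not cfg.rr_in_bsc:
        p0 = mortality_cycle_prob(age, params.lifetable, 1.0, cfg)
        P[space.bsc, :] = 0.0
        P[space.bsc, space.bsc] = 1.0 - p0
        P[space.bsc, space.dead] = p0
    if P.min() < 0:
        raise RuntimeError("negative transition probability")
    return P


@dataclass
class CohortTrace:
    """Per-cycle occupancy and within-cycle-corrected accrual weights."""

    space: StateSpace
    occupancy: np.ndarray        # (cycles, states), start-of-cycle proportions
    accrual_weights: np.ndarray  # (cycles, states), person-time weights
    age_at_cycle: np.ndarray     # (cycles,)
    discount_factor: np.ndarray  # (cycles,)

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: age, discount factor, occupancy and weights."""
        d = {"cycle": np.arange(len(self.age_at_cycle)), "age": self.age_at_cycle,
             "discount_factor": self.discount_factor}
        for j, lab in enumerate(self.space.labels):
            d[f"occ[{lab}]"] = self.occupancy[:, j]
        for j, lab in enumerate(self.space.labels):
            d[f"w[{lab}]"] = self.accrual_weights[:, j]
        return pd.DataFrame(d)


@dataclass
class Totals:
    """Discounted lifetime totals with a per-state breakdown."""

    cost: float
    qaly: float
    cost_by_state: dict[str, float]
    qaly_by_state: dict[str, float]


def cycle_mortality(params: ParameterSet, config: ModelConfig | None = None,
                    rr: float | None = None) -> np.ndarray:
    """Per-cycle death probabilities over the whole horizon (reusable across
    runs that share the life table and configuration)."""
    cfg = config or params.config
    ages = cfg.start_age + np.arange(cfg.n_cycles) * cfg.cycle_years
    r = cfg.rr_mortality if rr is None else rr
    return np.array([mortality_cycle_prob(a, params.lifetable, r, cfg) for a in ages])


def run_cohort(
    sequence: Sequence,
    params: ParameterSet,
    config: ModelConfig | None = None,
    lifetable: LifeTable | None = None,
    p_die: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate a unit cohort from ``start_age`` until past ``max_age``.

    The cohort starts entirely in the first line's induction state.  Accrual
    weights subtract half of each state's leavers (induction failures,
    discontinuers, decedents) when ``config.half_cycle_costs`` is set.
    """
    cfg = config or params.config
    lt = lifetable or params.lifetable
    space = StateSpace(sequence)
    n, T = len(space), cfg.n_cycles
    A = _survivor_matrix(space, params)

    # per-state probability of leaving mid-cycle, conditional on survival
    # (induction success i -> m is not a mid-cycle exit)
    leave_alive = 1.0 - np.diag(A).copy()
    for k in range(space.n_lines):
        i = 2 * k
        leave_alive[i] = 1.0 - A[i, 2 * k + 1]  # failures only
    leave_alive[space.dead] = 0.0

    occ = np.zeros((T, n))
    wts = np.zeros((T, n))
    ages = cfg.start_age + np.arange(T) * cfg.cycle_years
    disc = (1.0 + cfg.discount_annual) ** (-(np.arange(T) * cfg.cycle_years))

    if p_die is None:
        p_die = np.array([mortality_cycle_prob(a, lt, cfg.rr_mortality, cfg) for a in ages])
    if not cfg.rr_in_bsc:
        p_die_bsc = np.array([mortality_cycle_prob(a, lt, 1.0, cfg) for a in ages])

    x = np.zeros(n)
    x[0] = 1.0
    for t in range(T):
        occ[t] = x
        pd_t = p_die[t]
        pd_vec = np.full(n, pd_t)
        if not cfg.rr_in_bsc:
            pd_vec[space.bsc] = p_die_bsc[t]
        pd_vec[space.dead] = 0.0
        leavers = x * (pd_vec + (1.0 - pd_vec) * leave_alive)
        wts[t] = x - 0.5 * leavers if cfg.half_cycle_costs else x
        # advance: death first, then survivor transitions
        surv = x * (1.0 - pd_vec)
        x = surv @ A
        x[space.dead] += np.sum(occ[t] * pd_vec)
        drift = abs(x.sum() - 1.0)
        if drift > _MASS_TOL:
            raise RuntimeError(f"cohort mass drift {drift:.2e} at cycle {t}")
    return CohortTrace(space=space, occupancy=occ, accrual_weights=wts,
                       age_at_cycle=ages, discount_factor=disc)


def accrue_totals(
    trace: CohortTrace,
    sequence: Sequence,
    params: ParameterSet,
    config: ModelConfig | None = None,
) -> Totals:
    """Discounted lifetime cost and QALYs from a cohort trace.

    Induction states carry non-responder utility and induction-phase costs,
    maintenance states responder utility and maintenance-phase costs; BSC
    carries its own utility and per-cycle cost.  Each cycle contributes
    ``weight * value * cycle_years * discount``.
    """
    cfg = config or params.config
    space = trace.space
    n = len(space)
    state_cost = np.zeros(n)
    state_util = np.zeros(n)
    for j, st in enumerate(space.states):
        if st.phase in ("induction", "maintenance"):
            t = params.treatment(st.treatment)
            state_cost[j] = cycle_cost(t, st.phase, params.outpatient, cfg).total
            state_util[j] = t.u_nonresponder if st.phase == "induction" else t.u_responder
        elif st.phase == "bsc":
            state_cost[j] = params.bsc.cost_cycle
            state_util[j] = params.bsc.utility
    w = trace.accrual_weights * trace.discount_factor[:, None]
    cost_by = w.sum(axis=0) * state_cost
    qaly_by = w.sum(axis=0) * state_util * cfg.cycle_years
    labels = space.labels
    return Totals(
        cost=float(cost_by.sum()),
        qaly=float(qaly_by.sum()),
        cost_by_state=dict(zip(labels, cost_by)),
        qaly_by_state=dict(zip(labels, qaly_by)),
    )
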