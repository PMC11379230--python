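"""Cohort engine: probability conversions, transitions, traces, totals."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psorseq.markov import (
    StateSpace,
    accrue_totals,
    annual_to_cycle_prob,
    mortality_cycle_prob,
    run_cohort,
    transition_matrix,
)
from psorseq.params import LifeTable, Sequence
from psorseq.synthetic import random_parameter_set

from _microsim import microsim_totals


# -- probability conversions -------------------------------------------------

@pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0), (0.22, 0.073601)])
def test_annual_to_cycle_prob(p, expected):
    assert annual_to_cycle_prob(p, 16, 52) == pytest.approx(expected, abs=1e-6)


def test_annual_to_cycle_prob_domain():
    with pytest.raises(ValueError):
        annual_to_cycle_prob(1.2, 16, 52)
    with pytest.raises(ValueError):
        annual_to_cycle_prob(-0.1, 16, 52)


def test_mortality_cycle_prob(params):
    cfg = params.config
    flat = LifeTable(np.arange(0, 111), np.full(111, 0.01))
    zero = LifeTable(np.arange(0, 111), np.zeros(111))
    assert mortality_cycle_prob(50, zero, 1.52, cfg) == 0.0
    # relative risk of 1 reduces to the plain cycle conversion
    assert mortality_cycle_prob(50, flat, 1.0, cfg) == pytest.approx(
        annual_to_cycle_prob(0.01, 16, 52))
    # RR acts on the annual survival scale before cycle conversion
    assert mortality_cycle_prob(50, flat, 1.52, cfg) == pytest.approx(0.004690, abs=1e-6)
    assert 1.0 - (1.0 - 0.01) ** 1.52 == pytest.approx(0.015160, abs=1e-6)
    # beyond the horizon age death within the cycle is certain
    assert mortality_cycle_prob(cfg.max_age, flat, 1.52, cfg) == 1.0


# -- state space and transition matrix ---------------------------------------

def test_state_space_layout(params):
    seq = params.sequence("SEC→UST→ADA")
    space = StateSpace(seq)
    assert len(space) == 8
    assert space.labels[-2:] == ["BSC", "DEAD"]
    assert [s.phase for s in space.states[:2]] == ["induction", "maintenance"]


def test_transition_matrix_rows(zero_mortality):
    seq = zero_mortality.sequence("SEC→UST→ADA")
    P = transition_matrix(seq, 40.0, zero_mortality)
    space = StateSpace(seq)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    # absorbing death
    assert P[space.dead, space.dead] == 1.0
    assert P[space.dead].sum() == 1.0
    # first-line induction splits on the response probability
    assert P[0, 1] == pytest.approx(0.85)
    assert P[0, 2] == pytest.approx(0.15)
    # induction is a tunnel: no self-transition
    assert P[0, 0] == 0.0


def test_transition_matrix_perfect_therapy(zero_mortality):
    t = zero_mortality.treatment("SEC")
    p = zero_mortality.with_treatment(
        t.with_value("p_response", 1.0).with_value("annual_discontinuation", 0.0))
    seq = Sequence(label="SEC", lines=("SEC",))
    P = transition_matrix(seq, 40.0, p)
    assert P[0, 1] == 1.0            # induction -> maintenance surely
    assert P[1, 1] == 1.0            # maintenance absorbing among alive states


def test_transition_matrix_mortality_first(params):
    seq = params.sequence("SEC→UST→ADA")
    P = transition_matrix(seq, 80.0, params)
    space = StateSpace(seq)
    p_die = mortality_cycle_prob(80.0, params.lifetable, params.config.rr_mortality, params.config)
    assert P[0, space.dead] == pytest.approx(p_die)
    assert P[0, 1] == pytest.approx((1 - p_die) * 0.85)


# -- cohort propagation -------------------------------------------------------

def test_run_cohort_analytic_path(zero_mortality):
    t = zero_mortality.treatment("SYS")
    p = zero_mortality.with_treatment(
        t.with_value("p_response", 1.0).with_value("annual_discontinuation", 0.0))
    seq = Sequence(label="SYS", lines=("SYS",))
    tr = run_cohort(seq, p)
    N = p.config.n_cycles
    assert tr.occupancy[0, 0] == 1.0
    # one induction cycle, then maintenance until the horizon closes
    np.testing.assert_allclose(tr.occupancy[1:N, 1], 1.0, atol=1e-12)


def test_run_cohort_tunnel_chaining(zero_mortality):
    p = zero_mortality
    for name in ("SEC", "UST", "ADA"):
        p = p.with_treatment(p.treatment(name).with_value("p_response", 0.0))
    seq = p.sequence("SEC→UST→ADA")
    tr = run_cohort(seq, p)
    space = tr.space
    assert tr.occupancy[1, 2] == 1.0          # line 2 induction at cycle 1
    assert tr.occupancy[2, 4] == 1.0          # line 3 induction at cycle 2
    assert tr.occupancy[3, space.bsc] == 1.0  # BSC from cycle 3


def test_mass_conservation_all_fixture_sequences(params):
    for seq in params.sequences:
        tr = run_cohort(seq, params)
        np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = tr.occupancy[:, tr.space.dead]
        assert (np.diff(dead) >= -1e-15).all()
        assert (tr.accrual_weights <= tr.occupancy + 1e-15).all()


def test_discount_factor_indexing(params):
    tr = run_cohort(params.sequence("SEC→UST→ADA"), params)
    assert tr.discount_factor[0] == 1.0
    # 13 cycles x 16/52 years = 4 years
    assert tr.discount_factor[13] == pytest.approx(1.03 ** -4, abs=1e-6)
    assert tr.discount_factor[13] == pytest.approx(0.888487, abs=1e-6)


def test_trace_export_columns(params):
    tr = run_cohort(params.sequence("SEC→UST→ADA"), params)
    df = tr.to_frame()
    assert {"cycle", "age", "discount_factor", "occ[BSC]", "w[DEAD]"} <= set(df.columns)
    assert len(df) == params.config.n_cycles


# -- accrual ------------------------------------------------------------------

def test_undiscounted_person_time(zero_mortality):
    """u = 1 everywhere, d = 0, no transitions: QALYs are pure person-time."""
    t = (zero_mortality.treatment("SYS")
         .with_value("p_response", 1.0)
         .with_value("annual_discontinuation", 0.0)
         .with_value("u_responder", 1.0)
         .with_value("u_nonresponder", 1.0))
    p = replace(zero_mortality.with_treatment(t),
                config=replace(zero_mortality.config, discount_annual=0.0))
    seq = Sequence(label="SYS", lines=("SYS",))
    tot = accrue_totals(run_cohort(seq, p), seq, p)
    N = p.config.n_cycles
    # all cycles full weight except the forced-death closing cycle (half)
    assert tot.qaly == pytest.approx((N - 0.5) * 16 / 52, rel=1e-12)


def test_closed_form_totals_degenerate_limits(zero_mortality):
    """Flat costs, certain response, no discontinuation, d = 0: totals match
    the arithmetic hand formula exactly."""
    t = (zero_mortality.treatment("SYS")
         .with_value("p_response", 1.0)
         .with_value("annual_discontinuation", 0.0))
    p = replace(zero_mortality.with_treatment(t),
                config=replace(zero_mortality.config, discount_annual=0.0))
    seq = Sequence(label="SYS", lines=("SYS",))
    tot = accrue_totals(run_cohort(seq, p), seq, p)
    N = p.config.n_cycles
    cyc = 1183.0 + 299.0  # flat drug + monitoring, no admin for oral therapy
    assert tot.cost == pytest.approx(cyc * (N - 0.5), rel=1e-12)
    u_ind, u_mnt = t.u_nonresponder, t.u_responder
    assert tot.qaly == pytest.approx((u_ind + (N - 1.5) * u_mnt) * 16 / 52, rel=1e-12)


def test_zero_costs_zero_total(zero_mortality):
    p = zero_mortality
    for name in list(p.treatments):
        t = (p.treatment(name).with_value("unit_cost", 0.0)
             .with_value("monitoring_cost_cycle", 0.0))
        p = p.with_treatment(t)
    p = replace(p, outpatient=replace(p.outpatient, cost_per_visit=0.0),
                bsc=replace(p.bsc, cost_cycle=0.0))
    seq = p.sequence("SEC→UST→ADA")
    tot = accrue_totals(run_cohort(seq, p), seq, p)
    assert tot.cost == 0.0


def test_totals_breakdown_sums(params):
    seq = params.sequence("SEC→UST→ADA")
    tot = accrue_totals(run_cohort(seq, params), seq, params)
    assert tot.cost == pytest.approx(sum(tot.cost_by_state.values()))
    assert tot.qaly == pytest.approx(sum(tot.qaly_by_state.values()))
    assert tot.cost >= 0 and tot.qaly >= 0


# -- monotonicity properties --------------------------------------------------

def _totals(params, label):
    seq = params.sequence(label)
    return accrue_totals(run_cohort(seq, params), seq, params)


@pytest.mark.parametrize("name", ["SEC", "UST", "ADA"])
def test_qaly_monotone_in_response(params, name):
    base = _totals(params, "SEC→UST→ADA").qaly
    t = params.treatment(name)
    up = params.with_treatment(t.with_value("p_response", min(1.0, t.p_response + 0.05)))
    assert _totals(up, "SEC→UST→ADA").qaly >= base - 1e-9


@pytest.mark.parametrize("name", ["SEC", "UST", "ADA", "SYS"])
def test_cost_monotone_in_unit_cost(params, name):
    for label in ("SEC→UST→ADA", "SYS→UST→ADA"):
        base = _totals(params, label).cost
        t = params.treatment(name)
        up = params.with_treatment(t.with_value("unit_cost", 1.1 * t.unit_cost))
        assert _totals(up, label).cost >= base - 1e-9


def test_discount_monotonicity(params):
    for label in ("SEC→UST→ADA", "SYS→UST→ADA", "PHOTO→UST→ADA"):
        vals = []
        for d in (0.01, 0.03, 0.05):
            p = replace(params, config=replace(params.config, discount_annual=d))
            vals.append(_totals(p, label))
        assert vals[0].cost >= vals[1].cost >= vals[2].cost
        assert vals[0].qaly >= vals[1].qaly >= vals[2].qaly


# -- microsimulation oracle ---------------------------------------------------

@pytest.mark.parametrize("label,seed", [
    ("SEC→UST→ADA", 101), ("SYS→UST→ADA", 202), ("ADA_BS→UST→SEC", 303),
])
def test_cohort_matches_microsimulation(params, label, seed):
    """Expected totals agree with an independent individual-level
    microsimulation (200,000 simulees) within 3 Monte-Carlo SEs."""
    p = replace(params, bsc=replace(params.bsc, cost_cycle=500.0))
    seq = p.sequence(label)
    tot = accrue_totals(run_cohort(seq, p), seq, p)
    mc, se_c, mq, se_q = microsim_totals(seq, p, n_people=200_000, seed=seed)
    assert tot.cost == pytest.approx(mc, abs=3 * se_c)
    assert tot.qaly == pytest.approx(mq, abs=3 * se_q)


# -- fuzzing ------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_random_bundle_trace_invariants(seed):
    """Random valid parameter bundles keep unit mass, monotone deaths and
    weights bounded by occupancy on a two-line sequence."""
    ps = random_parameter_set(np.random.default_rng(seed), n_lines=2)
    tr = run_cohort(ps.sequences[0], ps)
    np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)
    assert (np.diff(tr.occupancy[:, tr.space.dead]) >= -1e-12).all()
    assert (tr.accrual_weights <= tr.occupancy + 1e-12).all()
    assert (tr.accrual_weights >= -1e-15).all()
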