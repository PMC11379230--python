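"""OWSA, price-reduction scenarios, and the probabilistic analysis."""

import numpy as np
import pandas as pd
import pytest

from psorseq.cea import evaluate_sequence
from psorseq.sensitivity import (
    PSADraws,
    apply_parameter,
    ceac,
    expected_loss,
    owsa,
    run_psa,
    sample_beta,
    sample_gamma,
    scenario_price_reduction,
)


# -- parameter registry -------------------------------------------------------

def test_apply_parameter_unknown_id(params):
    with pytest.raises(KeyError):
        apply_parameter(params, "SEC.vial_colour", 1.0)
    with pytest.raises(KeyError):
        apply_parameter(params, "XYZ.p_response", 0.5)


def test_apply_parameter_immutability(params):
    p2 = apply_parameter(params, "SEC.unit_cost", 1.0)
    assert params.treatment("SEC").unit_cost == 3555.0
    assert p2.treatment("SEC").unit_cost == 1.0


# -- one-way sensitivity ------------------------------------------------------

def test_owsa_noop_parameter(params):
    """A parameter absent from both compared sequences leaves the ICER alone."""
    e = owsa("PHOTO.unit_cost", 1141.0, 1712.0, params, "SEC→UST→ADA", "SYS→UST→ADA")
    assert e.icer_at_low == pytest.approx(e.icer_baseline)
    assert e.icer_at_high == pytest.approx(e.icer_baseline)
    assert e.spread == pytest.approx(0.0)


def test_owsa_degenerate_range(params):
    t = params.treatment("SEC")
    e = owsa("SEC.unit_cost", t.unit_cost, t.unit_cost, params, "SEC→UST→ADA", "SYS→UST→ADA")
    assert e.spread == pytest.approx(0.0)
    assert not e.non_monotone


def test_owsa_sec_price_monotone(params):
    e = owsa("SEC.unit_cost", 2844.0, 4266.0, params, "SEC→UST→ADA", "SYS→UST→ADA")
    assert e.icer_at_low < e.icer_baseline < e.icer_at_high
    assert not e.non_monotone


# -- scenarios ----------------------------------------------------------------

def test_scenario_zero_fraction_is_base_case(params):
    df = scenario_price_reduction(0.0, params, comparators=["SYS→UST→ADA"])
    base = evaluate_sequence(params, "SEC→UST→ADA")
    row = df[df.sequence == "SEC→UST→ADA"].iloc[0]
    assert row.total_cost == pytest.approx(base.cost)
    assert row.total_qaly == pytest.approx(base.qaly)


def test_scenario_full_reduction_removes_originator_drug_cost(params):
    df = scenario_price_reduction(1.0, params, comparators=["SYS→UST→ADA"])
    row = df[df.sequence == "SEC→UST→ADA"].iloc[0]
    # remaining cost is admin + monitoring + BSC only: far below base case
    assert row.total_cost < 0.15 * evaluate_sequence(params, "SEC→UST→ADA").cost


def test_scenario_comparator_cost_falls(params):
    base = evaluate_sequence(params, "SYS→UST→ADA").cost
    df = scenario_price_reduction(0.40, params, comparators=["SYS→UST→ADA"])
    comp_row = df[(df.sequence == "SYS→UST→ADA")].iloc[0]
    assert comp_row.total_cost < base   # comparator holds UST and ADA


def test_scenario_biosimilar_price_untouched(params):
    df = scenario_price_reduction(0.40, params, comparators=["SYS→UST→ADA"])
    bs = df[df.sequence == "SEC→UST→ADA_BS"].iloc[0]
    orig = df[df.sequence == "SEC→UST→ADA"].iloc[0]
    # with originators discounted 40%, ADA originator (888.6/vial) undercuts
    # the untouched biosimilar price (886 stays)
    assert bs.total_cost > 0.99 * orig.total_cost


def test_scenario_icers_strictly_decreasing(params):
    icers = []
    for f in (0.20, 0.30, 0.40, 0.50):
        df = scenario_price_reduction(f, params, comparators=["SYS→UST→ADA"])
        row = df[df.sequence == "SEC→UST→ADA"].iloc[0]
        icers.append(float(row.icer))
    assert all(a > b for a, b in zip(icers, icers[1:]))


# -- distribution sampling ----------------------------------------------------

def test_gamma_moment_matching():
    rng = np.random.default_rng(0)
    mean, se = 3555.0, 355.5
    draws = np.array([sample_gamma(mean, se, rng) for _ in range(200_000)])
    assert draws.mean() == pytest.approx(mean, abs=3 * se / np.sqrt(draws.size))
    assert draws.std() == pytest.approx(se, rel=0.02)
    assert (draws > 0).all()
    assert sample_gamma(mean, 0.0, rng) == mean
    with pytest.raises(ValueError):
        sample_gamma(0.0, 1.0, rng)


def test_beta_moment_matching():
    rng = np.random.default_rng(1)
    mean, se = 0.85, 0.085
    nu = mean * (1 - mean) / se**2 - 1
    assert nu == pytest.approx(16.6471, abs=1e-4)
    assert mean * nu == pytest.approx(14.1500, abs=1e-3)
    assert (1 - mean) * nu == pytest.approx(2.4971, abs=1e-3)
    draws = np.array([sample_beta(mean, se, rng) for _ in range(200_000)])
    assert draws.mean() == pytest.approx(mean, abs=3 * se / np.sqrt(draws.size))
    assert draws.std() == pytest.approx(se, rel=0.02)
    assert ((draws > 0) & (draws < 1)).all()
    assert sample_beta(0.5, 0.0, rng) == 0.5


def test_beta_infeasible_variance_names_parameter():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="my_param"):
        sample_beta(0.99, 0.5, rng, name="my_param")


# -- probabilistic analysis ---------------------------------------------------

SEQS = ["SYS→UST→ADA", "SEC→UST→ADA", "SEC→UST→ADA_BS"]


def test_psa_seeded_determinism(params):
    a = run_psa(params, SEQS, iterations=20, seed=42)
    b = run_psa(params, SEQS, iterations=20, seed=42)
    assert (a.costs == b.costs).all()
    assert (a.qalys == b.qalys).all()
    assert a.param_draws.equals(b.param_draws)
    c = run_psa(params, SEQS, iterations=20, seed=43)
    assert not (a.costs == c.costs).all()


def test_psa_degenerate_se_converges_to_deterministic(params):
    draws = run_psa(params, SEQS, iterations=5, seed=0, se_fraction=1e-7)
    for k, label in enumerate(SEQS):
        det = evaluate_sequence(params, label)
        assert draws.costs[:, k].mean() == pytest.approx(det.cost, rel=1e-4)
        assert draws.qalys[:, k].mean() == pytest.approx(det.qaly, rel=1e-4)


def test_psa_biosimilar_shares_noncost_draws(params):
    draws = run_psa(params, SEQS, iterations=10, seed=3)
    cols = set(draws.param_draws.columns)
    # ADA_BS aliases the originator's efficacy/discontinuation draws ...
    assert "ADA.p_response" in cols and "ADA_BS.p_response" not in cols
    assert "ADA_BS.annual_discontinuation" not in cols
    # ... and state utilities are block-level draws
    assert "utilities.biologic.u_responder" in cols
    assert "SEC.u_responder" not in cols
    # but keeps its own acquisition cost draw
    assert "ADA_BS.unit_cost" in cols
    assert not (draws.param_draws["ADA_BS.unit_cost"]
                == draws.param_draws["ADA.unit_cost"]).any()


def test_ceac_normalisation_and_dominance():
    # hand-built ensemble: strategy B dominant in every draw
    d = PSADraws(labels=["A", "B"],
                 costs=np.array([[100.0, 50.0]] * 4),
                 qalys=np.array([[1.0, 2.0]] * 4),
                 param_draws=pd.DataFrame(), seed=0)
    c = ceac(d, [0, 50_000, 100_000])
    np.testing.assert_allclose(c.probability.sum(axis=1), 1.0)
    np.testing.assert_allclose(c.probability[:, 1], 1.0)
    e = expected_loss(d, [0, 50_000])
    np.testing.assert_allclose(e.loss[:, 1], 0.0)
    assert (e.loss >= 0).all()


def test_ceac_ties_split_equally():
    d = PSADraws(labels=["A", "B"],
                 costs=np.array([[100.0, 100.0]] * 3),
                 qalys=np.array([[1.0, 1.0]] * 3),
                 param_draws=pd.DataFrame(), seed=0)
    c = ceac(d, [10_000.0])
    np.testing.assert_allclose(c.probability, 0.5)


def test_elc_argmin_matches_mean_nb_argmax(params):
    draws = run_psa(params, SEQS, iterations=60, seed=11)
    grid = np.arange(0, 400_001, 20_000.0)
    e = expected_loss(draws, grid)
    for i, lam in enumerate(grid):
        mean_nb = (lam * draws.qalys - draws.costs).mean(axis=0)
        assert e.loss[i].argmin() == mean_nb.argmax()
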