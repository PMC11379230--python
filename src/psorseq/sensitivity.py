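"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis re-runs the full model twice per parameter with
that parameter at its range endpoints, everything else at baseline.  The
utility inputs form one grouped tornado bar (all state utilities moved to
their low/high ends together), mirroring how the utility evidence enters the
model as a block; a per-parameter mode is also available.

Scenario analysis rescales the originator biologics' vial prices and
re-runs every sequence including the comparators.

The probabilistic analysis redraws every cost parameter from a
moment-matched gamma distribution and every probability/utility from a
moment-matched beta distribution, with standard error equal to a fixed
fraction of the baseline (default 10%).  One parameter receives one draw per
iteration shared by all strategies (common random parameters), a biosimilar
shares all non-cost draws with its originator, and state utilities are drawn
at block level (biologic vs non-biologic).  The life table and the discount
rate stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import icer
from .markov import Totals, accrue_totals, cycle_mortality, run_cohort
from .params import ModelConfig, ParameterSet, Sequence

__all__ = [
    "OwsaEntry", "PSADraws", "CeacCurve", "ElcCurve",
    "apply_parameter", "owsa", "owsa_default_entries", "run_owsa",
    "scenario_price_reduction",
    "sample_gamma", "sample_beta", "run_psa", "ceac", "expected_loss",
]

UTILITY_GROUP = "utilities"


# ---------------------------------------------------------------------------
# parameter registry

def _split(pid: str) -> tuple[str, str]:
    head, _, tail = pid.partition(".")
    if not tail:
        raise KeyError(f"unknown parameter id {pid!r}")
    return head, tail


def apply_parameter(params: ParameterSet, pid: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one registered parameter replaced.

    Ids: ``"<treatment>.<field>"`` (fields of :data:`psorseq.params.DSA_FIELDS`),
    ``"bsc.utility"``, ``"bsc.cost_cycle"``, ``"outpatient.cost_per_visit"``,
    ``"config.discount_annual"``.
    """
    head, tail = _split(pid)
    if head == "config":
        if tail != "discount_annual":
            raise KeyError(f"unknown parameter id {pid!r}")
        return replace(params, config=replace(params.config, discount_annual=value))
    if head == "bsc":
        if tail not in ("utility", "cost_cycle"):
            raise KeyError(f"unknown parameter id {pid!r}")
        return params.with_bsc(replace(params.bsc, **{tail: value}))
    if head == "outpatient":
        if tail != "cost_per_visit":
            raise KeyError(f"unknown parameter id {pid!r}")
        return replace(params, outpatient=replace(params.outpatient, cost_per_visit=value))
    from .params import DSA_FIELDS

    if head not in params.treatments or tail not in DSA_FIELDS:
        raise KeyError(f"unknown parameter id {pid!r}")
    return params.with_treatment(params.treatment(head).with_value(tail, value))


def _utility_ids(params: ParameterSet) -> list[tuple[str, float, float]]:
    """(id, low, high) for every state-utility input, defaulting to +/-20%."""
    out = []
    for name in sorted(params.treatments):
        t = params.treatment(name)
        for fname in ("u_responder", "u_nonresponder"):
            base = getattr(t, fname)
            lo, hi = t.dsa_ranges.get(fname, (0.8 * base, min(1.0, 1.2 * base)))
            out.append((f"{name}.{fname}", lo, hi))
    if params.bsc.dsa_utility is not None:
        out.append(("bsc.utility", *params.bsc.dsa_utility))
    else:
        u = params.bsc.utility
        out.append(("bsc.utility", 0.8 * u, min(1.0, 1.2 * u)))
    return out


def _apply_group(params: ParameterSet, end: str) -> ParameterSet:
    idx = 1 if end == "low" else 2
    p = params
    for entry in _utility_ids(params):
        p = apply_parameter(p, entry[0], entry[idx])
    return p


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis

@dataclass(frozen=True)
class OwsaEntry:
    parameter: str
    low: float | None
    high: float | None
    icer_at_low: float | str
    icer_at_high: float | str
    icer_baseline: float | str

    @property
    def spread(self) -> float:
        if isinstance(self.icer_at_low, str) or isinstance(self.icer_at_high, str):
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)

    @property
    def non_monotone(self) -> bool:
        """Baseline ICER falling outside the [low, high] ICER envelope."""
        vals = (self.icer_at_low, self.icer_at_high, self.icer_baseline)
        if any(isinstance(v, str) for v in vals):
            return False
        lo, hi = sorted(vals[:2])
        return not (lo - 1e-9 <= self.icer_baseline <= hi + 1e-9)


def _icer_for(params: ParameterSet, sequence: str | Sequence, comparator: str | Sequence):
    seq = params.sequence(sequence) if isinstance(sequence, str) else sequence
    comp = params.sequence(comparator) if isinstance(comparator, str) else comparator
    cfg = params.config
    tot_s = accrue_totals(run_cohort(seq, params, cfg), seq, params, cfg)
    tot_c = accrue_totals(run_cohort(comp, params, cfg), comp, params, cfg)
    return icer(tot_s, tot_c)


def owsa(
    varied_param: str,
    low: float | None,
    high: float | None,
    base_params: ParameterSet,
    sequence: str | Sequence,
    comparator: str | Sequence,
) -> OwsaEntry:
    """ICER of ``sequence`` vs ``comparator`` with one parameter at its ends.

    ``varied_param`` may be a registered id or the grouped ``"utilities"``
    bar, for which ``low``/``high`` are ignored and every utility input moves
    to its own range end jointly.
    """
    base = _icer_for(base_params, sequence, comparator)
    if varied_param == UTILITY_GROUP:
        p_lo = _apply_group(base_params, "low")
        p_hi = _apply_group(base_params, "high")
        low = high = None
    else:
        p_lo = apply_parameter(base_params, varied_param, low)
        p_hi = apply_parameter(base_params, varied_param, high)
    return OwsaEntry(
        parameter=varied_param, low=low, high=high,
        icer_at_low=_icer_for(p_lo, sequence, comparator),
        icer_at_high=_icer_for(p_hi, sequence, comparator),
        icer_baseline=base,
    )


def owsa_default_entries(params: ParameterSet,
                         discount_range: tuple[float, float] = (0.01, 0.05),
                         group_utilities: bool = True) -> list[tuple[str, float | None, float | None]]:
    """Tornado parameter list: drug unit costs, outpatient cost, BSC cost,
    response probabilities, discontinuation risks, utilities (grouped by
    default) and the discount rate.  Ranges come from the loaded DSA columns,
    falling back to +/-20% of baseline."""
    entries: list[tuple[str, float | None, float | None]] = []
    for name in sorted(params.treatments):
        t = params.treatment(name)
        for fname in ("unit_cost", "p_response", "annual_discontinuation"):
            base = getattr(t, fname)
            lo, hi = t.dsa_ranges.get(fname, (0.8 * base, 1.2 * base))
            entries.append((f"{name}.{fname}", lo, hi))
        if not group_utilities:
            for fname in ("u_responder", "u_nonresponder"):
                base = getattr(t, fname)
                lo, hi = t.dsa_ranges.get(fname, (0.8 * base, min(1.0, 1.2 * base)))
                entries.append((f"{name}.{fname}", lo, hi))
    ov = params.outpatient
    lo, hi = ov.dsa_range or (0.8 * ov.cost_per_visit, 1.2 * ov.cost_per_visit)
    entries.append(("outpatient.cost_per_visit", lo, hi))
    c = params.bsc.cost_cycle
    entries.append(("bsc.cost_cycle", 0.8 * c, 1.2 * c))
    if group_utilities:
        entries.append((UTILITY_GROUP, None, None))
    else:
        entries.append(("bsc.utility", *(params.bsc.dsa_utility or
                                         (0.8 * params.bsc.utility, min(1.0, 1.2 * params.bsc.utility)))))
    entries.append(("config.discount_annual", *discount_range))
    return entries


def run_owsa(params: ParameterSet, sequence: str | Sequence, comparator: str | Sequence,
             entries: list[tuple[str, float | None, float | None]] | None = None) -> pd.DataFrame:
    """Tornado table sorted by descending ICER spread."""
    entries = entries if entries is not None else owsa_default_entries(params)
    rows = []
    for pid, lo, hi in entries:
        e = owsa(pid, lo, hi, params, sequence, comparator)
        rows.append({"parameter": e.parameter, "low": e.low, "high": e.high,
                     "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
                     "icer_baseline": e.icer_baseline, "spread": e.spread,
                     "non_monotone": e.non_monotone})
    df = pd.DataFrame(rows)
    return df.sort_values("spread", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# scenario analysis: originator price reductions

def scenario_price_reduction(
    fraction: float,
    params: ParameterSet,
    sequences: list[str | Sequence] | None = None,
    comparators: list[str | Sequence] | None = None,
    originators: tuple[str, ...] = ("SEC", "UST", "ADA"),
) -> pd.DataFrame:
    """Re-run all sequences with originator vial prices cut by ``fraction``.

    Biosimilars, systemic therapy and phototherapy keep their prices.  Each
    non-comparator sequence is reported against every comparator with its
    recomputed ICER.
    """
    if not (0.0 <= fraction < 1.0) and fraction != 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    p = params
    for name in originators:
        t = params.treatment(name)
        p = p.with_treatment(t.with_value("unit_cost", t.unit_cost * (1.0 - fraction)))
    seqs = [p.sequence(s) if isinstance(s, str) else s
            for s in (sequences or [s.label for s in p.sequences])]
    comps = [p.sequence(s) if isinstance(s, str) else s for s in (comparators or [])]
    totals = {s.label: accrue_totals(run_cohort(s, p), s, p) for s in {*seqs, *comps}}
    rows = []
    comp_list = comps or [None]
    for comp in comp_list:
        if comp is not None:
            tc = totals[comp.label]
            rows.append({"comparator": comp.label, "sequence": comp.label,
                         "total_cost": tc.cost, "total_qaly": tc.qaly, "icer": "",
                         "reduction": fraction})
        for s in seqs:
            if comp is not None and s.label == comp.label:
                continue
            t = totals[s.label]
            row = {"comparator": comp.label if comp else "", "sequence": s.label,
                   "total_cost": t.cost, "total_qaly": t.qaly, "reduction": fraction}
            row["icer"] = icer(t, totals[comp.label]) if comp is not None else ""
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def sample_gamma(mean: float, se: float, rng: np.random.Generator) -> float:
    """Moment-matched gamma draw: shape ``(mean/se)**2``, scale ``se**2/mean``."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean!r}")
    if se == 0:
        return float(mean)
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def sample_beta(mean: float, se: float, rng: np.random.Generator, name: str = "") -> float:
    """Moment-matched beta draw: ``alpha = mean*nu``, ``beta = (1-mean)*nu``
    with ``nu = mean*(1-mean)/se**2 - 1``."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie in (0, 1), got {mean!r} ({name})")
    if se == 0:
        return float(mean)
    if se**2 >= mean * (1.0 - mean):
        raise ValueError(f"infeasible beta variance for {name or 'parameter'}: "
                         f"se**2 = {se**2:.4g} >= mean*(1-mean) = {mean * (1 - mean):.4g}")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


@dataclass
class PSADraws:
    """Monte-Carlo ensemble: per-iteration totals per strategy plus the
    sampled parameter vectors."""

    labels: list[str]
    costs: np.ndarray   # (iterations, strategies)
    qalys: np.ndarray   # (iterations, strategies)
    param_draws: pd.DataFrame
    seed: int

    @property
    def iterations(self) -> int:
        return self.costs.shape[0]


def _psa_registry(params: ParameterSet) -> list[tuple[str, str, float, list[tuple[str, str]]]]:
    """Sorted draw registry: (draw id, dist, baseline, [(target, field), ...]).

    A ``<base>_BS`` biosimilar aliases its originator's probability draws;
    utilities are drawn once per biologic / non-biologic block.
    """
    reg: dict[str, tuple[str, float, list[tuple[str, str]]]] = {}

    def add(did: str, dist: str, base: float, slot: tuple[str, str]) -> None:
        if did in reg:
            reg[did][2].append(slot)
        else:
            reg[did] = (dist, base, [slot])

    for name in sorted(params.treatments):
        t = params.treatment(name)
        base_name = name[:-3] if name.endswith("_BS") and name[:-3] in params.treatments else None
        eff_owner = base_name or name
        add(f"{eff_owner}.p_response", "beta", params.treatment(eff_owner).p_response,
            (name, "p_response"))
        add(f"{eff_owner}.annual_discontinuation", "beta",
            params.treatment(eff_owner).annual_discontinuation, (name, "annual_discontinuation"))
        block = "biologic" if t.is_biologic else "nonbiologic"
        add(f"utilities.{block}.u_responder", "beta", t.u_responder, (name, "u_responder"))
        add(f"utilities.{block}.u_nonresponder", "beta", t.u_nonresponder, (name, "u_nonresponder"))
        add(f"{name}.unit_cost", "gamma", t.unit_cost, (name, "unit_cost"))
        add(f"{name}.monitoring_cost_cycle", "gamma", t.monitoring_cost_cycle,
            (name, "monitoring_cost_cycle"))
    add("bsc.utility", "beta", params.bsc.utility, ("bsc", "utility"))
    if params.bsc.cost_cycle > 0:
        add("bsc.cost_cycle", "gamma", params.bsc.cost_cycle, ("bsc", "cost_cycle"))
    add("outpatient.cost_per_visit", "gamma", params.outpatient.cost_per_visit,
        ("outpatient", "cost_per_visit"))
    return [(did, dist, base, slots) for did, (dist, base, slots) in sorted(reg.items())]


def run_psa(
    params: ParameterSet,
    sequences: list[str | Sequence],
    config: ModelConfig | None = None,
    iterations: int | None = None,
    seed: int | None = None,
    se_fraction: float | None = None,
) -> PSADraws:
    """Joint parameter resampling with common random parameters.

    Every registered cost is redrawn from a gamma and every probability or
    utility from a beta, both moment-matched with SE equal to
    ``se_fraction`` of the baseline; within an iteration the same draw feeds
    every strategy.  Identical seeds give bit-identical ensembles.
    """
    cfg = config or params.config
    iters = iterations if iterations is not None else cfg.psa_iterations
    sf = se_fraction if se_fraction is not None else cfg.psa_se_fraction
    sd = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(sd)
    seqs = [params.sequence(s) if isinstance(s, str) else s for s in sequences]
    labels = [s.label for s in seqs]
    p_die = cycle_mortality(params, cfg)

    reg = _psa_registry(params)
    costs = np.zeros((iters, len(seqs)))
    qalys = np.zeros((iters, len(seqs)))
    draws = np.zeros((iters, len(reg)))
    for it in range(iters):
        p = params
        for j, (did, dist, base, slots) in enumerate(reg):
            if dist == "gamma":
                v = sample_gamma(base, sf * base, rng) if base > 0 else 0.0
            else:
                v = sample_beta(base, sf * base, rng, name=did)
            draws[it, j] = v
            for target, fname in slots:
                p = apply_parameter(p, f"{target}.{fname}", v)
        for k, s in enumerate(seqs):
            tot = accrue_totals(run_cohort(s, p, cfg, p_die=p_die), s, p, cfg)
            costs[it, k], qalys[it, k] = tot.cost, tot.qaly
    pdf = pd.DataFrame(draws, columns=[r[0] for r in reg])
    return PSADraws(labels=labels, costs=costs, qalys=qalys, param_draws=pdf, seed=sd)


@dataclass
class CeacCurve:
    """Probability each strategy maximises net benefit, per WTP value."""

    wtp: np.ndarray
    labels: list[str]
    probability: np.ndarray  # (len(wtp), strategies)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=self.labels)
        df.insert(0, "wtp", self.wtp)
        return df


@dataclass
class ElcCurve:
    """Expected foregone net benefit of each strategy, per WTP value (USD)."""

    wtp: np.ndarray
    labels: list[str]
    loss: np.ndarray  # (len(wtp), strategies)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loss, columns=self.labels)
        df.insert(0, "wtp", self.wtp)
        return df


def _net_benefit(draws: PSADraws, lam: float) -> np.ndarray:
    return lam * draws.qalys - draws.costs


def ceac(draws: PSADraws, wtp_grid) -> CeacCurve:
    """Fraction of iterations in which each strategy attains maximal net
    benefit (ties split equally)."""
    grid = np.asarray(wtp_grid, dtype=float)
    prob = np.zeros((grid.size, len(draws.labels)))
    for i, lam in enumerate(grid):
        nb = _net_benefit(draws, lam)
        best = nb.max(axis=1, keepdims=True)
        winners = nb >= best - 1e-9
        prob[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(wtp=grid, labels=list(draws.labels), probability=prob)


def expected_loss(draws: PSADraws, wtp_grid) -> ElcCurve:
    """Mean of ``max_s NB - NB(s)`` across iterations, per WTP value."""
    grid = np.asarray(wtp_grid, dtype=float)
    loss = np.zeros((grid.size, len(draws.labels)))
    for i, lam in enumerate(grid):
        nb = _net_benefit(draws, lam)
        loss[i] = (nb.max(axis=1, keepdims=True) - nb).mean(axis=0)
    return ElcCurve(wtp=grid, labels=list(draws.labels), loss=loss)
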