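"""Incremental cost-effectiveness analysis and the BSC cost calibration.

All biologic-first sequences are compared pairwise against a stated common
comparator (systemic-first or phototherapy-first), as incremental cost per
QALY (ICER) and net monetary benefit.  Biosimilar substitution is summarised
as ``(originator cost - biosimilar cost) / originator cost x 100``.

The per-cycle cost of best supportive care is the one input without a
published value; it is recovered by one-dimensional calibration: the BSC
cycle cost is the root of ``total_cost(comparator; c) = target``, a strictly
increasing map solved by bisection to 0.01 USD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .markov import Totals, accrue_totals, run_cohort
from .params import BSCParams, ModelConfig, ParameterSet, Sequence

__all__ = [
    "DOMINANT", "DOMINATED", "UNDEFINED",
    "CEAResult", "SavingsResult",
    "icer", "nmb", "cost_savings",
    "evaluate_sequence", "calibrate_bsc_cost", "CalibrationError",
]

DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # dearer and less effective
UNDEFINED = "undefined"    # zero QALY difference


class CalibrationError(RuntimeError):
    """Raised when the calibration target is below the feasible range."""


@dataclass(frozen=True)
class CEAResult:
    """One sequence against one comparator."""

    label: str
    total_cost: float
    total_qaly: float
    vs_comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | str
    nmb_at: dict[float, float]


@dataclass(frozen=True)
class SavingsResult:
    """Biosimilar substitution summary for one originator/biosimilar pair."""

    originator: str
    biosimilar: str
    originator_cost: float
    biosimilar_cost: float

    @property
    def cost_difference(self) -> float:
        return self.originator_cost - self.biosimilar_cost

    @property
    def saving_pct(self) -> float:
        return 100.0 * self.cost_difference / self.originator_cost


def icer(intervention: Totals, comparator: Totals) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance flag."""
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    if dq == 0.0:
        return UNDEFINED
    if dq > 0:
        return DOMINANT if dc < 0 else dc / dq
    return DOMINATED if dc > 0 else dc / dq


def nmb(intervention: Totals, comparator: Totals, wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost``."""
    return wtp * (intervention.qaly - comparator.qaly) - (intervention.cost - comparator.cost)


def cost_savings(originator: Totals, biosimilar: Totals, *,
                 originator_label: str = "originator",
                 biosimilar_label: str = "biosimilar") -> SavingsResult:
    """Cost difference and percentage saving of a biosimilar substitution."""
    return SavingsResult(
        originator=originator_label, biosimilar=biosimilar_label,
        originator_cost=originator.cost, biosimilar_cost=biosimilar.cost,
    )


def evaluate_sequence(params: ParameterSet, sequence: Sequence | str,
                      config: ModelConfig | None = None) -> Totals:
    """Run the cohort for one sequence and return its discounted totals."""
    seq = params.sequence(sequence) if isinstance(sequence, str) else sequence
    cfg = config or params.config
    trace = run_cohort(seq, params, cfg)
    return accrue_totals(trace, seq, params, cfg)


def calibrate_bsc_cost(
    comparator_sequence: Sequence | str,
    target_total_cost: float,
    params: ParameterSet,
    config: ModelConfig | None = None,
    tol: float = 0.01,
) -> float:
    """Per-cycle BSC cost at which the comparator's total cost hits the target.

    Raises :class:`CalibrationError` when the target lies below the total at
    BSC cost zero (the minimum achievable under the remaining inputs).
    """
    seq = params.sequence(comparator_sequence) if isinstance(comparator_sequence, str) else comparator_sequence
    cfg = config or params.config

    def total_at(c: float) -> float:
        p = params.with_bsc(replace(params.bsc, cost_cycle=c))
        return evaluate_sequence(p, seq, cfg).cost

    lo_val = total_at(0.0)
    if target_total_cost < lo_val - tol:
        raise CalibrationError(
            f"target {target_total_cost:,.2f} below minimum achievable "
            f"{lo_val:,.2f} (comparator {seq.label} at BSC cost 0)"
        )
    if abs(target_total_cost - lo_val) <= tol:
        return 0.0
    hi = 1.0
    while total_at(hi) < target_total_cost:
        hi *= 2.0
        if hi > 1e9:
            raise CalibrationError("calibration bracket exceeded 1e9 USD/cycle")
    return float(brentq(lambda c: total_at(c) - target_total_cost, 0.0, hi, xtol=tol))
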