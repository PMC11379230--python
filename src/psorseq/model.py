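"""Model / Results interface over the cohort engine.

:class:`PsoriasisCEModel` bundles a validated parameter set;
:meth:`PsoriasisCEModel.fit` resolves the one unpublished input (the BSC
per-cycle cost, by calibration against the comparator's printed total),
runs every sequence, and returns a :class:`CEAFitResults` carrying totals,
pairwise incremental results and biosimilar savings, with ``summary()``
rendering the incremental analysis tables.  Sensitivity analyses (tornado,
price-reduction scenarios, probabilistic) hang off the results object so
they always run from the calibrated inputs.

Example
-------
>>> from psorseq import PsoriasisCEModel
>>> res = PsoriasisCEModel.default().fit()
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import (
    CalibrationError,
    CEAResult,
    SavingsResult,
    calibrate_bsc_cost,
    cost_savings,
    evaluate_sequence,
    icer,
    nmb,
)
from .markov import Totals, accrue_totals, run_cohort
from .params import BSCParams, ParameterSet, Sequence, default_parameter_path, load_parameters
from .sensitivity import (
    PSADraws,
    ceac,
    expected_loss,
    run_owsa,
    run_psa,
    scenario_price_reduction,
)

__all__ = ["PsoriasisCEModel", "CEAFitResults", "PSAResults"]


def _is_biosimilar(name: str, treatments) -> bool:
    return name.endswith("_BS") and name[:-3] in treatments


def _hash_params(params: ParameterSet) -> str:
    cfg = params.config
    payload = {
        "config": {k: getattr(cfg, k) for k in (
            "cycle_weeks", "weeks_per_year", "start_age", "max_age",
            "discount_annual", "rr_mortality", "wtp_threshold",
            "psa_iterations", "psa_se_fraction", "seed", "rr_in_bsc",
            "half_cycle_costs")},
        "bsc_cost_cycle": params.bsc.cost_cycle,
        "sequences": [s.label for s in params.sequences],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class PsoriasisCEModel:
    """Lifetime sequential-treatment cohort model for one parameter bundle."""

    def __init__(self, params: ParameterSet):
        self.params = params.validate()

    @classmethod
    def from_files(cls, path: str | Path) -> "PsoriasisCEModel":
        """Build from a ``parameters.yaml`` bundle on disk."""
        return cls(load_parameters(path))

    @classmethod
    def default(cls) -> "PsoriasisCEModel":
        """Build from the bundled moderate-to-severe psoriasis fixture."""
        return cls.from_files(default_parameter_path())

    # -- structure ---------------------------------------------------------

    def config_hash(self) -> str:
        """Short digest of the loaded configuration (for run manifests)."""
        return _hash_params(self.params)

    @property
    def comparators(self) -> list[Sequence]:
        """Sequences opening with a non-biologic line (standard first-line care)."""
        return [s for s in self.params.sequences
                if not self.params.treatment(s.lines[0]).is_biologic]

    @property
    def interventions(self) -> list[Sequence]:
        return [s for s in self.params.sequences
                if self.params.treatment(s.lines[0]).is_biologic]

    def biosimilar_pairs(self) -> list[tuple[str, str]]:
        """(originator label, biosimilar label) for every sequence pair that
        differs only by an originator <-> biosimilar swap."""
        labels = {s.label for s in self.params.sequences}
        pairs = []
        for s in self.params.sequences:
            if any(_is_biosimilar(n, self.params.treatments) for n in s.lines):
                orig = "→".join(n[:-3] if _is_biosimilar(n, self.params.treatments) else n
                                for n in s.lines)
                if orig in labels:
                    pairs.append((orig, s.label))
        return pairs

    # -- fitting -----------------------------------------------------------

    def fit(self, calibration: str = "clamp", bsc_cost: float | None = None) -> "CEAFitResults":
        """Calibrate the BSC cycle cost and evaluate every sequence.

        calibration
            ``"clamp"`` (default): if the calibration target lies below the
            feasible range, pin the BSC cost at the boundary (zero) and
            record the shortfall in ``calibration_note``;
            ``"strict"``: propagate :class:`CalibrationError` instead;
            ``"none"``: keep the loaded/explicit BSC cost.
        bsc_cost
            Explicit per-cycle BSC cost, bypassing calibration.
        """
        params = self.params
        note = "bsc cost taken from inputs"
        if bsc_cost is not None:
            params = params.with_bsc(replace(params.bsc, cost_cycle=float(bsc_cost)))
            note = f"bsc cost fixed at {bsc_cost:,.2f}"
        elif calibration != "none" and params.calibration_target is not None:
            comp_label, target = params.calibration_target
            try:
                c = calibrate_bsc_cost(comp_label, target, params)
                note = (f"bsc cost calibrated to {c:,.2f}/cycle so that "
                        f"{comp_label} totals {target:,.2f}")
            except CalibrationError as err:
                if calibration == "strict":
                    raise
                c = 0.0
                note = f"calibration infeasible, clamped to 0: {err}"
            params = params.with_bsc(replace(params.bsc, cost_cycle=c))
        totals = {s.label: evaluate_sequence(params, s) for s in params.sequences}
        return CEAFitResults(model=self, params=params, totals=totals, calibration_note=note)


@dataclass
class PSAResults:
    """Probabilistic sensitivity analysis ensemble with curve constructors."""

    draws: PSADraws
    wtp_grid: np.ndarray

    def ceac(self):
        return ceac(self.draws, self.wtp_grid)

    def expected_loss(self):
        return expected_loss(self.draws, self.wtp_grid)

    def summary_frame(self) -> pd.DataFrame:
        """Mean probabilistic totals per strategy."""
        return pd.DataFrame({
            "sequence": self.draws.labels,
            "mean_cost": self.draws.costs.mean(axis=0),
            "mean_qaly": self.draws.qalys.mean(axis=0),
        })


@dataclass
class CEAFitResults:
    """Fitted base case: calibrated inputs, totals, incremental comparisons."""

    model: PsoriasisCEModel
    params: ParameterSet
    totals: dict[str, Totals]
    calibration_note: str
    _cache: dict = field(default_factory=dict, repr=False)

    # -- base-case accessors ----------------------------------------------

    @property
    def bsc_cost_cycle(self) -> float:
        return self.params.bsc.cost_cycle

    def total(self, label: str) -> Totals:
        return self.totals[self.params.sequence(label).label]

    def compare(self, sequence: str, comparator: str, wtp: float | None = None) -> CEAResult:
        """Pairwise incremental result of ``sequence`` against ``comparator``."""
        s, c = self.total(sequence), self.total(comparator)
        wtps = [wtp] if wtp is not None else [self.params.config.wtp_threshold]
        return CEAResult(
            label=self.params.sequence(sequence).label,
            total_cost=s.cost, total_qaly=s.qaly,
            vs_comparator=self.params.sequence(comparator).label,
            delta_cost=s.cost - c.cost, delta_qaly=s.qaly - c.qaly,
            icer=icer(s, c), nmb_at={w: nmb(s, c, w) for w in wtps},
        )

    def results_table(self, comparator: str) -> pd.DataFrame:
        """Incremental analysis of every biologic-first sequence vs one
        comparator, with biosimilar cost differences where applicable."""
        comp = self.params.sequence(comparator).label
        by_bs = {bs: orig for orig, bs in self.model.biosimilar_pairs()}
        rows = [{"sequence": comp, "total_cost": self.total(comp).cost,
                 "total_qaly": self.total(comp).qaly, "icer": "",
                 "cost_difference": "", "saving_pct": ""}]
        for s in self.model.interventions:
            r = self.compare(s.label, comp)
            row = {"sequence": s.label, "total_cost": r.total_cost,
                   "total_qaly": r.total_qaly, "icer": r.icer,
                   "cost_difference": "", "saving_pct": ""}
            if s.label in by_bs:
                sv = self.savings_for(by_bs[s.label], s.label)
                row["cost_difference"] = sv.cost_difference
                row["saving_pct"] = sv.saving_pct
            rows.append(row)
        return pd.DataFrame(rows)

    def savings_for(self, originator: str, biosimilar: str) -> SavingsResult:
        return cost_savings(self.total(originator), self.total(biosimilar),
                            originator_label=self.params.sequence(originator).label,
                            biosimilar_label=self.params.sequence(biosimilar).label)

    def savings_table(self) -> pd.DataFrame:
        rows = []
        for orig, bs in self.model.biosimilar_pairs():
            sv = self.savings_for(orig, bs)
            rows.append({"originator": sv.originator, "biosimilar": sv.biosimilar,
                         "originator_cost": sv.originator_cost,
                         "biosimilar_cost": sv.biosimilar_cost,
                         "cost_difference": sv.cost_difference,
                         "saving_pct": sv.saving_pct})
        return pd.DataFrame(rows)

    def nmb_table(self, wtp: float | None = None) -> pd.DataFrame:
        w = wtp if wtp is not None else self.params.config.wtp_threshold
        rows = []
        for comp in self.model.comparators:
            for s in self.model.interventions:
                r = self.compare(s.label, comp.label, wtp=w)
                rows.append({"comparator": comp.label, "sequence": s.label,
                             "wtp": w, "nmb": r.nmb_at[w], "icer": r.icer})
        return pd.DataFrame(rows)

    def frontier_table(self, wtp: float | None = None) -> pd.DataFrame:
        """Fully incremental analysis across all strategies (optional mode):
        strategies sorted by cost, dominated ones flagged, ICERs chained
        along the efficiency frontier."""
        items = sorted(self.totals.items(), key=lambda kv: kv[1].cost)
        rows = []
        frontier: list[tuple[str, Totals]] = []
        for label, tot in items:
            status, chained = "frontier", ""
            while frontier:
                _, prev = frontier[-1]
                if tot.qaly <= prev.qaly:
                    status, chained = "dominated", ""
                    break
                r = (tot.cost - prev.cost) / (tot.qaly - prev.qaly)
                if len(frontier) >= 2:
                    _, prev2 = frontier[-2]
                    r_prev = (prev.cost - prev2.cost) / (prev.qaly - prev2.qaly)
                    if r < r_prev:  # extended dominance of the previous point
                        frontier.pop()
                        continue
                chained = r
                break
            if status == "frontier":
                frontier.append((label, tot))
            rows.append({"sequence": label, "total_cost": tot.cost,
                         "total_qaly": tot.qaly, "status": status, "icer_frontier": chained})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text incremental cost-effectiveness tables per comparator."""
        cfg = self.params.config
        out = [
            "Sequential-treatment cost-effectiveness model (lifetime horizon)",
            f"  cycle: {cfg.cycle_weeks:g} weeks | start age {cfg.start_age:g} | "
            f"discount {cfg.discount_annual:.1%}/yr | WTP {cfg.wtp_threshold:,.2f} USD/QALY",
            f"  {self.calibration_note}",
            "",
        ]
        for comp in self.model.comparators:
            df = self.results_table(comp.label).copy()
            for col in ("total_cost", "icer", "cost_difference"):
                df[col] = df[col].map(lambda v: f"{v:,.0f}" if isinstance(v, (int, float, np.floating)) else v)
            df["total_qaly"] = df["total_qaly"].map(lambda v: f"{v:.2f}")
            df["saving_pct"] = df["saving_pct"].map(
                lambda v: f"{v:.1f}" if isinstance(v, (int, float, np.floating)) else v)
            out.append(f"vs {comp.label}:")
            out.append(df.to_string(index=False))
            out.append("")
        return "\n".join(out)

    # -- sensitivity analyses (run from the calibrated inputs) -------------

    def owsa(self, sequence: str, comparator: str, entries=None) -> pd.DataFrame:
        return run_owsa(self.params, sequence, comparator, entries=entries)

    def scenario(self, fractions=(0.20, 0.30, 0.40, 0.50),
                 originators: tuple[str, ...] = ("SEC", "UST", "ADA")) -> pd.DataFrame:
        """Originator price-reduction scenarios, all sequences vs all comparators."""
        frames = [
            scenario_price_reduction(
                f, self.params,
                sequences=[s.label for s in self.model.interventions],
                comparators=[c.label for c in self.model.comparators],
                originators=originators,
            )
            for f in fractions
        ]
        return pd.concat(frames, ignore_index=True)

    def psa(self, sequences=None, iterations: int | None = None,
            seed: int | None = None, wtp_grid=None) -> PSAResults:
        seqs = sequences or [s.label for s in self.params.sequences]
        draws = run_psa(self.params, seqs, iterations=iterations, seed=seed)
        grid = np.asarray(wtp_grid if wtp_grid is not None else self.params.config.wtp_grid,
                          dtype=float)
        return PSAResults(draws=draws, wtp_grid=grid)

    # -- provenance --------------------------------------------------------

    def config_hash(self) -> str:
        """Short digest of the calibrated configuration (for run manifests)."""
        return _hash_params(self.params)
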