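"""Per-cycle drug, administration and monitoring costs.

Biologic acquisition cost is priced per injection event: each event consumes
``ceil(dose / vial_mg)`` indivisible vials.  Induction events are enumerated
from the label schedule within the first cycle on the drug; maintenance
cycles carry the long-run average number of doses per cycle
(``cycle_weeks / interval``, possibly fractional).  Administration cost is
one outpatient visit per injection for provider-administered biologics, a
single visit for self-administered ones (charged in the induction cycle),
two sessions per week of narrowband UVB for phototherapy, and nothing for
oral systemic therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import BSCParams, DosingSchedule, ModelConfig, OutpatientCost, TreatmentParams

__all__ = ["CycleCost", "injection_events", "drug_cost_cycle", "admin_cost_cycle", "cycle_cost"]

PHASES = ("induction", "maintenance", "bsc")


@dataclass(frozen=True)
class CycleCost:
    """Cost of one cycle in one state, split into its components (USD)."""

    drug: float
    administration: float
    monitoring: float
    phase: str

    @property
    def total(self) -> float:
        return self.drug + self.administration + self.monitoring


def injection_events(schedule: DosingSchedule, phase: str, cycle_weeks: float) -> tuple[float, float]:
    """(number of injection events, total mg administered) in one cycle.

    Maintenance returns the fractional long-run average
    ``cycle_weeks / maintenance_interval_weeks`` rather than a
    calendar-aligned integer count.
    """
    if phase == "bsc":
        raise ValueError("no dosing in BSC")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if phase == "maintenance":
        n = cycle_weeks / schedule.maintenance_interval_weeks
        return n, n * schedule.maintenance_dose_mg
    # induction: loading event, listed weeks, then interval-spaced until cycle end
    weeks = [schedule.loading_week, *schedule.induction_dose_weeks]
    w = weeks[-1] + schedule.maintenance_interval_weeks
    while w < cycle_weeks - 1e-9:
        weeks.append(w)
        w += schedule.maintenance_interval_weeks
    mg = schedule.loading_dose_mg + (len(weeks) - 1) * schedule.induction_dose_mg
    return float(len(weeks)), mg


def _vials(dose_mg: float, vial_mg: float) -> int:
    """Indivisible vials consumed by one injection event."""
    return int(math.ceil(dose_mg / vial_mg - 1e-12))


def drug_cost_cycle(treatment: TreatmentParams, phase: str, cycle_weeks: float = 16.0) -> float:
    """Acquisition cost of one cycle in the given phase (USD).

    Biologics: sum over injection events of vials x vial cost (fractional
    maintenance event counts scale linearly).  Systemic therapy and
    phototherapy carry their flat per-cycle cost in every phase.
    """
    if phase == "bsc":
        raise ValueError("no dosing in BSC")
    if not treatment.is_biologic:
        return treatment.flat_cycle_cost
    sch = treatment.dosing
    assert sch is not None
    if phase == "induction":
        n_events, _ = injection_events(sch, "induction", cycle_weeks)
        loading_vials = _vials(sch.loading_dose_mg, sch.vial_mg)
        other_vials = _vials(sch.induction_dose_mg, sch.vial_mg)
        return (loading_vials + (n_events - 1) * other_vials) * treatment.vial_cost
    n_events, _ = injection_events(sch, "maintenance", cycle_weeks)
    return n_events * _vials(sch.maintenance_dose_mg, sch.vial_mg) * treatment.vial_cost


def admin_cost_cycle(
    treatment: TreatmentParams,
    phase: str,
    outpatient: OutpatientCost,
    cycle_weeks: float = 16.0,
) -> float:
    """Administration cost of one cycle in the given phase (USD)."""
    if phase == "bsc":
        raise ValueError("no administration in BSC")
    visit = outpatient.cost_per_visit
    if treatment.admin_model == "per_injection":
        n_events, _ = injection_events(treatment.dosing, phase, cycle_weeks)
        return n_events * visit
    if treatment.admin_model == "once_only":
        return visit if phase == "induction" else 0.0
    if treatment.admin_model == "sessions_per_week":
        return treatment.sessions_per_week * cycle_weeks * visit
    return 0.0


def cycle_cost(
    treatment_or_bsc: TreatmentParams | BSCParams,
    phase: str,
    outpatient: OutpatientCost,
    config: ModelConfig,
) -> CycleCost:
    """Assemble drug + administration + monitoring for one state-cycle."""
    if isinstance(treatment_or_bsc, BSCParams):
        if phase != "bsc":
            raise ValueError("BSC parameters imply phase 'bsc'")
        return CycleCost(0.0, 0.0, treatment_or_bsc.cost_cycle, phase="bsc")
    t = treatment_or_bsc
    return CycleCost(
        drug=drug_cost_cycle(t, phase, config.cycle_weeks),
        administration=admin_cost_cycle(t, phase, outpatient, config.cycle_weeks),
        monitoring=t.monitoring_cost_cycle,
        phase=phase,
    )
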