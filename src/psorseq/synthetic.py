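"""Synthetic inputs: a parametric life table and randomized parameter bundles.

The national abridged life table the mortality inputs call for is not
redistributable here, so general-population mortality is emulated with a
Gompertz-Makeham hazard ``mu(x) = a + b * c**x``.  The default parameters
are calibrated so period life expectancy at birth is ~75 years
(Malaysia-like).  An annual death probability follows by integrating the
hazard over each year of age:

    q(x) = 1 - exp(-(a + b * c**x * (c - 1) / ln c))

``random_parameter_set`` draws complete valid parameter bundles for
property-testing the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    BSCParams,
    DosingSchedule,
    LifeTable,
    ModelConfig,
    OutpatientCost,
    ParameterSet,
    Sequence,
    TreatmentParams,
)

__all__ = ["MortalityModel", "make_life_table", "life_expectancy", "random_parameter_set"]


@dataclass(frozen=True)
class MortalityModel:
    """Gompertz-Makeham hazard: ``makeham_a`` age-independent background,
    ``gompertz_b`` senescent scale, ``gompertz_c`` rate of ageing per year."""

    makeham_a: float = 3.0e-4
    gompertz_b: float = 3.88e-5
    gompertz_c: float = 1.10

    def validate(self) -> "MortalityModel":
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_c <= 1:
            raise ValueError("require a >= 0, b > 0, c > 1")
        return self

    def annual_q(self, age: float) -> float:
        """Death probability over [age, age+1) from the integrated hazard."""
        a, b, c = self.makeham_a, self.gompertz_b, self.gompertz_c
        cum = a + b * c**age * (c - 1.0) / math.log(c)
        return 1.0 - math.exp(-cum)


def make_life_table(model: MortalityModel | None = None,
                    age_range: tuple[int, int] = (0, 110)) -> LifeTable:
    """Single-year life table from a Gompertz-Makeham mortality model."""
    m = (model or MortalityModel()).validate()
    ages = np.arange(age_range[0], age_range[1] + 1)
    return LifeTable(ages, [m.annual_q(a) for a in ages])


def life_expectancy(lifetable: LifeTable, from_age: float = 0.0) -> float:
    """Period life expectancy by survivorship summation (half-year credit in
    the year of death)."""
    s, e = 1.0, 0.0
    for age in np.arange(math.floor(from_age), lifetable.ages[-1] + 1):
        q = lifetable.annual_q(age)
        e += s * (1.0 - 0.5 * q)
        s *= 1.0 - q
    return e


def _dosing(rng: np.random.Generator, cycle_weeks: float) -> DosingSchedule:
    interval = float(rng.choice([2.0, 4.0, 8.0, 12.0]))
    n_listed = int(rng.integers(0, 4))
    listed = tuple(float(w) for w in sorted(rng.choice(
        np.arange(1, cycle_weeks), size=n_listed, replace=False))) if n_listed else ()
    vial = float(rng.choice([40.0, 45.0, 150.0]))
    return DosingSchedule(
        loading_dose_mg=vial * int(rng.integers(1, 3)), loading_week=0.0,
        induction_dose_weeks=listed, induction_dose_mg=vial,
        maintenance_interval_weeks=interval, maintenance_dose_mg=vial, vial_mg=vial,
    )


def random_parameter_set(rng: np.random.Generator, n_lines: int = 2) -> ParameterSet:
    """A complete, valid random parameter bundle for engine fuzzing.

    Probabilities are drawn in the open unit interval, unit costs over a wide
    positive range, and a random sequence of ``n_lines`` distinct treatments
    is included; the bundle always passes load-time validation.
    """
    cfg = ModelConfig(
        discount_annual=float(rng.uniform(0.0, 0.08)),
        rr_mortality=float(rng.uniform(1.0, 2.5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    ).validate()
    names = [f"T{i}" for i in range(n_lines + 1)]
    treatments = {}
    for name in names:
        kind = str(rng.choice(["biologic", "systemic", "phototherapy"]))
        biologic = kind == "biologic"
        treatments[name] = TreatmentParams(
            name=name, kind=kind,
            p_response=float(rng.uniform(0.05, 0.95)),
            annual_discontinuation=float(rng.uniform(0.05, 0.95)),
            u_responder=float(rng.uniform(0.3, 1.0)),
            u_nonresponder=float(rng.uniform(0.1, 0.9)),
            monitoring_cost_cycle=float(rng.uniform(0, 500)),
            unit_cost=float(rng.uniform(10, 12_000)),
            admin_model=str(rng.choice(["per_injection", "once_only", "none"])) if biologic
            else ("sessions_per_week" if kind == "phototherapy" else "none"),
            dosing=_dosing(rng, cfg.cycle_weeks) if biologic else None,
        ).validate(cfg.cycle_weeks)
    lt = make_life_table(MortalityModel(
        makeham_a=float(rng.uniform(0.0, 2e-3)),
        gompertz_b=float(rng.uniform(1e-5, 2e-4)),
        gompertz_c=float(rng.uniform(1.05, 1.13)),
    ))
    lines = tuple(rng.choice(names, size=n_lines, replace=False))
    seq = Sequence(label="→".join(lines), lines=lines)
    ps = ParameterSet(
        config=cfg, treatments=treatments,
        bsc=BSCParams(utility=float(rng.uniform(0.0, 0.5)),
                      cost_cycle=float(rng.uniform(0, 3_000))),
        outpatient=OutpatientCost(cost_per_visit=float(rng.uniform(10, 200))),
        sequences=[seq], lifetable=lt,
    )
    return ps.validate()
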