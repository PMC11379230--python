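"""Parameter data model and fixture I/O.

The model is driven by three plain-text files:

``parameters.yaml``
    Global configuration (cycle length, discounting, mortality relative
    risk, willingness-to-pay threshold, PSA settings), best-supportive-care
    inputs, outpatient visit cost, biologic dosing schedules and the list of
    treatment sequences.

``treatments.csv``
    One row per therapy with response probability, annual discontinuation
    risk, state utilities, per-cycle monitoring cost, acquisition cost
    (per-vial for biologics, flat per-cycle for systemic therapy and
    phototherapy) and the deterministic sensitivity-analysis range of each
    varied field.

``lifetable.csv``
    ``age,qx`` rows giving the annual all-cause death probability.  Ages may
    be single years or the lower bounds of abridged bands; a band's ``qx``
    applies to every single year it covers.

All monetary amounts are US dollars.  Utilities are per year of life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TSequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "ModelConfig",
    "DosingSchedule",
    "TreatmentParams",
    "BSCParams",
    "OutpatientCost",
    "Sequence",
    "LifeTable",
    "ParameterSet",
    "load_parameters",
    "write_parameters",
    "validate_dsa_ranges",
    "default_parameter_path",
]

KINDS = ("biologic", "systemic", "phototherapy")
ADMIN_MODELS = ("per_injection", "once_only", "sessions_per_week", "none")

#: fields of :class:`TreatmentParams` that carry a DSA range
DSA_FIELDS = (
    "p_response",
    "annual_discontinuation",
    "u_responder",
    "u_nonresponder",
    "monitoring_cost_cycle",
    "unit_cost",
)


class ParameterError(ValueError):
    """Raised when a parameter file or value fails validation."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(name, f"probability/utility {p!r} outside [0, 1]")


def _check_nonneg(name: str, x: float) -> None:
    if x < 0:
        raise ParameterError(name, f"cost {x!r} must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings.

    The cohort enters the model at ``start_age`` with the first treatment's
    induction cycle and is followed in cycles of ``cycle_weeks`` weeks until
    ``max_age``, beyond which death within the cycle is certain.  Costs and
    QALYs are discounted at ``discount_annual`` per year.  ``rr_mortality``
    multiplies the all-cause mortality hazard of the general-population life
    table (severe psoriasis carries excess mortality).
    """

    cycle_weeks: float = 16.0
    weeks_per_year: float = 52.0
    start_age: float = 35.0
    max_age: float = 100.0
    discount_annual: float = 0.03
    rr_mortality: float = 1.52
    wtp_threshold: float = 104_337.19
    wtp_grid: tuple[float, ...] = tuple(np.arange(0.0, 400_001.0, 2_000.0))
    psa_iterations: int = 10_000
    psa_se_fraction: float = 0.10
    seed: int = 20_240_906
    #: apply the mortality relative risk in BSC as well (the whole cohort has
    #: severe disease); set False to restrict the excess risk to active lines.
    rr_in_bsc: bool = True
    #: charge leavers half a cycle of their origin state's cost (within-cycle
    #: correction).  With False, induction failures are charged the full
    #: induction cycle cost instead.
    half_cycle_costs: bool = True

    @property
    def cycle_years(self) -> float:
        return self.cycle_weeks / self.weeks_per_year

    @property
    def n_cycles(self) -> int:
        """Cycles needed to carry the cohort from start_age past max_age."""
        return int(math.ceil((self.max_age - self.start_age) / self.cycle_years)) + 1

    def validate(self) -> "ModelConfig":
        if self.cycle_weeks <= 0:
            raise ParameterError("cycle_weeks", "must be > 0")
        if not (0.0 <= self.discount_annual < 1.0):
            raise ParameterError("discount_annual", "must be in [0, 1)")
        if self.rr_mortality <= 0:
            raise ParameterError("rr_mortality", "must be > 0")
        if not self.start_age < self.max_age:
            raise ParameterError("start_age", "must be < max_age")
        if not (0.0 < self.psa_se_fraction < 1.0):
            raise ParameterError("psa_se_fraction", "must be in (0, 1)")
        if self.psa_iterations <= 0:
            raise ParameterError("psa_iterations", "must be > 0")
        return self


@dataclass(frozen=True)
class DosingSchedule:
    """Label-schedule dosing of a biologic within the repeating cycle grid.

    Induction (first cycle on the drug) administers ``loading_dose_mg`` at
    ``loading_week``, ``induction_dose_mg`` at each week in
    ``induction_dose_weeks``, and further ``induction_dose_mg`` doses every
    ``maintenance_interval_weeks`` from the last listed week until the cycle
    ends.  Maintenance cycles administer ``maintenance_dose_mg`` every
    ``maintenance_interval_weeks`` (a fractional average per cycle).
    """

    loading_dose_mg: float
    loading_week: float
    induction_dose_weeks: tuple[float, ...]
    induction_dose_mg: float
    maintenance_interval_weeks: float
    maintenance_dose_mg: float
    vial_mg: float

    def validate(self, cycle_weeks: float, name: str = "dosing") -> "DosingSchedule":
        weeks = (self.loading_week, *self.induction_dose_weeks)
        if any(w2 <= w1 for w1, w2 in zip(weeks, weeks[1:])):
            raise ParameterError(f"{name}.induction_dose_weeks", "must be strictly increasing")
        if any(not (0 <= w < cycle_weeks) for w in weeks):
            raise ParameterError(f"{name}.induction_dose_weeks", f"weeks must lie in [0, {cycle_weeks})")
        if self.maintenance_interval_weeks <= 0:
            raise ParameterError(f"{name}.maintenance_interval_weeks", "must be > 0")
        if self.vial_mg <= 0:
            raise ParameterError(f"{name}.vial_mg", "must be > 0")
        if min(self.loading_dose_mg, self.induction_dose_mg, self.maintenance_dose_mg) < 0:
            raise ParameterError(f"{name}.dose_mg", "doses must be >= 0")
        return self


@dataclass(frozen=True)
class TreatmentParams:
    """One therapy: efficacy, persistence, utilities and cost components.

    ``unit_cost`` is the price per vial for biologics and the flat per-cycle
    acquisition cost for systemic therapy and phototherapy.  ``dsa_ranges``
    maps a field name from :data:`DSA_FIELDS` to its (low, high)
    deterministic sensitivity-analysis range.
    """

    name: str
    kind: str
    p_response: float
    annual_discontinuation: float
    u_responder: float
    u_nonresponder: float
    monitoring_cost_cycle: float
    unit_cost: float
    admin_model: str
    dosing: DosingSchedule | None = None
    sessions_per_week: float = 2.0
    dsa_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def is_biologic(self) -> bool:
        return self.kind == "biologic"

    @property
    def vial_cost(self) -> float:
        if not self.is_biologic:
            raise ParameterError(f"{self.name}.vial_cost", "not a biologic")
        return self.unit_cost

    @property
    def flat_cycle_cost(self) -> float:
        if self.is_biologic:
            raise ParameterError(f"{self.name}.flat_cycle_cost", "biologics are costed per vial")
        return self.unit_cost

    def validate(self, cycle_weeks: float) -> "TreatmentParams":
        if self.kind not in KINDS:
            raise ParameterError(f"{self.name}.kind", f"unknown kind {self.kind!r}")
        if self.admin_model not in ADMIN_MODELS:
            raise ParameterError(f"{self.name}.admin_model", f"unknown admin model {self.admin_model!r}")
        for fname in ("p_response", "annual_discontinuation", "u_responder", "u_nonresponder"):
            _check_prob(f"{self.name}.{fname}", getattr(self, fname))
        for fname in ("monitoring_cost_cycle", "unit_cost"):
            _check_nonneg(f"{self.name}.{fname}", getattr(self, fname))
        if self.is_biologic:
            if self.dosing is None:
                raise ParameterError(f"{self.name}.dosing", "biologic without a dosing schedule")
            self.dosing.validate(cycle_weeks, name=f"{self.name}.dosing")
        for fname in self.dsa_ranges:
            if fname not in DSA_FIELDS:
                raise ParameterError(f"{self.name}.dsa_ranges", f"unknown DSA field {fname!r}")
        return self

    def with_value(self, field_name: str, value: float) -> "TreatmentParams":
        """Copy with one scalar field replaced (used by OWSA/PSA/scenarios)."""
        if field_name not in DSA_FIELDS:
            raise ParameterError(field_name, "not a varied treatment field")
        return replace(self, **{field_name: value})


@dataclass(frozen=True)
class BSCParams:
    """Best supportive care: state utility and per-cycle cost.

    The per-cycle cost is usually calibrated against a printed comparator
    total rather than supplied directly (see
    :func:`psorseq.cea.calibrate_bsc_cost`).
    """

    utility: float = 0.11
    cost_cycle: float = 0.0
    dsa_utility: tuple[float, float] | None = None

    def validate(self) -> "BSCParams":
        _check_prob("bsc.utility", self.utility)
        _check_nonneg("bsc.cost_cycle", self.cost_cycle)
        return self


@dataclass(frozen=True)
class OutpatientCost:
    """Cost of one outpatient visit (drives administration costs)."""

    cost_per_visit: float = 71.0
    dsa_range: tuple[float, float] | None = None

    def validate(self) -> "OutpatientCost":
        _check_nonneg("outpatient.cost_per_visit", self.cost_per_visit)
        return self


@dataclass(frozen=True)
class Sequence:
    """An ordered course of one to three active lines ending in BSC."""

    label: str
    lines: tuple[str, ...]

    def validate(self, known: Iterable[str]) -> "Sequence":
        if not (1 <= len(self.lines) <= 3):
            raise ParameterError(f"sequence {self.label}", "needs 1-3 active lines")
        if len(set(self.lines)) != len(self.lines):
            raise ParameterError(f"sequence {self.label}", "repeated treatment within sequence")
        unknown = [t for t in self.lines if t not in set(known)]
        if unknown:
            raise ParameterError(f"sequence {self.label}", f"unknown treatment {unknown[0]!r}")
        return self

    @classmethod
    def from_string(cls, text: str) -> "Sequence":
        toks = [t.strip().replace(" ", "_") for t in text.replace("->", "→").split("→") if t.strip()]
        toks = [t for t in toks if t.upper() != "BSC"]
        return cls(label="→".join(toks), lines=tuple(toks))


class LifeTable:
    """Age → annual all-cause death probability q(a).

    Entries may be single years of age or lower bounds of abridged bands;
    the band's probability applies to every year up to the next entry.
    """

    def __init__(self, ages: TSequence[float], qx: TSequence[float]):
        ages = np.asarray(ages, dtype=float)
        qx = np.asarray(qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ParameterError("lifetable", "ages and qx must be equal-length 1-d arrays")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.qx = qx[order]
        if np.any(np.diff(self.ages) <= 0):
            raise ParameterError("lifetable.age", "ages must be strictly increasing")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ParameterError("lifetable.qx", "q(a) must lie in [0, 1]")

    def annual_q(self, age: float) -> float:
        """q for the single year of age containing ``age`` (constant in band)."""
        idx = int(np.searchsorted(self.ages, math.floor(age), side="right")) - 1
        if idx < 0:
            raise ParameterError("lifetable", f"age {age} below table domain {self.ages[0]}")
        return float(self.qx[idx])

    def covers(self, lo: float, hi: float) -> bool:
        return self.ages[0] <= lo and hi <= self.ages[-1] + 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


@dataclass
class ParameterSet:
    """The full validated input bundle the model runs from."""

    config: ModelConfig
    treatments: dict[str, TreatmentParams]
    bsc: BSCParams
    outpatient: OutpatientCost
    sequences: list[Sequence]
    lifetable: LifeTable
    #: comparator label / printed total cost that pins the BSC cycle cost
    calibration_target: tuple[str, float] | None = None

    def treatment(self, name: str) -> TreatmentParams:
        try:
            return self.treatments[name]
        except KeyError:
            raise ParameterError("treatment", f"unknown treatment {name!r}") from None

    def sequence(self, label: str) -> Sequence:
        label = Sequence.from_string(label).label
        for s in self.sequences:
            if s.label == label:
                return s
        raise ParameterError("sequence", f"unknown sequence {label!r}")

    def with_treatment(self, t: TreatmentParams) -> "ParameterSet":
        new = dict(self.treatments)
        new[t.name] = t
        return replace(self, treatments=new)

    def with_bsc(self, bsc: BSCParams) -> "ParameterSet":
        return replace(self, bsc=bsc)

    def validate(self) -> "ParameterSet":
        self.config.validate()
        for t in self.treatments.values():
            t.validate(self.config.cycle_weeks)
        self.bsc.validate()
        self.outpatient.validate()
        for s in self.sequences:
            s.validate(self.treatments)
        if not self.lifetable.covers(self.config.start_age, self.config.max_age):
            raise ParameterError(
                "lifetable",
                f"must cover ages [{self.config.start_age}, {self.config.max_age}]",
            )
        return self


# ---------------------------------------------------------------------------
# file I/O

_CONFIG_KEYS = {
    "cycle_weeks", "weeks_per_year", "start_age", "max_age", "discount_annual",
    "rr_mortality", "wtp_threshold", "wtp_grid", "psa_iterations",
    "psa_se_fraction", "seed", "rr_in_bsc", "half_cycle_costs",
}
_BSC_KEYS = {"utility", "utility_low", "utility_high", "cost_cycle", "calibrate_to"}
_OUTPATIENT_KEYS = {"cost_per_visit", "low", "high"}
_DOSING_KEYS = {
    "loading_dose_mg", "loading_week", "induction_dose_weeks", "induction_dose_mg",
    "maintenance_interval_weeks", "maintenance_dose_mg", "vial_mg",
}
_TOP_KEYS = {"config", "bsc", "outpatient", "dosing", "sequences", "files"}

TREATMENT_COLUMNS = [
    "name", "kind",
    "p_response", "p_response_low", "p_response_high",
    "annual_disc", "annual_disc_low", "annual_disc_high",
    "u_resp", "u_resp_low", "u_resp_high",
    "u_nonresp", "u_nonresp_low", "u_nonresp_high",
    "monitor_cycle", "monitor_low", "monitor_high",
    "vial_cost", "vial_cost_low", "vial_cost_high",
    "flat_cycle_cost", "flat_low", "flat_high",
    "admin_model",
]


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ParameterError(where, f"unknown key {unknown[0]!r}")


def default_parameter_path() -> Path:
    """Path of the bundled psoriasis parameter fixture."""
    return Path(__file__).parent / "data" / "parameters.yaml"


def _parse_wtp_grid(spec) -> tuple[float, ...]:
    if spec is None:
        return ModelConfig().wtp_grid
    if isinstance(spec, str):
        start, stop, step = (float(x) for x in spec.split(":"))
        return tuple(np.arange(start, stop + 0.5 * step, step))
    if isinstance(spec, Mapping):
        _reject_unknown(spec, {"start", "stop", "step"}, "config.wtp_grid")
        return tuple(np.arange(float(spec["start"]), float(spec["stop"]) + 0.5 * float(spec["step"]),
                               float(spec["step"])))
    return tuple(float(x) for x in spec)


def _float_or_none(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate the YAML/CSV parameter bundle rooted at ``path``.

    ``path`` points at the ``parameters.yaml`` file; the treatment table and
    life table are read from the sibling files named under its ``files`` key
    (defaults ``treatments.csv`` / ``lifetable.csv``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ParameterError(str(path), "top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, str(path))

    cfg_raw = dict(raw.get("config", {}))
    _reject_unknown(cfg_raw, _CONFIG_KEYS, "config")
    if "wtp_grid" in cfg_raw:
        cfg_raw["wtp_grid"] = _parse_wtp_grid(cfg_raw["wtp_grid"])
    config = ModelConfig(**cfg_raw)

    bsc_raw = dict(raw.get("bsc", {}))
    _reject_unknown(bsc_raw, _BSC_KEYS, "bsc")
    calibration_target = None
    if "calibrate_to" in bsc_raw:
        cal = bsc_raw.pop("calibrate_to")
        _reject_unknown(cal, {"comparator", "total_cost"}, "bsc.calibrate_to")
        calibration_target = (Sequence.from_string(cal["comparator"]).label, float(cal["total_cost"]))
    dsa_u = None
    if "utility_low" in bsc_raw or "utility_high" in bsc_raw:
        dsa_u = (float(bsc_raw.pop("utility_low")), float(bsc_raw.pop("utility_high")))
    bsc = BSCParams(utility=float(bsc_raw.get("utility", 0.11)),
                    cost_cycle=float(bsc_raw.get("cost_cycle", 0.0)),
                    dsa_utility=dsa_u)

    out_raw = dict(raw.get("outpatient", {}))
    _reject_unknown(out_raw, _OUTPATIENT_KEYS, "outpatient")
    dsa_o = None
    if "low" in out_raw or "high" in out_raw:
        dsa_o = (float(out_raw["low"]), float(out_raw["high"]))
    outpatient = OutpatientCost(cost_per_visit=float(out_raw.get("cost_per_visit", 71.0)), dsa_range=dsa_o)

    dosing: dict[str, DosingSchedule] = {}
    for name, d in dict(raw.get("dosing", {})).items():
        _reject_unknown(d, _DOSING_KEYS, f"dosing.{name}")
        dosing[name] = DosingSchedule(
            loading_dose_mg=float(d["loading_dose_mg"]),
            loading_week=float(d["loading_week"]),
            induction_dose_weeks=tuple(float(w) for w in d.get("induction_dose_weeks", [])),
            induction_dose_mg=float(d["induction_dose_mg"]),
            maintenance_interval_weeks=float(d["maintenance_interval_weeks"]),
            maintenance_dose_mg=float(d["maintenance_dose_mg"]),
            vial_mg=float(d["vial_mg"]),
        )

    files = dict(raw.get("files", {}))
    _reject_unknown(files, {"treatments", "lifetable"}, "files")
    tpath = path.parent / files.get("treatments", "treatments.csv")
    lpath = path.parent / files.get("lifetable", "lifetable.csv")
    if not tpath.exists():
        raise FileNotFoundError(f"treatment table not found: {tpath}")
    if not lpath.exists():
        raise FileNotFoundError(f"life table not found: {lpath}")

    tdf = pd.read_csv(tpath)
    unknown_cols = sorted(set(tdf.columns) - set(TREATMENT_COLUMNS))
    if unknown_cols:
        raise ParameterError("treatments.csv", f"unknown column {unknown_cols[0]!r}")
    missing = [c for c in TREATMENT_COLUMNS if c not in tdf.columns]
    if missing:
        raise ParameterError("treatments.csv", f"missing column {missing[0]!r}")

    treatments: dict[str, TreatmentParams] = {}
    for _, row in tdf.iterrows():
        name = str(row["name"])
        kind = str(row["kind"])
        vial = _float_or_none(row["vial_cost"])
        flat = _float_or_none(row["flat_cycle_cost"])
        if kind == "biologic":
            if vial is None:
                raise ParameterError(f"{name}.vial_cost", "biologic requires a vial cost")
            unit, unit_lo, unit_hi = vial, _float_or_none(row["vial_cost_low"]), _float_or_none(row["vial_cost_high"])
        else:
            if flat is None:
                raise ParameterError(f"{name}.flat_cycle_cost", "non-biologic requires a flat cycle cost")
            unit, unit_lo, unit_hi = flat, _float_or_none(row["flat_low"]), _float_or_none(row["flat_high"])
        ranges: dict[str, tuple[float, float]] = {}
        for fname, col in [
            ("p_response", "p_response"), ("annual_discontinuation", "annual_disc"),
            ("u_responder", "u_resp"), ("u_nonresponder", "u_nonresp"),
            ("monitoring_cost_cycle", "monitor"),
        ]:
            lo, hi = _float_or_none(row[f"{col}_low"]), _float_or_none(row[f"{col}_high"])
            if lo is not None and hi is not None:
                ranges[fname] = (lo, hi)
        if unit_lo is not None and unit_hi is not None:
            ranges["unit_cost"] = (unit_lo, unit_hi)
        treatments[name] = TreatmentParams(
            name=name, kind=kind,
            p_response=float(row["p_response"]),
            annual_discontinuation=float(row["annual_disc"]),
            u_responder=float(row["u_resp"]),
            u_nonresponder=float(row["u_nonresp"]),
            monitoring_cost_cycle=float(row["monitor_cycle"]),
            unit_cost=unit,
            admin_model=str(row["admin_model"]),
            dosing=dosing.get(name),
            dsa_ranges=ranges,
        )

    ldf = pd.read_csv(lpath)
    if sorted(ldf.columns) != ["age", "qx"]:
        raise ParameterError("lifetable.csv", "columns must be exactly age,qx")
    lifetable = LifeTable(ldf["age"].to_numpy(), ldf["qx"].to_numpy())

    sequences = [Sequence.from_string(s) for s in raw.get("sequences", [])]
    ps = ParameterSet(config=config, treatments=treatments, bsc=bsc, outpatient=outpatient,
                      sequences=sequences, lifetable=lifetable,
                      calibration_target=calibration_target)
    return ps.validate()


def write_parameters(ps: ParameterSet, directory: str | Path) -> Path:
    """Write ``ps`` back out as a parameters.yaml / treatments.csv /
    lifetable.csv bundle and return the YAML path (round-trips with
    :func:`load_parameters`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = ps.config
    doc = {
        "config": {
            "cycle_weeks": cfg.cycle_weeks, "weeks_per_year": cfg.weeks_per_year,
            "start_age": cfg.start_age, "max_age": cfg.max_age,
            "discount_annual": cfg.discount_annual, "rr_mortality": cfg.rr_mortality,
            "wtp_threshold": cfg.wtp_threshold,
            "wtp_grid": [float(x) for x in cfg.wtp_grid],
            "psa_iterations": cfg.psa_iterations, "psa_se_fraction": cfg.psa_se_fraction,
            "seed": cfg.seed, "rr_in_bsc": cfg.rr_in_bsc, "half_cycle_costs": cfg.half_cycle_costs,
        },
        "bsc": {"utility": ps.bsc.utility, "cost_cycle": ps.bsc.cost_cycle},
        "outpatient": {"cost_per_visit": ps.outpatient.cost_per_visit},
        "dosing": {},
        "sequences": [s.label for s in ps.sequences],
    }
    if ps.bsc.dsa_utility is not None:
        doc["bsc"]["utility_low"], doc["bsc"]["utility_high"] = ps.bsc.dsa_utility
    if ps.calibration_target is not None:
        doc["bsc"]["calibrate_to"] = {
            "comparator": ps.calibration_target[0], "total_cost": ps.calibration_target[1],
        }
    if ps.outpatient.dsa_range is not None:
        doc["outpatient"]["low"], doc["outpatient"]["high"] = ps.outpatient.dsa_range
    rows = []
    for t in ps.treatments.values():
        if t.dosing is not None:
            d = t.dosing
            doc["dosing"][t.name] = {
                "loading_dose_mg": d.loading_dose_mg, "loading_week": d.loading_week,
                "induction_dose_weeks": list(d.induction_dose_weeks),
                "induction_dose_mg": d.induction_dose_mg,
                "maintenance_interval_weeks": d.maintenance_interval_weeks,
                "maintenance_dose_mg": d.maintenance_dose_mg, "vial_mg": d.vial_mg,
            }
        r = {c: "" for c in TREATMENT_COLUMNS}
        r.update(name=t.name, kind=t.kind, p_response=t.p_response,
                 annual_disc=t.annual_discontinuation, u_resp=t.u_responder,
                 u_nonresp=t.u_nonresponder, monitor_cycle=t.monitoring_cost_cycle,
                 admin_model=t.admin_model)
        if t.is_biologic:
            r["vial_cost"] = t.unit_cost
        else:
            r["flat_cycle_cost"] = t.unit_cost
        col_of = {"p_response": "p_response", "annual_discontinuation": "annual_disc",
                  "u_responder": "u_resp", "u_nonresponder": "u_nonresp",
                  "monitoring_cost_cycle": "monitor",
                  "unit_cost": "vial_cost" if t.is_biologic else "flat"}
        for fname, (lo, hi) in t.dsa_ranges.items():
            r[f"{col_of[fname]}_low"], r[f"{col_of[fname]}_high"] = lo, hi
        rows.append(r)
    ypath = directory / "parameters.yaml"
    ypath.write_text(yaml.safe_dump(doc, sort_keys=False))
    pd.DataFrame(rows, columns=TREATMENT_COLUMNS).to_csv(directory / "treatments.csv", index=False)
    ps.lifetable.to_frame().to_csv(directory / "lifetable.csv", index=False)
    return ypath


def validate_dsa_ranges(treatments: Iterable[TreatmentParams]) -> list[tuple[str, str, float, float, float]]:
    """Report fields whose baseline value falls outside its DSA range.

    Returns ``(treatment, field, baseline, low, high)`` tuples; nothing is
    mutated.  A degenerate range with low == baseline == high is consistent.
    """
    out = []
    for t in treatments:
        for fname, (lo, hi) in t.dsa_ranges.items():
            base = getattr(t, fname)
            if not (lo <= base <= hi):
                out.append((t.name, fname, base, lo, hi))
    return out
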