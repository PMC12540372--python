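"""Clinical covariates -> model scaling factors.

Maps CYP2C9 diplotype, renal function (KDIGO-style GFR classes), cirrhosis
severity (Child-Turcotte-Pugh class), bodyweight and food state onto the
four dimensionless factors of the model, and composes them into a
simulation-ready :class:`~glimtwin.parameters.ParameterSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

from .parameters import (
    ParameterSet,
    apply_absorption,
    apply_bodyweight,
    apply_cirrhosis,
    apply_cyp2c9,
    apply_renal,
)

#: in-vitro-derived relative CYP2C9 enzyme activity per allele
ALLELE_ACTIVITY: dict[str, float] = {"*1": 1.0, "*2": 0.68, "*3": 0.23}

RenalClass = Literal["normal", "mild", "moderate", "severe"]
CtpClass = Literal["none", "CTP-A", "CTP-B", "CTP-C"]
FedState = Literal["fasted", "fed"]

#: renal-function scaling factor per KDIGO-style class
F_RENAL: dict[str, float] = {
    "normal": 1.0, "mild": 0.69, "moderate": 0.32, "severe": 0.19,
}

#: cirrhosis severity factor per CTP class.  CTP-C is a calibration anchor
#: fitted so a 1 mg dose yields ~3.5-fold AUC vs normal liver function
#: (see data/reference_calibration.json); A and B are interpolated
#: monotonically.  Config, not constants.
F_CIRRHOSIS: dict[str, float] = {
    "none": 0.0, "CTP-A": 0.35, "CTP-B": 0.65, "CTP-C": 0.8661986781302478,
}

#: fed-state bioavailability placeholder (scalar food effect)
F_ABSORPTION_FED = 0.85


def allele_activity(allele: str, table: dict[str, float] | None = None) -> float:
    """Relative activity of one CYP2C9 allele (extensible via ``table``)."""
    table = ALLELE_ACTIVITY if table is None else table
    try:
        return table[allele]
    except KeyError:
        raise ValueError(
            f"unknown CYP2C9 allele {allele!r}; supported: {sorted(table)}"
        ) from None


def diplotype_activity(genotype: str | tuple[str, str],
                       table: dict[str, float] | None = None) -> float:
    """Mean of the two constituent allele activities (order-symmetric)."""
    a1, a2 = parse_genotype(genotype)
    return 0.5 * (allele_activity(a1, table) + allele_activity(a2, table))


def parse_genotype(genotype: str | tuple[str, str]) -> tuple[str, str]:
    """'*1/*3' or ('*1', '*3') -> allele pair."""
    if isinstance(genotype, str):
        parts = genotype.split("/")
    else:
        parts = list(genotype)
    if len(parts) != 2:
        raise ValueError(
            f"a diplotype consists of exactly 2 alleles, got {genotype!r}"
        )
    return parts[0].strip(), parts[1].strip()


def renal_class_from_gfr(gfr: float) -> str:
    """KDIGO-style class from GFR in mL/min/1.73 m².

    Normal is (90, inf); mild [50, 90]; moderate [35, 50); severe (0, 35).
    The published 49/50 gap is closed with a half-open moderate interval.
    """
    if gfr <= 0:
        raise ValueError(f"GFR must be > 0, got {gfr}")
    if gfr > 90:
        return "normal"
    if gfr >= 50:
        return "mild"
    if gfr >= 35:
        return "moderate"
    return "severe"


def f_renal_for_class(renal_class: str) -> float:
    try:
        return F_RENAL[renal_class]
    except KeyError:
        raise ValueError(
            f"unknown renal class {renal_class!r}; supported: {sorted(F_RENAL)}"
        ) from None


def f_cirrhosis_for_ctp(ctp_class: str) -> float:
    try:
        return F_CIRRHOSIS[ctp_class]
    except KeyError:
        raise ValueError(
            f"unknown CTP class {ctp_class!r}; supported: {sorted(F_CIRRHOSIS)}"
        ) from None


@dataclass(frozen=True)
class ScalingFactors:
    f_cyp2c9: float = 1.0
    f_renal_function: float = 1.0
    f_cirrhosis: float = 0.0
    f_absorption: float = 1.0

    def __post_init__(self):
        if self.f_cyp2c9 < 0:
            raise ValueError("f_cyp2c9 must be >= 0")
        if not 0.0 < self.f_renal_function <= 1.0:
            raise ValueError("f_renal_function must be in (0, 1]")
        if not 0.0 <= self.f_cirrhosis <= 1.0:
            raise ValueError("f_cirrhosis must be in [0, 1]")
        if not 0.0 < self.f_absorption <= 1.0:
            raise ValueError("f_absorption must be in (0, 1]")


@dataclass(frozen=True)
class Patient:
    """Clinical covariates of a virtual patient.

    ``renal`` accepts either a class name or a numeric GFR (mL/min/1.73 m²),
    but not both semantics at once — a number is classified by
    :func:`renal_class_from_gfr`.
    """

    bodyweight: float = 75.0
    genotype: str = "*1/*1"
    renal: str | float = "normal"
    hepatic: str = "none"
    fed_state: FedState = "fasted"

    def __post_init__(self):
        parse_genotype(self.genotype)  # raises on malformed diplotypes
        if self.fed_state not in ("fasted", "fed"):
            raise ValueError(f"unknown fed_state {self.fed_state!r}")

    @property
    def renal_class(self) -> str:
        if isinstance(self.renal, (int, float)):
            return renal_class_from_gfr(float(self.renal))
        if self.renal not in F_RENAL:
            raise ValueError(
                f"unknown renal class {self.renal!r}; supported: {sorted(F_RENAL)}"
            )
        return self.renal

    def scaling_factors(self) -> ScalingFactors:
        return ScalingFactors(
            f_cyp2c9=diplotype_activity(self.genotype),
            f_renal_function=f_renal_for_class(self.renal_class),
            f_cirrhosis=f_cirrhosis_for_ctp(self.hepatic),
            f_absorption=1.0 if self.fed_state == "fasted" else F_ABSORPTION_FED,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "Patient":
        known = {"bodyweight", "genotype", "renal", "hepatic", "fed_state"}
        return cls(**{k: v for k, v in d.items() if k in known})


def build_parameters(patient: Patient, base: ParameterSet) -> ParameterSet:
    """Apply all covariate scalings of ``patient`` to ``base``.

    The apply_* operations only set stored factors, so the composition is
    order-independent (bitwise)."""
    f = patient.scaling_factors()
    p = apply_bodyweight(base, patient.bodyweight)
    p = apply_cyp2c9(p, f.f_cyp2c9)
    p = apply_renal(p, f.f_renal_function)
    p = apply_cirrhosis(p, f.f_cirrhosis)
    p = apply_absorption(p, f.f_absorption)
    return p


@dataclass(frozen=True)
class Scenario:
    """A runnable scenario: patient + dosing regimen (+ seed)."""

    patient: Patient = field(default_factory=Patient)
    dose_mg: float = 4.0
    route: str = "oral-tablet"
    n_doses: int = 1
    interval_h: float = 24.0
    t_end_h: float | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        patient = Patient.from_dict(d)
        known = {"dose_mg", "route", "n_doses", "interval_h", "t_end_h", "seed"}
        return cls(patient=patient, **{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path) -> "Scenario":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"scenario file {path} must contain an object")
        return cls.from_dict(data)
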