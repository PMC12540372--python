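"""Model parameters and patient-factor scaling.

The :class:`ParameterSet` holds all kinetic and physiological constants of
the glimepiride whole-body model at the 75-kg healthy fasted reference,
together with the four clinical scaling factors (CYP2C9 activity, renal
function, cirrhosis, food/bioavailability) and bodyweight.  Scaling factors
are *stored*, not eagerly multiplied into the rate constants: the effective
rates used by the ODE right-hand side are derived in a single canonical
order by :meth:`ParameterSet.effective`.  This makes the ``apply_*``
operations exactly commutative.

Units
-----
amounts µmol; volumes L; flows and permeability-surface products L/h;
renal clearances mL/min (clinical convention); first-order rates 1/h;
Vmax µmol/h; Km µM; molar masses g/mol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from types import SimpleNamespace

REFERENCE_BODYWEIGHT = 75.0  # kg
#: allometric exponent for organ/compartment volumes
VOLUME_EXPONENT = 0.8
#: allometric exponent for flows, metabolic and excretory capacities
RATE_EXPONENT = 0.75

# sub-compartment fractions of anatomical organ volumes
LIVER_PLASMA_FRACTION = 0.15
LIVER_CELL_FRACTION = 0.70
KIDNEY_PLASMA_FRACTION = 0.20


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the ODE system at the 75-kg reference, plus the
    patient scaling factors that modulate them."""

    # -- absorption --------------------------------------------------------
    k_diss: float = 1.1          # 1/h, tablet dissolution in gut lumen
    k_abs: float = 1.1           # 1/h, absorption of dissolved GLI
    f_absorption: float = 1.0    # bioavailable fraction (fasted = 1)

    # -- hepatic metabolism ------------------------------------------------
    Vmax_gli2m1: float = 265.0   # µmol/h, CYP2C9 GLI->M1 maximal velocity
    Km_gli2m1: float = 50.0      # µM, Michaelis constant (literature-anchored)
    k_m12m2: float = 4.2         # 1/h, hepatocellular M1->M2 conversion

    # -- hepatocyte membrane exchange (bidirectional PS products) ----------
    ps_li_gli: float = 2.8       # L/h
    ps_li_m1: float = 10.0       # L/h
    ps_li_m2: float = 10.0       # L/h

    # -- excretion ---------------------------------------------------------
    CLren_m1: float = 94.0       # mL/min, renal clearance of M1
    CLren_m2: float = 250.0      # mL/min, renal clearance of M2
    k_sec_m1: float = 6.0        # 1/h, venous plasma -> gut lumen secretion
    k_sec_m2: float = 0.95       # 1/h

    # -- tissue distribution -----------------------------------------------
    ftissue_gli: float = 2.0     # L/h, plasma <-> rest-tissue exchange
    Kp_gli: float = 0.16         # rest-tissue : plasma partition coefficient

    # -- physiology (75 kg reference) --------------------------------------
    V_ve: float = 1.8            # L venous plasma
    V_ar: float = 1.2            # L arterial plasma
    V_li: float = 1.5            # L liver
    V_ki: float = 0.3            # L kidney
    V_re: float = 30.0           # L effective rest tissue
    Q_co: float = 180.0          # L/h cardiac plasma flow
    Q_li_art: float = 11.7       # L/h hepatic arterial plasma flow
    Q_gu: float = 32.4           # L/h portal (gut) plasma flow
    Q_ki: float = 34.2           # L/h renal plasma flow

    # -- molar masses (config constants) -----------------------------------
    MW_gli: float = 490.6        # g/mol
    MW_m1: float = 506.6
    MW_m2: float = 520.6

    # -- patient factors ----------------------------------------------------
    bodyweight: float = REFERENCE_BODYWEIGHT  # kg
    f_cyp2c9: float = 1.0
    f_renal_function: float = 1.0
    f_cirrhosis: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "k_diss", "k_abs", "Vmax_gli2m1", "k_m12m2",
            "ps_li_gli", "ps_li_m1", "ps_li_m2",
            "CLren_m1", "CLren_m2", "k_sec_m1", "k_sec_m2", "ftissue_gli",
            "V_ve", "V_ar", "V_li", "V_ki", "V_re",
            "Q_co", "Q_li_art", "Q_gu", "Q_ki",
            "f_cyp2c9", "f_renal_function",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 <= self.f_absorption <= 1.0:
            raise ValueError(f"f_absorption must be in [0, 1], got {self.f_absorption}")
        if not 0.0 <= self.f_cirrhosis <= 1.0:
            raise ValueError(f"f_cirrhosis must be in [0, 1], got {self.f_cirrhosis}")
        if self.Km_gli2m1 <= 0:
            raise ValueError("Km_gli2m1 must be > 0")
        if self.Kp_gli <= 0:
            raise ValueError("Kp_gli must be > 0")
        if self.Q_li_art + self.Q_gu + self.Q_ki > self.Q_co:
            raise ValueError("sum of organ plasma flows exceeds cardiac plasma flow")
        if not 20.0 <= self.bodyweight <= 250.0:
            raise ValueError(
                f"bodyweight must be within [20, 250] kg, got {self.bodyweight}"
            )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    # -- effective (scaled) model quantities --------------------------------
    def effective(self) -> SimpleNamespace:
        """Resolve scaling factors and allometry into the quantities the ODE
        right-hand side actually uses.

        Volumes scale with (BW/75)^0.8; flows and all metabolic/excretory
        capacities with (BW/75)^0.75, which keeps the terminal half-life
        nearly bodyweight-independent while reproducing the inverse
        exposure-bodyweight relation.  f_cyp2c9 and (1 - f_cirrhosis)
        multiply the CYP2C9 Vmax; (1 - f_cirrhosis) also multiplies the
        M1->M2 conversion; f_cirrhosis is in addition the portal/arterial
        shunt fraction; f_renal_function multiplies the metabolite renal
        clearances.
        """
        s_vol = (self.bodyweight / REFERENCE_BODYWEIGHT) ** VOLUME_EXPONENT
        s_cap = (self.bodyweight / REFERENCE_BODYWEIGHT) ** RATE_EXPONENT
        # 1/h constants on a compartment amount represent capacity k*V:
        # to scale the capacity with s_cap while the volume grows with s_vol
        # the rate constant itself scales with s_cap / s_vol.
        s_k = s_cap / s_vol

        e = SimpleNamespace()
        e.k_diss = self.k_diss
        e.k_abs = self.k_abs
        e.f_absorption = self.f_absorption
        e.vmax = self.Vmax_gli2m1 * self.f_cyp2c9 * (1.0 - self.f_cirrhosis) * s_cap
        e.km = self.Km_gli2m1
        e.k_m12m2 = self.k_m12m2 * (1.0 - self.f_cirrhosis) * s_k
        e.ps_li_gli = self.ps_li_gli * s_cap
        e.ps_li_m1 = self.ps_li_m1 * s_cap
        e.ps_li_m2 = self.ps_li_m2 * s_cap
        # mL/min -> L/h: * 60 / 1000
        e.clren_m1 = self.CLren_m1 * 0.06 * self.f_renal_function * s_cap
        e.clren_m2 = self.CLren_m2 * 0.06 * self.f_renal_function * s_cap
        e.k_sec_m1 = self.k_sec_m1 * s_k
        e.k_sec_m2 = self.k_sec_m2 * s_k
        e.ftissue = self.ftissue_gli * s_cap
        e.kp = self.Kp_gli
        e.shunt = self.f_cirrhosis

        e.V_ve = self.V_ve * s_vol
        e.V_ar = self.V_ar * s_vol
        e.V_li_pl = self.V_li * LIVER_PLASMA_FRACTION * s_vol
        e.V_hep = self.V_li * LIVER_CELL_FRACTION * s_vol
        e.V_ki_pl = self.V_ki * KIDNEY_PLASMA_FRACTION * s_vol
        e.V_re = self.V_re * s_vol
        e.Q_co = self.Q_co * s_cap
        e.Q_li_art = self.Q_li_art * s_cap
        e.Q_gu = self.Q_gu * s_cap
        e.Q_ki = self.Q_ki * s_cap
        e.mw = {"gli": self.MW_gli, "m1": self.MW_m1, "m2": self.MW_m2}
        return e


# ---------------------------------------------------------------------------
# packaged reference parameter set
# ---------------------------------------------------------------------------

def reference_parameters() -> ParameterSet:
    """The calibrated parameter set for a 75-kg healthy fasted adult.

    Produced by ``scripts/calibrate_reference.py`` (weighted least squares
    against a bundled table of published summary pharmacokinetics, see
    :func:`glimtwin.calibration.fit_reference`) and shipped as package data.
    """
    ref = resources.files("glimtwin").joinpath("data/reference_parameters.json")
    return ParameterSet.from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# patient-factor application (pure, commutative)
# ---------------------------------------------------------------------------

def apply_bodyweight(params: ParameterSet, bodyweight: float) -> ParameterSet:
    """Return a copy scaled to ``bodyweight`` (kg, within [20, 250])."""
    if not 20.0 <= bodyweight <= 250.0:
        raise ValueError(
            f"bodyweight must be within [20, 250] kg, got {bodyweight}"
        )
    return params.replace(bodyweight=float(bodyweight))


def apply_cirrhosis(params: ParameterSet, f_cirrhosis: float) -> ParameterSet:
    """Set the cirrhosis severity factor in [0, 1].

    (1 - f) multiplies the functional-parenchyma processes (GLI->M1 Vmax and
    M1->M2 conversion); f is additionally the fraction of liver-directed
    plasma flow shunted directly to the venous pool.
    """
    if not 0.0 <= f_cirrhosis <= 1.0:
        raise ValueError(f"f_cirrhosis must be in [0, 1], got {f_cirrhosis}")
    return params.replace(f_cirrhosis=float(f_cirrhosis))


def apply_renal(params: ParameterSet, f_renal_function: float) -> ParameterSet:
    """Set the renal function factor in (0, 1]; f = 0 is accepted (anuric)."""
    if f_renal_function < 0:
        raise ValueError(f"f_renal_function must be >= 0, got {f_renal_function}")
    if f_renal_function > 1.0:
        raise ValueError(f"f_renal_function must be <= 1, got {f_renal_function}")
    return params.replace(f_renal_function=float(f_renal_function))


def apply_cyp2c9(params: ParameterSet, f_cyp2c9: float) -> ParameterSet:
    """Set the CYP2C9 activity factor (>= 0) multiplying the GLI->M1 Vmax."""
    if f_cyp2c9 < 0:
        raise ValueError(f"f_cyp2c9 must be >= 0, got {f_cyp2c9}")
    return params.replace(f_cyp2c9=float(f_cyp2c9))


def apply_absorption(params: ParameterSet, f_absorption: float) -> ParameterSet:
    """Set the bioavailable fraction in (0, 1] (food effect)."""
    if not 0.0 < f_absorption <= 1.0:
        raise ValueError(f"f_absorption must be in (0, 1], got {f_absorption}")
    return params.replace(f_absorption=float(f_absorption))
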