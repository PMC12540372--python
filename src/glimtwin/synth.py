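"""Synthetic clinical-study generator.

Produces :class:`~glimtwin.calibration.StudyDataset` tables with known
ground truth, emulating the structure of curated clinical PK studies
(mean ± SD time courses of GLI/M1/M2 plasma concentration and cumulative
urinary metabolite amounts per dose arm).  Used for the
parameter-recovery tests and as demo input for the fitting CLI; it stands
in for real curated data, which this package does not ship.

Noise model: plasma concentrations get multiplicative lognormal noise
(mean-one, given CV); urinary amounts get proportional plus additive
noise.  Inter-individual variability perturbs selected parameters
lognormally per virtual subject.  Everything is deterministic given the
design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .calibration import StudyDataset
from .parameters import ParameterSet


@dataclass(frozen=True)
class Arm:
    """One intervention arm of a study design."""

    dose_mg: float
    route: str = "oral-tablet"
    f_cyp2c9: float = 1.0
    f_renal_function: float = 1.0
    f_cirrhosis: float = 0.0
    bodyweight: float = 75.0
    label: str = ""


@dataclass(frozen=True)
class StudyDesign:
    name: str
    arms: tuple
    sampling_times: tuple                # h, plasma sampling
    urine_times: tuple = ()              # h, cumulative urine sampling
    n_subjects: int = 12
    observables: tuple = ("gli", "m1", "m2")
    noise_cv: float = 0.0                # proportional CV on concentrations
    urine_noise_cv: float = 0.0
    urine_noise_floor: float = 0.0       # µmol additive SD
    iiv_cv: dict = field(default_factory=dict)  # param field -> lognormal CV
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for cv in (self.noise_cv, self.urine_noise_cv, *self.iiv_cv.values()):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if min(self.sampling_times, default=1.0) <= 0:
            raise ValueError("sampling times must be > 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    s2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def generate_study(design: StudyDesign, truth: ParameterSet) -> StudyDataset:
    """Simulate every virtual subject of every arm and aggregate to
    mean ± SD records in the curation schema."""
    rng = np.random.default_rng(design.seed)
    t_end = max([*design.sampling_times, *design.urine_times]) + 1.0
    rows = []
    for arm in design.arms:
        arm_params = truth.replace(
            bodyweight=arm.bodyweight, f_cyp2c9=arm.f_cyp2c9,
            f_renal_function=arm.f_renal_function,
            f_cirrhosis=arm.f_cirrhosis,
        )
        # subject-level values: (subject, observable, time)
        plasma = {s: [] for s in design.observables}
        urine: list[np.ndarray] = []
        for _ in range(design.n_subjects):
            p = arm_params
            iiv = {}
            for name, cv in design.iiv_cv.items():
                iiv[name] = getattr(arm_params, name) * _lognormal_factor(rng, cv)
            if iiv:
                p = arm_params.replace(**iiv)
            res = engine.simulate(
                p, [engine.DoseEvent(time=0.0, amount=arm.dose_mg,
                                     route=arm.route)],
                t_end=t_end, dt_out=max(t_end / 400.0, 0.05),
                rtol=1e-6, atol=1e-9,
            )
            for s in design.observables:
                c = np.interp(design.sampling_times, res.time,
                              res.plasma_conc(s, "ng/mL"))
                c = c * _lognormal_factor(rng, design.noise_cv, len(c))
                plasma[s].append(c)
            if design.urine_times:
                u = np.interp(design.urine_times, res.time,
                              res.urine_m1 + res.urine_m2)
                u = (u * _lognormal_factor(rng, design.urine_noise_cv, len(u))
                     + rng.normal(0.0, design.urine_noise_floor, len(u))
                     if (design.urine_noise_cv or design.urine_noise_floor)
                     else u)
                urine.append(np.maximum(u, 0.0))

        def emit(times, stack, substance, matrix, unit):
            arr = np.vstack(stack)
            mean = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else \
                np.zeros(arr.shape[1])
            for t, m, s in zip(times, mean, sd):
                rows.append({
                    "study": design.name, "n": design.n_subjects,
                    "dose_mg": arm.dose_mg, "route": arm.route,
                    "f_cyp2c9": arm.f_cyp2c9,
                    "f_renal_function": arm.f_renal_function,
                    "f_cirrhosis": arm.f_cirrhosis,
                    "bodyweight": arm.bodyweight,
                    "substance": substance, "matrix": matrix,
                    "time_h": t, "value": m, "sd": s, "unit": unit,
                })

        for s in design.observables:
            emit(design.sampling_times, plasma[s], s, "plasma", "ng/mL")
        if design.urine_times:
            emit(design.urine_times, urine, "m1+m2", "urine", "umol")
    return StudyDataset(pd.DataFrame(rows))


_PLASMA_TIMES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)
_URINE_TIMES = (12.0, 24.0, 48.0)


def reference_fixture_suite(truth: ParameterSet | None = None,
                            n_subjects: int = 1, noise_cv: float = 0.0,
                            seed: int = 0) -> dict[str, StudyDataset]:
    """One synthetic analogue per clinical scenario family:

    * a 5-arm single-dose escalation (1, 2, 3, 4, 6 mg),
    * a 4-level renal-function study at 3 mg,
    * a 4-level cirrhosis study at 1 mg,
    * a bodyweight contrast at 8 mg,
    * a CYP2C9 genotype study at 4 mg.

    Defaults are noise-free single-subject designs (ground truth exactly
    recoverable); pass ``n_subjects``/``noise_cv`` for noisy cohorts.
    """
    truth = truth or ParameterSet()
    kw = dict(n_subjects=n_subjects, noise_cv=noise_cv,
              sampling_times=_PLASMA_TIMES, urine_times=_URINE_TIMES)
    designs = {
        "dose_escalation": StudyDesign(
            name="dose_escalation", seed=seed,
            arms=tuple(Arm(dose_mg=d) for d in (1, 2, 3, 4, 6)), **kw),
        "renal": StudyDesign(
            name="renal", seed=seed + 1,
            arms=tuple(Arm(dose_mg=3.0, f_renal_function=f, label=lbl)
                       for lbl, f in (("normal", 1.0), ("mild", 0.69),
                                      ("moderate", 0.32), ("severe", 0.19))),
            **kw),
        "cirrhosis": StudyDesign(
            name="cirrhosis", seed=seed + 2,
            arms=tuple(Arm(dose_mg=1.0, f_cirrhosis=f, label=lbl)
                       for lbl, f in (("none", 0.0), ("CTP-A", 0.35),
                                      ("CTP-B", 0.65), ("CTP-C", 0.88))),
            **kw),
        "bodyweight": StudyDesign(
            name="bodyweight", seed=seed + 3,
            arms=(Arm(dose_mg=8.0, bodyweight=60.0, label="normal-weight"),
                  Arm(dose_mg=8.0, bodyweight=130.0, label="obese")), **kw),
        "genotype": StudyDesign(
            name="genotype", seed=seed + 4,
            arms=tuple(Arm(dose_mg=4.0, f_cyp2c9=f, label=lbl)
                       for lbl, f in (("*1/*1", 1.0), ("*1/*2", 0.84),
                                      ("*1/*3", 0.615), ("*3/*3", 0.23))),
            **kw),
    }
    return {name: generate_study(d, truth) for name, d in designs.items()}
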