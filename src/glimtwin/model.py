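"""Whole-body compartmental ODE system for glimepiride, M1 and M2.

Compartment topology (amounts in µmol):

* gut lumen: solid and dissolved glimepiride (tablet dissolution, then
  first-order absorption into the portal inflow; a ``1 - f_absorption``
  fraction of the dissolved pool is lost to feces unabsorbed),
* venous and arterial plasma, liver plasma, hepatocyte, kidney plasma and a
  lumped rest-tissue compartment for each of GLI, M1, M2,
* cumulative urinary M1/M2, cumulative fecal M1/M2 (plasma -> gut-lumen
  reverse secretion; no reabsorption) and cumulative unabsorbed GLI.

Metabolism is restricted to the hepatocyte: Michaelis-Menten CYP2C9
conversion GLI -> M1 (Vmax modulated by f_cyp2c9 and 1 - f_cirrhosis)
followed by first-order M1 -> M2.  Hepatocyte membrane passage is a
bidirectional permeability-surface flux PS * (C_plasma - C_cell); the GLI
PS is of the same magnitude as the intrinsic metabolic clearance, so
hepatic elimination is partly uptake-limited — this is what keeps the
genotype effect on exposure (AUC fold *3/*3 vs *1/*1 ~ 2) well below the
naive 1/0.23.  Unchanged glimepiride is not excreted renally; metabolites
are cleared by the kidney (f_renal_function * CLren * C_kidney-plasma) and
secreted from plasma to the gut lumen (fecal route).  In cirrhosis a
fraction f_cirrhosis of the liver-directed flow (portal + hepatic-arterial,
carrying freshly absorbed drug) bypasses the liver straight into the venous
pool.
"""

from __future__ import annotations

import numpy as np

# state indices -------------------------------------------------------------
LUMEN_SOLID = 0
LUMEN_DISS = 1
# per-substance organ blocks: ve, ar, li_pl, hep, ki_pl, re
_ORG = ("ve", "ar", "li_pl", "hep", "ki_pl", "re")
_BLOCK = {"gli": 2, "m1": 8, "m2": 14}
IDX = {
    (sub, org): _BLOCK[sub] + i for sub in _BLOCK for i, org in enumerate(_ORG)
}
URINE_M1 = 20
URINE_M2 = 21
FECES_M1 = 22
FECES_M2 = 23
FECES_GLI = 24
N_STATES = 25

SUBSTANCES = ("gli", "m1", "m2")


def derivatives(t: float, y: np.ndarray, e, infusion_gli: float = 0.0,
                infusion_m1: float = 0.0) -> np.ndarray:
    """Time derivative of the state vector.

    Parameters
    ----------
    y : state amounts, µmol (see module docstring for layout).
    e : effective parameter namespace from ``ParameterSet.effective()``.
    infusion_gli, infusion_m1 : zero-order IV input rates, µmol/h.
    """
    dy = np.zeros(N_STATES)

    # gut lumen -------------------------------------------------------------
    a_solid = max(y[LUMEN_SOLID], 0.0)
    a_diss = max(y[LUMEN_DISS], 0.0)
    dy[LUMEN_SOLID] = -e.k_diss * a_solid
    diss_in = e.k_diss * a_solid
    abs_flux = e.k_abs * e.f_absorption * a_diss
    lost_flux = e.k_abs * (1.0 - e.f_absorption) * a_diss
    dy[LUMEN_DISS] = diss_in - abs_flux - lost_flux
    dy[FECES_GLI] = lost_flux

    q_li_in = e.Q_li_art + e.Q_gu          # total liver-directed plasma flow
    q_other = e.Q_co - q_li_in - e.Q_ki    # arterio-venous bypass (rest organs)
    g = 1.0 - e.shunt

    for sub in SUBSTANCES:
        ve = y[IDX[sub, "ve"]]
        ar = y[IDX[sub, "ar"]]
        lp = y[IDX[sub, "li_pl"]]
        hp = y[IDX[sub, "hep"]]
        kp = y[IDX[sub, "ki_pl"]]
        re = y[IDX[sub, "re"]]

        c_ve = ve / e.V_ve
        c_ar = ar / e.V_ar
        c_lp = lp / e.V_li_pl
        c_hp = hp / e.V_hep
        c_kp = kp / e.V_ki_pl
        c_re = re / e.V_re

        # absorbed GLI enters the portal inflow
        inflow_extra = abs_flux if sub == "gli" else 0.0
        li_in = q_li_in * c_ar + inflow_extra

        # hepatocyte membrane exchange (PS flux, plasma -> cell positive)
        ps = {"gli": e.ps_li_gli, "m1": e.ps_li_m1, "m2": e.ps_li_m2}[sub]
        j_mem = ps * (c_lp - c_hp)

        # rest-tissue exchange (venous <-> tissue)
        j_tis = e.ftissue * (c_ve - c_re / e.kp)

        d_ve = (g * q_li_in * c_lp + e.shunt * li_in + e.Q_ki * c_kp
                + q_other * c_ar - e.Q_co * c_ve - j_tis)
        d_ar = e.Q_co * c_ve - (q_li_in + e.Q_ki + q_other) * c_ar
        d_lp = g * li_in - g * q_li_in * c_lp - j_mem
        d_hp = j_mem
        d_kp = e.Q_ki * (c_ar - c_kp)
        d_re = j_tis

        if sub == "m1":
            ren = e.clren_m1 * c_kp
            sec = e.k_sec_m1 * max(ve, 0.0)
            d_kp -= ren
            d_ve -= sec
            dy[URINE_M1] += ren
            dy[FECES_M1] += sec
        elif sub == "m2":
            ren = e.clren_m2 * c_kp
            sec = e.k_sec_m2 * max(ve, 0.0)
            d_kp -= ren
            d_ve -= sec
            dy[URINE_M2] += ren
            dy[FECES_M2] += sec

        dy[IDX[sub, "ve"]] = d_ve
        dy[IDX[sub, "ar"]] = d_ar
        dy[IDX[sub, "li_pl"]] = d_lp
        dy[IDX[sub, "hep"]] = d_hp
        dy[IDX[sub, "ki_pl"]] = d_kp
        dy[IDX[sub, "re"]] = d_re

    # hepatic metabolism ------------------------------------------------------
    c_hep_gli = max(y[IDX["gli", "hep"]], 0.0) / e.V_hep
    v1 = e.vmax * c_hep_gli / (e.km + c_hep_gli)
    v2 = e.k_m12m2 * max(y[IDX["m1", "hep"]], 0.0)
    dy[IDX["gli", "hep"]] -= v1
    dy[IDX["m1", "hep"]] += v1 - v2
    dy[IDX["m2", "hep"]] += v2

    # IV inputs ---------------------------------------------------------------
    dy[IDX["gli", "ve"]] += infusion_gli
    dy[IDX["m1", "ve"]] += infusion_m1

    if not np.all(np.isfinite(dy)):
        raise FloatingPointError(
            f"non-finite derivative at t={t}: state={y!r}"
        )
    return dy


def total_moles(y: np.ndarray) -> float:
    """Total GLI + M1 + M2 moles over all compartments incl. urine/feces."""
    return float(np.sum(y[:N_STATES]))


def mass_balance_error(y: np.ndarray, administered_umol: float) -> float:
    """Relative mass-balance defect |total - administered| / administered."""
    if administered_umol == 0:
        return abs(total_moles(y))
    return abs(total_moles(y) - administered_umol) / administered_umol
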