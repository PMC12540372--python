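"""Non-compartmental analysis of concentration-time profiles.

All routines are model-free: they accept plain ``(time, concentration)``
arrays (simulated or observed).  Terminal elimination is estimated by
log-linear regression over the last k post-Tmax samples, with k chosen to
maximize the adjusted R²; AUC uses the linear trapezoid with optional
C_last / lambda_z extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LN2 = float(np.log(2.0))
MIN_TERMINAL_POINTS = 3
MIN_ADJ_R2 = 0.8


@dataclass
class LambdaZResult:
    lambda_z: float        # 1/h (NaN if no decaying terminal phase)
    n_points: int
    adj_r2: float
    ok: bool


@dataclass
class PKParameters:
    """Standard NCA summary for one substance."""

    cmax: float                 # ng/mL
    tmax: float                 # h
    auc_0_t: float              # ng*h/mL
    auc_0_inf: float            # ng*h/mL (NaN if lambda_z not estimable)
    lambda_z: float             # 1/h
    t_half: float               # h
    cl_over_f: float            # mL/min
    extrapolated_fraction: float
    ok: bool = True

    def to_dict(self) -> dict:
        return {
            "cmax_ng_ml": self.cmax,
            "tmax_h": self.tmax,
            "auc_0_t_ng_h_ml": self.auc_0_t,
            "auc_0_inf_ng_h_ml": self.auc_0_inf,
            "lambda_z_per_h": self.lambda_z,
            "t_half_h": self.t_half,
            "cl_over_f_ml_min": self.cl_over_f,
            "extrapolated_fraction": self.extrapolated_fraction,
        }


def _check_profile(t, c):
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("time and concentration must be 1-D arrays of equal length")
    if t.size < 2:
        raise ValueError("profile needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t, c


def lambda_z(t, c) -> LambdaZResult:
    """Terminal slope by adjusted-R²-selected log-linear regression.

    Candidate windows are the last k points after Tmax (k = 3 .. all);
    windows including non-positive concentrations are skipped.  If no
    window reaches adjusted R² of 0.8 with a positive slope estimate the
    result is flagged and lambda_z is NaN.
    """
    t, c = _check_profile(t, c)
    i_max = int(np.argmax(c))
    t_post = t[i_max + 1:]
    c_post = c[i_max + 1:]
    pos = c_post > 0
    t_post, c_post = t_post[pos], c_post[pos]
    n = t_post.size
    if n < MIN_TERMINAL_POINTS:
        return LambdaZResult(np.nan, 0, np.nan, False)

    logc = np.log(c_post)
    # suffix regressions via reversed cumulative sums, O(n)
    tr, yr = t_post[::-1], logc[::-1]
    cs_t, cs_y = np.cumsum(tr), np.cumsum(yr)
    cs_tt, cs_ty, cs_yy = np.cumsum(tr * tr), np.cumsum(tr * yr), np.cumsum(yr * yr)

    best = LambdaZResult(np.nan, 0, -np.inf, False)
    for k in range(MIN_TERMINAL_POINTS, n + 1):
        sx, sy = cs_t[k - 1], cs_y[k - 1]
        sxx, sxy, syy = cs_tt[k - 1], cs_ty[k - 1], cs_yy[k - 1]
        vx = sxx - sx * sx / k
        vy = syy - sy * sy / k
        cxy = sxy - sx * sy / k
        if vx <= 0:
            continue
        slope = cxy / vx
        if slope >= 0:
            continue
        r2 = 1.0 if vy == 0 else cxy * cxy / (vx * vy)
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if adj > best.adj_r2:
            best = LambdaZResult(-slope, k, adj, adj >= MIN_ADJ_R2)
    if not best.ok:
        return LambdaZResult(np.nan, best.n_points, best.adj_r2, False)
    return best


def auc(t, c, extrapolate: bool = False) -> float:
    """Linear-trapezoid AUC over the observed span; optionally add the
    C_last / lambda_z tail."""
    t, c = _check_profile(t, c)
    area = float(np.trapezoid(c, t))
    if extrapolate:
        lz = lambda_z(t, c)
        if not lz.ok:
            raise ValueError(
                "cannot extrapolate AUC: no decaying terminal phase "
                f"(best adjusted R² = {lz.adj_r2:.3g})"
            )
        area += float(c[-1]) / lz.lambda_z
    return area


def pk_summary(t, c, dose_mg: float | None = None) -> PKParameters:
    """Cmax/Tmax (first grid maximum), AUCs, terminal slope and CL/F.

    ``c`` in ng/mL, ``t`` in h, ``dose_mg`` the administered dose of the
    profiled substance; CL/F is reported in mL/min.
    """
    t, c = _check_profile(t, c)
    if np.all(c == 0):
        return PKParameters(0.0, np.nan, 0.0, np.nan, np.nan, np.nan,
                            np.nan, np.nan, ok=False)
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_t = float(np.trapezoid(c, t))
    lz = lambda_z(t, c)
    if lz.ok:
        auc_inf = auc_t + float(c[-1]) / lz.lambda_z
        t_half = LN2 / lz.lambda_z
        extrap = 1.0 - auc_t / auc_inf
    else:
        auc_inf = t_half = extrap = np.nan
    if dose_mg is not None and lz.ok and auc_inf > 0:
        # dose mg -> ng; AUC ng*h/mL -> CL mL/h -> mL/min
        cl_over_f = dose_mg * 1e6 / auc_inf / 60.0
    else:
        cl_over_f = np.nan
    return PKParameters(cmax, tmax, auc_t, auc_inf, lz.lambda_z, t_half,
                        cl_over_f, extrap, ok=True)


def metabolite_clearance(result, substance: str = "m1") -> float:
    """Apparent plasma clearance of a metabolite, mL/min.

    Defined as cumulative urinary metabolite recovery (M1 + M2, since M2
    derives entirely from M1) divided by the metabolite's plasma AUC over
    the simulated span:

        CL_app = (A_urine,M1 + A_urine,M2) / AUC_metabolite

    with amounts in µmol and the AUC in µM·h, i.e. a volume-per-time that
    reduces to f_renal·CLren only when the urinary route dominates.  This
    is the quantity reported against creatinine-clearance in the renal
    impairment analyses.  Use a span long enough (>= 72 h) for near-complete
    excretion.
    """
    t = result.time
    c_um = result.plasma_conc(substance, unit="uM")
    auc_um_h = float(np.trapezoid(c_um, t))  # µM * h = µmol/L * h
    if auc_um_h <= 0:
        return np.nan
    urinary = float(result.urine_m1[-1] + result.urine_m2[-1])  # µmol
    cl_l_per_h = urinary / auc_um_h
    return cl_l_per_h * 1000.0 / 60.0  # L/h -> mL/min


def pk_from_result(result, substance: str, dose_mg: float | None = None
                   ) -> PKParameters:
    """NCA of a simulated plasma profile."""
    return pk_summary(result.time, result.plasma_conc(substance, "ng/mL"),
                      dose_mg=dose_mg)
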