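import numpy as np
import pytest

from glimtwin import engine, nca
from glimtwin.parameters import ParameterSet, reference_parameters


@pytest.fixture(scope="session")
def ref() -> ParameterSet:
    """The shipped calibrated reference parameter set."""
    return reference_parameters()


@pytest.fixture(scope="session")
def base() -> ParameterSet:
    """Constructor-default parameters (pre-calibration magnitudes)."""
    return ParameterSet()


@pytest.fixture(scope="session")
def dose_sims(ref):
    """Single-dose reference simulations for 1, 2, 4, 8 mg (48-h span),
    shared across NCA/acceptance tests."""
    return {d: engine.single_oral_dose(ref, float(d)) for d in (1, 2, 4, 8)}


@pytest.fixture(scope="session")
def dose_pk(dose_sims):
    return {d: nca.pk_from_result(r, "gli", dose_mg=float(d))
            for d, r in dose_sims.items()}


def one_compartment_iv_params() -> ParameterSet:
    """Degenerate configuration: very fast plasma mixing, no tissue
    distribution, no metabolism or secretion — M1 renal excretion is the
    only elimination, so an IV M1 bolus decays mono-exponentially with
    k = CLren_eff / V_plasma,total."""
    return ParameterSet(
        Q_co=300000.0, Q_li_art=10000.0, Q_gu=20000.0, Q_ki=200000.0,
        Vmax_gli2m1=0.0, k_m12m2=0.0,
        ps_li_gli=0.0, ps_li_m1=0.0, ps_li_m2=0.0,
        ftissue_gli=0.0, k_sec_m1=0.0, k_sec_m2=0.0,
        CLren_m2=0.0,
    )


def total_plasma_volume(params: ParameterSet) -> float:
    e = params.effective()
    return e.V_ve + e.V_ar + e.V_li_pl + e.V_ki_pl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
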