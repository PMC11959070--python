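"""Unit conversions at the solver boundary.

The public API speaks clinical units (mmHg, mL/s, cm, 10^-3/mmHg); the
solver works in SI (Pa, m^3/s, m, Pa^-1).
"""

MMHG_TO_PA: float = 133.322
PA_TO_MMHG: float = 1.0 / MMHG_TO_PA

ML_TO_M3: float = 1e-6
M3_TO_ML: float = 1e6

CM_TO_M: float = 1e-2


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p * PA_TO_MMHG


def distensibility_to_si(c_per_mmhg_e3: float) -> float:
    """Convert distensibility from 10^-3/mmHg to 1/Pa."""
    return c_per_mmhg_e3 * 1e-3 / MMHG_TO_PA


def resistance_to_si(r_mmhg_s_ml: float) -> float:
    """Convert resistance from mmHg*s/mL to Pa*s/m^3."""
    return r_mmhg_s_ml * MMHG_TO_PA / ML_TO_M3


def compliance_to_si(c_ml_mmhg: float) -> float:
    """Convert compliance from mL/mmHg to m^3/Pa."""
    return c_ml_mmhg * ML_TO_M3 / MMHG_TO_PA
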