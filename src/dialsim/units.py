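"""Unit conventions and the single conversion point for K_uf.

Internal working units throughout the package:

========================  =============
quantity                  unit
========================  =============
flow rates (Qb, Qd, Qf)   mL/min
pressures                 mmHg
volumes (body)            L
solute masses             mg
solute concentrations     mg/L
clearances                mL/min
time                      min
========================  =============

The ultrafiltration coefficient K_uf is configured in the conventional
clinical unit mL/(h*mmHg) and converted exactly once, here, to
mL/(min*mmHg).
"""

MIN_PER_H = 60.0
WEEK_MIN = 10_080.0

#: molar masses used for osmotic bookkeeping, mg/mmol
MW_UREA = 60.06
MW_B2M = 11_800.0

#: reference body-water volume for EKRc normalisation, L
V_REF_L = 40.0


def kuf_to_ml_min_mmhg(kuf_ml_h_mmhg: float) -> float:
    """Convert a UF coefficient from mL/(h*mmHg) to mL/(min*mmHg)."""
    return kuf_ml_h_mmhg / MIN_PER_H


def mg_dl_to_mg_l(c: float) -> float:
    """Convert a concentration from mg/dL to mg/L."""
    return c * 10.0
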