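"""Unit conversions shared across the perfusion and flow modules."""

from __future__ import annotations


def perfusion_unit_scale(lambda_ml_g: float = 0.95, t1_blood_ms: float = 1900.0) -> float:
    """Scale converting the dimensionless T1 ratio term to ml/min/100 g.

    The FAIR perfusion model reads P = (lambda / T1_blood) * (T1_global / T1_ss - 1).
    With lambda in ml/g and T1_blood in ms the prefactor has units ml/(g*ms);
    multiplying by 60 000 ms/min and 100 g yields ml/min/100 g.  At the defaults
    (lambda = 0.95 ml/g, T1_blood = 1900 ms) the scale is exactly 3000.
    """
    if lambda_ml_g <= 0 or t1_blood_ms <= 0:
        raise ValueError("lambda and T1_blood must be strictly positive")
    return lambda_ml_g / t1_blood_ms * 60_000.0 * 100.0


#: ml/min per (mm^2 * cm/s): 1 cm/s = 10 mm/s, 1 mm^3/s = 0.06 ml/min.
FLOW_ML_MIN_PER_MM2_CM_S = 0.6
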