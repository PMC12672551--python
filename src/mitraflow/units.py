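"""Unit conventions and conversion constants.

All geometry is expressed in millimetres, volumes in millilitres, flow rates
in ml/s, velocities in m/s and pressures in mmHg at the public interfaces.
The flow solver works internally in SI (m, m/s, Pa, kg·m⁻³).
"""

#: Pascals per millimetre of mercury.
MMHG_TO_PA = 133.322

MM_TO_M = 1e-3
ML_TO_M3 = 1e-6
M3_TO_ML = 1e6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA
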