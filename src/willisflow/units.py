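"""Unit conversion constants.

SI units are used everywhere inside the package (Pa, m, s, m^3/s).
Clinical units (mmHg, mm, cm/s, ml) appear only at the I/O boundary and are
converted exactly once on the way in or out.
"""

MMHG_TO_PA = 133.322387415
PA_TO_MMHG = 1.0 / MMHG_TO_PA

MM_TO_M = 1e-3
M_TO_MM = 1e3

CM_S_TO_M_S = 1e-2
M_S_TO_CM_S = 1e2

ML_TO_M3 = 1e-6
M3_TO_ML = 1e6


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p * PA_TO_MMHG
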