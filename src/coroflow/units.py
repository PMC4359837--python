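"""Unit conventions and conversions.

Geometry is expressed in millimetres, the flow solver works in SI
(metres, Pa) and the wall solver in the mm-MPa-N system; pressures are
reported in mmHg. Conversions are explicit at module boundaries.
"""

MMHG_PA = 133.322  # 1 mmHg in Pa
MM_M = 1.0e-3      # 1 mm in m
PA_MPA = 1.0e-6    # 1 Pa in MPa


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_PA
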