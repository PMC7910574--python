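"""Unit conversion constants.

Public interfaces use mmHg / mm / cm·s⁻¹ / mL·s⁻¹ / s; the solver works in SI.
"""

MMHG_TO_PA: float = 133.322
"""Pascals per millimetre of mercury."""


def mmhg_to_pa(p_mmhg):
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    return p_pa / MMHG_TO_PA
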