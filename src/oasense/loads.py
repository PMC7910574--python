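"""Pressure loading: external compartment pressures and the cardiac inlet wave.

The intracranial OA segment is compressed by ICP, the extracranial segment by
the intraorbital pressure Pio plus any externally applied pressure Pe (the
snapshot method's actuation variable; Pe = 0 in monitoring mode). The optic
canal is rigid, so its external pressure is irrelevant and reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CANAL, EOA, IOA, VesselGeometry

__all__ = ["PressureLoad", "inlet_pressure_waveform", "external_pressure_at"]


@dataclass(frozen=True)
class PressureLoad:
    """Pressures acting on the vessel and the inlet forcing.

    Attributes
    ----------
    icp_mmhg : float
        Intracranial pressure compressing the IOA region.
    pio_mmhg : float
        Intraorbital tissue pressure on the EOA region (4 mmHg nominal).
    pe_mmhg : float
        Externally applied orbital pressure on the EOA region; 0 when not
        applied (monitoring mode).
    inlet_mean_mmhg, inlet_amplitude_mmhg : float
        Cycle mean and pulse amplitude of the inlet pressure waveform.
    period_s : float
        Cardiac period.
    waveform : str
        Waveform shape id; ``"rectified-sine"`` is the default shape.
    outlet_resistance_mmhg_s_ml : float
        Terminal (distal bed) resistance closing the outlet. The default is
        tuned once so the cycle-mean probe velocity is ≈17 cm/s in the
        canonical geometry.
    """

    icp_mmhg: float = 10.0
    pio_mmhg: float = 4.0
    pe_mmhg: float = 0.0
    inlet_mean_mmhg: float = 60.0
    inlet_amplitude_mmhg: float = 20.0
    period_s: float = 1.0
    waveform: str = "rectified-sine"
    outlet_resistance_mmhg_s_ml: float = 223.0

    def __post_init__(self) -> None:
        if self.icp_mmhg < 0 or self.pio_mmhg < 0 or self.pe_mmhg < 0:
            raise ValueError("icp, pio and pe must be non-negative")
        if self.period_s <= 0:
            raise ValueError("cardiac period must be positive")
        if self.inlet_amplitude_mmhg < 0:
            raise ValueError("pulse amplitude must be non-negative")
        if self.inlet_mean_mmhg <= self.inlet_amplitude_mmhg:
            raise ValueError("mean inlet pressure must exceed the pulse amplitude")
        if self.outlet_resistance_mmhg_s_ml <= 0:
            raise ValueError("outlet resistance must be positive")

    def with_(self, **kwargs) -> "PressureLoad":
        return replace(self, **kwargs)


_TWO_OVER_PI = 2.0 / np.pi


def inlet_pressure_waveform(t_s, load: PressureLoad):
    """Inlet pressure (mmHg) at time(s) ``t_s``.

    Periodic with the cardiac period; the cycle mean equals
    ``inlet_mean_mmhg`` and the minimum is ≥ mean − amplitude. The default
    shape is a mean-removed rectified sinusoid::

        p(t) = mean + amplitude · (|sin(π t / T)| − 2/π)

    whose systolic upstroke/diastolic decay crudely mimics an arterial pulse.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if load.waveform == "rectified-sine":
        shape = np.abs(np.sin(np.pi * t / load.period_s)) - _TWO_OVER_PI
    elif load.waveform == "constant":
        shape = np.zeros_like(t)
    else:
        raise ValueError(f"unknown waveform shape {load.waveform!r}")
    p = load.inlet_mean_mmhg + load.inlet_amplitude_mmhg * shape
    return p if p.shape else float(p)


def external_pressure_at(x_mm, geometry: VesselGeometry, load: PressureLoad):
    """External compartment pressure (mmHg) at axial position(s) ``x_mm``.

    ICP in the IOA region, Pio + Pe in the EOA region, and 0 by convention in
    the rigid canal (where the wall does not move, so the value is inert).
    """
    region = geometry.region_index(x_mm)
    per_region = np.array(
        [load.icp_mmhg, 0.0, load.pio_mmhg + load.pe_mmhg], dtype=float
    )
    out = per_region[region]
    return out if np.ndim(region) else float(out)
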