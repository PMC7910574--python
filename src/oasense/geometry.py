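"""Segmented ophthalmic-artery geometry.

The vessel is an idealized straight tube split inlet→outlet into three
contiguous regions: the intracranial segment (IOA), the bony optic canal
(rigid), and the extracranial segment (EOA). Doppler "probes" sit at one
axial station inside each compliant segment; probe readings are averaged over
a small vicinity around the station.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["VesselGeometry", "build_default_geometry"]

# Region indices used throughout the solver.
IOA, CANAL, EOA = 0, 1, 2
_REGION_NAMES = ("ioa", "canal", "eoa")


@dataclass(frozen=True)
class VesselGeometry:
    """Three-region ophthalmic-artery geometry (all lengths in mm).

    Parameters
    ----------
    total_length_mm : float
        Inlet-to-outlet length of the idealized straight vessel.
    ioa_end_mm, canal_end_mm : float
        Region boundaries: IOA occupies ``[0, ioa_end)``, the optic canal
        ``[ioa_end, canal_end)`` and the EOA ``[canal_end, total_length]``.
    radius_mm : tuple[float, float, float]
        Reference lumen radius per region (IOA, canal, EOA).
    compliance_per_mmhg : tuple[float, float, float]
        Fractional cross-sectional area change per mmHg of transmural
        pressure for each region. The optic canal is bony and must be rigid
        (compliance exactly 0).
    probe_ioa_mm, probe_eoa_mm : float
        Axial measurement stations, one strictly inside each compliant
        segment.
    probe_halfwidth_mm : float
        Half-width of the vicinity over which probe readings are averaged.
    reference_transmural_mmhg : float
        Transmural pressure at which a compliant region attains its
        reference area (operating-point reference of the tube law).
    """

    total_length_mm: float
    ioa_end_mm: float
    canal_end_mm: float
    radius_mm: tuple[float, float, float]
    compliance_per_mmhg: tuple[float, float, float]
    probe_ioa_mm: float
    probe_eoa_mm: float
    probe_halfwidth_mm: float = 1.0
    reference_transmural_mmhg: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ioa_end_mm < self.canal_end_mm < self.total_length_mm):
            raise ValueError(
                "regions must partition [0, total_length] in order IOA, canal, EOA"
            )
        if len(self.radius_mm) != 3 or len(self.compliance_per_mmhg) != 3:
            raise ValueError("radius_mm and compliance_per_mmhg need one value per region")
        if any(r <= 0 for r in self.radius_mm):
            raise ValueError("all radii must be positive")
        if any(c < 0 for c in self.compliance_per_mmhg):
            raise ValueError("compliances must be non-negative")
        if self.compliance_per_mmhg[CANAL] != 0.0:
            raise ValueError("the optic canal is bony: its compliance must be 0")
        if self.probe_halfwidth_mm <= 0:
            raise ValueError("probe_halfwidth_mm must be positive")
        if not (0.0 < self.probe_ioa_mm < self.ioa_end_mm):
            raise ValueError("IOA probe must lie strictly inside the IOA region")
        if not (self.canal_end_mm < self.probe_eoa_mm < self.total_length_mm):
            raise ValueError("EOA probe must lie strictly inside the EOA region")

    # -- queries ----------------------------------------------------------

    def region_index(self, x_mm):
        """Region index (0=IOA, 1=canal, 2=EOA) for axial position(s) x."""
        x = np.asarray(x_mm, dtype=float)
        if np.any(x < 0) or np.any(x > self.total_length_mm):
            raise ValueError("axial position outside the vessel")
        idx = np.full(x.shape, EOA, dtype=int)
        idx[x < self.canal_end_mm] = CANAL
        idx[x < self.ioa_end_mm] = IOA
        return idx if x.shape else int(idx)

    def region_bounds_mm(self, region: int) -> tuple[float, float]:
        edges = (0.0, self.ioa_end_mm, self.canal_end_mm, self.total_length_mm)
        return edges[region], edges[region + 1]

    def probe_location_mm(self, location_id: str) -> float:
        loc = location_id.lower()
        if loc == "ioa":
            return self.probe_ioa_mm
        if loc == "eoa":
            return self.probe_eoa_mm
        raise ValueError(f"unknown probe location {location_id!r} (use 'ioa' or 'eoa')")

    @property
    def interprobe_length_mm(self) -> float:
        """Axial distance between the two measurement stations."""
        return self.probe_eoa_mm - self.probe_ioa_mm

    def reference_area_mm2(self, region: int) -> float:
        return float(np.pi * self.radius_mm[region] ** 2)

    def with_(self, **kwargs) -> "VesselGeometry":
        """Return a modified copy (convenience wrapper over dataclasses.replace)."""
        return replace(self, **kwargs)


def build_default_geometry() -> VesselGeometry:
    """Canonical geometry of the idealized straight ophthalmic artery.

    Lumen radius 0.7 mm throughout; IOA 0–10 mm, optic canal 10–14 mm
    (rigid), EOA 14–30 mm; probes at 5 mm and 22 mm (17 mm apart). With the
    default blood viscosity and a cycle-mean probe velocity of ~17 cm/s this
    yields an analytic inter-probe Hagen–Poiseuille drop of ~1.2 mmHg.
    """
    return VesselGeometry(
        total_length_mm=30.0,
        ioa_end_mm=10.0,
        canal_end_mm=14.0,
        radius_mm=(0.7, 0.7, 0.7),
        compliance_per_mmhg=(0.003, 0.0, 0.003),
        probe_ioa_mm=5.0,
        probe_eoa_mm=22.0,
        probe_halfwidth_mm=1.0,
    )
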