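"""Snapshot-mode non-invasive ICP measurement.

The snapshot method sweeps the externally applied orbital pressure Pe and
locates the *balance point* — the Pe at which the cycle-averaged blood flow
velocities at the intracranial (IOA) and extracranial (EOA) probes are equal.
At balance the external compressions of the two segments are equivalent, so

    ICP ≈ Pe* + Pio + ΔP_gradient + residual,

where Pio is the intraorbital pressure, ΔP_gradient the arterial pressure
drop between the probes (Hagen–Poiseuille), and the residual the
patient-specific component that is not known a priori. The first two terms
are systematic, known, and can be subtracted in software; the residual bounds
the attainable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BalanceNotBracketedError
from .geometry import VesselGeometry
from .loads import PressureLoad
from .model import SimConfig, poiseuille_pressure_drop, probe, simulate

__all__ = [
    "SweepResult",
    "ErrorDecomposition",
    "sweep_pe",
    "find_balance_pe",
    "balance_mean_flow",
    "decompose_error",
    "snapshot_estimate_icp",
]


@dataclass
class SweepResult:
    """Velocity-difference curve Δv(Pe) from a Pe sweep at fixed ICP and Pio.

    ``delta_v_cm_s[i]`` is the cycle-averaged IOA probe velocity minus the
    cycle-averaged EOA probe velocity at ``pe_mmhg[i]``. Per-run cycle-mean
    inlet flow and inter-probe pressure difference are kept for the
    systematic-error decomposition. ``poly_coeffs`` is filled by
    :func:`find_balance_pe`.
    """

    icp_mmhg: float
    pio_mmhg: float
    pe_mmhg: np.ndarray
    delta_v_cm_s: np.ndarray
    mean_flow_ml_s: np.ndarray
    pressure_drop_mmhg: np.ndarray
    failed_pe_mmhg: list = field(default_factory=list)
    poly_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pe_mmhg = np.asarray(self.pe_mmhg, dtype=float)
        self.delta_v_cm_s = np.asarray(self.delta_v_cm_s, dtype=float)
        if np.any(np.diff(self.pe_mmhg) <= 0):
            raise ValueError("pe grid must be strictly increasing")
        if not np.all(np.isfinite(self.delta_v_cm_s)):
            raise ValueError("delta-v values must be finite")


@dataclass(frozen=True)
class ErrorDecomposition:
    """Decomposition of the snapshot systematic error (all mmHg).

    total_offset = ICP − balance_Pe splits exactly into the intraorbital
    component (Pio), the inter-probe Poiseuille gradient, and a residual that
    closes the sum bit-exactly.
    """

    balance_pe_mmhg: float
    total_offset_mmhg: float
    pio_component_mmhg: float
    gradient_component_mmhg: float
    residual_mmhg: float


def sweep_pe(
    icp_mmhg: float,
    pio_mmhg: float,
    pe_grid,
    geometry: VesselGeometry,
    config: SimConfig,
    base_load: PressureLoad | None = None,
    skip_failed: bool = False,
) -> SweepResult:
    """Simulate one run per Pe on the grid and collect the Δv curve.

    All runs share the geometry, numerics and inlet/outlet parameters of
    ``base_load`` (defaults if omitted); only Pe varies. A diverged run
    raises unless ``skip_failed`` is set, in which case its Pe is recorded in
    ``failed_pe_mmhg`` and excluded.
    """
    pe_grid = np.asarray(pe_grid, dtype=float)
    if pe_grid.size == 0 or np.any(np.diff(pe_grid) <= 0):
        raise ValueError("pe_grid must be non-empty and strictly increasing")
    if base_load is None:
        base_load = PressureLoad()

    pe_ok, dv, flow, drop, failed = [], [], [], [], []
    for pe in pe_grid:
        load = base_load.with_(icp_mmhg=icp_mmhg, pio_mmhg=pio_mmhg, pe_mmhg=float(pe))
        try:
            hemo = simulate(geometry, load, config)
        except Exception:
            if not skip_failed:
                raise
            failed.append(float(pe))
            continue
        p_ioa = probe(hemo, geometry, "ioa")
        p_eoa = probe(hemo, geometry, "eoa")
        pe_ok.append(float(pe))
        dv.append(p_ioa.velocity_mean_cm_s - p_eoa.velocity_mean_cm_s)
        flow.append(float(hemo.q_in_ml_s[hemo.cycle_slice(-1)].mean()))
        drop.append(p_ioa.pressure_mean_mmhg - p_eoa.pressure_mean_mmhg)

    return SweepResult(
        icp_mmhg=icp_mmhg,
        pio_mmhg=pio_mmhg,
        pe_mmhg=np.array(pe_ok),
        delta_v_cm_s=np.array(dv),
        mean_flow_ml_s=np.array(flow),
        pressure_drop_mmhg=np.array(drop),
        failed_pe_mmhg=failed,
    )


def find_balance_pe(sweep: SweepResult, poly_order: int = 2) -> float:
    """Balance Pe: the zero crossing of a polynomial fitted to Δv(Pe).

    A quadratic is fitted by default (linear when fewer than 4 points). When
    the fitted polynomial has several real roots inside the grid span, the
    one nearest the raw data's sign change is returned, which is robust to
    fit wiggles. The fit coefficients are cached on ``sweep.poly_coeffs``.

    Raises
    ------
    BalanceNotBracketedError
        If Δv does not change sign on the grid (balance outside sweep range).
    """
    pe, dv = sweep.pe_mmhg, sweep.delta_v_cm_s
    sign_change = np.nonzero(np.diff(np.sign(dv)) != 0)[0]
    if sign_change.size == 0:
        raise BalanceNotBracketedError(
            f"delta-v does not change sign on Pe ∈ [{pe[0]}, {pe[-1]}] mmHg "
            f"(ICP = {sweep.icp_mmhg} mmHg): balance outside sweep range"
        )
    i = int(sign_change[0])
    # linear interpolation of the raw bracketing pair, used as root selector
    raw_root = pe[i] - dv[i] * (pe[i + 1] - pe[i]) / (dv[i + 1] - dv[i])

    order = poly_order if len(pe) >= 4 else 1
    coeffs = np.polyfit(pe, dv, order)
    sweep.poly_coeffs = coeffs
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real
    in_span = real[(real >= pe[0] - 1e-9) & (real <= pe[-1] + 1e-9)]
    if in_span.size == 0:
        # fit wiggled its roots out of the span; fall back to the raw bracket
        return float(raw_root)
    return float(in_span[np.argmin(np.abs(in_span - raw_root))])


def balance_mean_flow(sweep: SweepResult, balance_pe_mmhg: float) -> float:
    """Cycle-mean inlet flow (mL/s) at the balance point, interpolated on Pe."""
    return float(np.interp(balance_pe_mmhg, sweep.pe_mmhg, sweep.mean_flow_ml_s))


def decompose_error(
    icp_mmhg: float,
    balance_pe_mmhg: float,
    pio_mmhg: float,
    geometry: VesselGeometry,
    mean_flow_ml_s: float,
    viscosity_pa_s: float = 3.5e-3,
) -> ErrorDecomposition:
    """Split the balance offset ICP − Pe* into its systematic components.

    The intraorbital component is Pio itself; the gradient component is the
    analytic Hagen–Poiseuille inter-probe drop at the supplied mean flow
    (conventionally the balance run's cycle-mean inlet flow); the residual
    closes the sum exactly and represents the patient-specific part.
    """
    total = icp_mmhg - balance_pe_mmhg
    gradient = poiseuille_pressure_drop(geometry, mean_flow_ml_s, viscosity_pa_s)
    return ErrorDecomposition(
        balance_pe_mmhg=balance_pe_mmhg,
        total_offset_mmhg=total,
        pio_component_mmhg=pio_mmhg,
        gradient_component_mmhg=gradient,
        residual_mmhg=total - pio_mmhg - gradient,
    )


def snapshot_estimate_icp(
    balance_pe_mmhg: float, pio_mmhg: float, gradient_mmhg: float
) -> float:
    """Corrected snapshot ICP estimate: Pe* + Pio + gradient (mmHg).

    The a-priori-known systematic components are added back, leaving only the
    patient-specific residual as estimation error.
    """
    for v in (balance_pe_mmhg, pio_mmhg, gradient_mmhg):
        if not np.isfinite(v):
            raise ValueError("inputs must be finite")
    return float(balance_pe_mmhg + pio_mmhg + gradient_mmhg)
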