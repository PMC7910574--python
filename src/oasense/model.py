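"""Reduced-order (1-D) pulsatile flow model of the compliant ophthalmic artery.

The model replaces a full 3-D fluid–structure interaction solve with
cross-sectionally averaged mass and momentum balances coupled to an algebraic
tube law:

    C(p) ∂p/∂t + ∂Q/∂x = 0                       (mass, C = dA/dp)
    ∂Q/∂t = −(A/ρ) ∂p/∂x − 8πμ Q / (ρ A)         (momentum, Poiseuille friction)
    A(x, t) = A_ref(x) · g(c(x) · (p − p_ext(x) − p_ref))   (tube law)

External pressures load the wall region-wise (ICP on the intracranial
segment, Pio + Pe on the extracranial one; the optic canal is rigid). The
inlet is a prescribed pressure waveform, the outlet a terminal resistance to
a zero venous reference. Convective acceleration is dropped — at ophthalmic
artery scale (radius ≈ 0.7 mm, velocity ≈ 17 cm/s) it is dominated by the
viscous and pressure terms, and dropping it keeps the semi-implicit pressure
solve linear and unconditionally stable at the 4 ms reporting step even
though the elastic wave speed violates the explicit CFL limit by orders of
magnitude.

All public values are in mmHg / mm / cm·s⁻¹ / mL·s⁻¹; the solver itself runs
in SI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import expit

from .errors import SimulationError
from .geometry import CANAL, VesselGeometry
from .loads import PressureLoad, external_pressure_at, inlet_pressure_waveform
from .units import MMHG_TO_PA

__all__ = [
    "SimConfig",
    "HemoField",
    "ProbeSeries",
    "tube_law_area",
    "tube_law_area_slope",
    "simulate",
    "probe",
    "cycle_convergence",
    "poiseuille_pressure_drop",
    "volume_budget",
]


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of the 1-D solver.

    ``time_step_s × samples_per_cycle`` must equal the cardiac period of the
    load (checked at simulation time). At least two cycles are required so a
    cycle-to-cycle convergence check is possible; the default three-cycle
    protocol ramps all loads during cycle 1 and analyzes cycle 3.
    """

    time_step_s: float = 0.004
    samples_per_cycle: int = 250
    n_cycles: int = 3
    ramp_cycles: int = 1
    spatial_nodes: int = 61
    blood_density_kg_m3: float = 1050.0
    blood_viscosity_pa_s: float = 3.5e-3
    convergence_tol: float = 1e-4
    collapse_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.time_step_s <= 0 or self.samples_per_cycle < 2:
            raise ValueError("invalid time discretization")
        if self.n_cycles < 2:
            raise ValueError("need at least 2 cycles for a convergence check")
        if not (1 <= self.ramp_cycles < self.n_cycles):
            raise ValueError("ramp must occupy at least one, and not all, cycles")
        if self.spatial_nodes < 5:
            raise ValueError("too few spatial nodes")
        if self.blood_density_kg_m3 <= 0 or self.blood_viscosity_pa_s <= 0:
            raise ValueError("blood properties must be positive")
        if not (0 < self.collapse_floor < 1):
            raise ValueError("collapse floor must be a fraction in (0, 1)")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class HemoField:
    """Space–time solution of one simulation run.

    Arrays are shaped ``(n_times, n_nodes)``; ``cycle_index`` labels each time
    sample with its cardiac cycle (0-based; cycle 0 is the ramp).
    """

    time_s: np.ndarray
    x_mm: np.ndarray
    area_mm2: np.ndarray
    velocity_cm_s: np.ndarray
    pressure_mmhg: np.ndarray
    cycle_index: np.ndarray
    q_in_ml_s: np.ndarray
    q_out_ml_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def samples_per_cycle(self) -> int:
        return int(self.metadata["samples_per_cycle"])

    def cycle_slice(self, cycle: int) -> slice:
        n = self.samples_per_cycle
        n_cycles = len(self.time_s) // n
        if cycle < 0:
            cycle += n_cycles
        if not 0 <= cycle < n_cycles:
            raise IndexError("cycle index out of range")
        return slice(cycle * n, (cycle + 1) * n)


@dataclass
class ProbeSeries:
    """Vicinity-averaged probe readings over the final cardiac cycle."""

    location_id: str
    time_s: np.ndarray
    velocity_cm_s: np.ndarray
    area_mm2: np.ndarray
    pressure_mmhg: np.ndarray
    velocity_mean_cm_s: float
    area_mean_mm2: float
    pressure_mean_mmhg: float


# ---------------------------------------------------------------------------
# Tube law
# ---------------------------------------------------------------------------

def _g_and_slope(s, floor: float):
    """Smoothly floored exponential g(s) and its derivative g'(s).

    g(s) ≈ exp(s) away from collapse and is smoothly bounded below by the
    collapse floor via a soft-max blend of width floor/4.
    """
    s = np.clip(np.asarray(s, dtype=float), -60.0, 60.0)
    e = np.exp(s)
    tau = floor / 4.0
    g = tau * np.logaddexp(e / tau, floor / tau)
    w = expit((e - floor) / tau)  # blend weight → 1 away from the floor
    return g, e * w


def tube_law_area(
    p_lumen_mmhg,
    p_ext_mmhg,
    reference_radius_mm: float,
    compliance_per_mmhg: float,
    reference_transmural_mmhg: float = 40.0,
    collapse_floor: float = 0.05,
):
    """Cross-sectional area (mm²) from the algebraic tube law.

    ``A = A_ref · g(c · (Δp − Δp_ref))`` with transmural pressure
    ``Δp = p_lumen − p_ext``; g is exponential with a smooth collapse floor,
    g(0) = 1, so the reference area is attained at the reference transmural
    pressure. A rigid region (c = 0) returns the reference area regardless of
    the pressures.
    """
    if compliance_per_mmhg < 0:
        raise ValueError("compliance must be non-negative")
    a_ref = np.pi * reference_radius_mm**2
    dp = np.asarray(p_lumen_mmhg, dtype=float) - np.asarray(p_ext_mmhg, dtype=float)
    if compliance_per_mmhg == 0.0:
        out = np.full(dp.shape, a_ref)
        return out if dp.shape else float(a_ref)
    g, _ = _g_and_slope(
        compliance_per_mmhg * (dp - reference_transmural_mmhg), collapse_floor
    )
    out = a_ref * g
    return out if dp.shape else float(out)


def tube_law_area_slope(
    p_lumen_mmhg,
    p_ext_mmhg,
    reference_radius_mm: float,
    compliance_per_mmhg: float,
    reference_transmural_mmhg: float = 40.0,
    collapse_floor: float = 0.05,
):
    """dA/dp_lumen (mm² per mmHg) of the tube law; 0 for rigid regions."""
    a_ref = np.pi * reference_radius_mm**2
    dp = np.asarray(p_lumen_mmhg, dtype=float) - np.asarray(p_ext_mmhg, dtype=float)
    if compliance_per_mmhg == 0.0:
        out = np.zeros(dp.shape)
        return out if dp.shape else 0.0
    _, gp = _g_and_slope(
        compliance_per_mmhg * (dp - reference_transmural_mmhg), collapse_floor
    )
    out = a_ref * compliance_per_mmhg * gp
    return out if dp.shape else float(out)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def simulate(
    geometry: VesselGeometry, load: PressureLoad, config: SimConfig
) -> HemoField:
    """Run the pulsatile 1-D simulation and return the full field.

    Cycle 1 linearly ramps every acting pressure (inlet waveform, ICP, Pio,
    Pe) from zero to its prescribed value; subsequent cycles run at full
    load. The cycle-convergence metric (max relative probe-area difference
    between the last two cycles) is stored in ``metadata["convergence"]``.

    Raises
    ------
    SimulationError
        If the semi-implicit step produces non-finite pressures.
    """
    T = load.period_s
    if abs(config.time_step_s * config.samples_per_cycle - T) > 1e-9 * T:
        raise SimulationError(
            "time_step_s × samples_per_cycle must equal the cardiac period "
            f"({config.time_step_s} × {config.samples_per_cycle} ≠ {T})"
        )

    nx = config.spatial_nodes
    x_m = np.linspace(0.0, geometry.total_length_mm * 1e-3, nx)
    x_mm = x_m * 1e3
    dx = x_m[1] - x_m[0]
    region = geometry.region_index(x_mm)
    radius_mm = np.asarray(geometry.radius_mm)[region]
    a_ref_m2 = np.pi * (radius_mm * 1e-3) ** 2
    c_mmhg = np.asarray(geometry.compliance_per_mmhg)[region]
    p_ext_full_pa = external_pressure_at(x_mm, geometry, load) * MMHG_TO_PA
    p_ref = geometry.reference_transmural_mmhg

    rho = config.blood_density_kg_m3
    mu = config.blood_viscosity_pa_s
    r_out = load.outlet_resistance_mmhg_s_ml * MMHG_TO_PA / 1e-6  # Pa·s/m³
    dt = config.time_step_s
    nt = config.n_cycles * config.samples_per_cycle
    ramp_time = config.ramp_cycles * T

    compliant = c_mmhg > 0

    def area_si(p_pa, p_ext_pa):
        dp_mmhg = (p_pa - p_ext_pa) / MMHG_TO_PA
        a = a_ref_m2.copy()
        if compliant.any():
            g, _ = _g_and_slope(
                c_mmhg[compliant] * (dp_mmhg[compliant] - p_ref),
                config.collapse_floor,
            )
            a[compliant] = a_ref_m2[compliant] * g
        return a

    def slope_si(p_pa, p_ext_pa):
        """dA/dp in m²/Pa; zero in rigid regions."""
        dp_mmhg = (p_pa - p_ext_pa) / MMHG_TO_PA
        s = np.zeros(nx)
        if compliant.any():
            _, gp = _g_and_slope(
                c_mmhg[compliant] * (dp_mmhg[compliant] - p_ref),
                config.collapse_floor,
            )
            s[compliant] = a_ref_m2[compliant] * c_mmhg[compliant] * gp / MMHG_TO_PA
        return s

    cell = np.full(nx, dx)
    cell[0] = cell[-1] = dx / 2.0  # half cells at the Dirichlet/outlet ends

    p = np.zeros(nx)  # Pa, unloaded initial state
    A = area_si(p, np.zeros(nx))
    Q = np.zeros(nx - 1)  # m³/s on interfaces

    P_out = np.empty((nt, nx))
    V_out = np.empty((nt, nx))
    A_out = np.empty((nt, nx))
    q_in_out = np.empty(nt)
    q_out_out = np.empty(nt)
    floor_hits = 0
    friction = 8.0 * np.pi * mu

    for n in range(nt):
        t_new = (n + 1) * dt
        # Smoothstep ramp: monotone 0→1 over the ramp cycle(s) with zero end
        # slope, so no residual transient is excited at the ramp/periodic
        # boundary and cycles 2 and 3 coincide to the convergence tolerance.
        u = min(t_new / ramp_time, 1.0)
        ramp = u * u * (3.0 - 2.0 * u)
        p_in = ramp * inlet_pressure_waveform(t_new, load) * MMHG_TO_PA
        p_ext = ramp * p_ext_full_pa

        a_face = 0.5 * (A[:-1] + A[1:])
        damp = 1.0 + dt * friction / (rho * a_face)
        beta = (dt * a_face / (rho * dx)) / damp
        gamma = Q / damp
        cap = slope_si(p, p_ext) * cell / dt  # m³/Pa/s

        # Tridiagonal system for p[1:]; node 0 is Dirichlet at p_in.
        # Row j solves node i = j+1. Interfaces: beta[i] couples nodes i, i+1.
        m = nx - 1
        diag = np.empty(m)
        rhs = np.empty(m)
        diag[:-1] = cap[1:-1] + beta[1:] + beta[:-1]
        rhs[:-1] = cap[1:-1] * p[1:-1] - (gamma[1:] - gamma[:-1])
        rhs[0] += beta[0] * p_in
        diag[-1] = cap[-1] + beta[-1] + 1.0 / r_out  # resistive outlet node
        rhs[-1] = cap[-1] * p[-1] + gamma[-1]

        ab = np.zeros((3, m))
        ab[0, 1:] = -beta[1:]  # superdiagonal A[j, j+1]
        ab[1, :] = diag
        ab[2, :-1] = -beta[1:]  # subdiagonal A[j+1, j]
        p_new_inner = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(p_new_inner)):
            raise SimulationError(
                f"solver diverged at t = {t_new:.3f} s "
                f"(ICP={load.icp_mmhg}, Pe={load.pe_mmhg} mmHg)"
            )
        p_new = np.concatenate(([p_in], p_new_inner))
        Q = gamma - beta * (p_new[1:] - p_new[:-1])
        A_new = area_si(p_new, p_ext)
        floor_hits += int(np.sum(A_new <= 1.05 * config.collapse_floor * a_ref_m2))

        q_out = p_new[-1] / r_out
        q_in = Q[0] + cell[0] * (A_new[0] - A[0]) / dt

        v = np.empty(nx)
        v[1:-1] = 0.5 * (Q[:-1] + Q[1:]) / A_new[1:-1]
        v[0] = Q[0] / A_new[0]
        v[-1] = q_out / A_new[-1]

        P_out[n] = p_new / MMHG_TO_PA
        V_out[n] = v * 100.0  # cm/s
        A_out[n] = A_new * 1e6  # mm²
        q_in_out[n] = q_in * 1e6  # mL/s
        q_out_out[n] = q_out * 1e6
        p, A = p_new, A_new

    if floor_hits:
        warnings.warn(
            f"collapse floor reached at {floor_hits} space-time samples; "
            "areas are saturated at the floor",
            RuntimeWarning,
            stacklevel=2,
        )

    field_ = HemoField(
        time_s=dt * np.arange(1, nt + 1),
        x_mm=x_mm,
        area_mm2=A_out,
        velocity_cm_s=V_out,
        pressure_mmhg=P_out,
        cycle_index=np.repeat(np.arange(config.n_cycles), config.samples_per_cycle),
        q_in_ml_s=q_in_out,
        q_out_ml_s=q_out_out,
        metadata={
            "samples_per_cycle": config.samples_per_cycle,
            "n_cycles": config.n_cycles,
            "icp_mmhg": load.icp_mmhg,
            "pio_mmhg": load.pio_mmhg,
            "pe_mmhg": load.pe_mmhg,
            "collapse_floor_hits": floor_hits,
        },
    )
    if config.n_cycles >= 3:
        field_.metadata["convergence"] = cycle_convergence(field_, geometry)
    return field_


# ---------------------------------------------------------------------------
# Probing & diagnostics
# ---------------------------------------------------------------------------

def _vicinity_mask(field: HemoField, geometry: VesselGeometry, location_id: str):
    loc = geometry.probe_location_mm(location_id)
    half = geometry.probe_halfwidth_mm
    region = int(geometry.region_index(loc))
    lo, hi = geometry.region_bounds_mm(region)
    if loc - half < lo or loc + half > hi:
        raise ValueError(
            f"probe vicinity [{loc - half}, {loc + half}] mm extends outside "
            f"its region [{lo}, {hi}] mm"
        )
    return np.abs(field.x_mm - loc) <= half + 1e-9


def probe(field: HemoField, geometry: VesselGeometry, location_id: str) -> ProbeSeries:
    """Vicinity-averaged velocity/area/pressure at a probe, final cycle only."""
    mask = _vicinity_mask(field, geometry, location_id)
    sl = field.cycle_slice(-1)
    v = field.velocity_cm_s[sl][:, mask].mean(axis=1)
    a = field.area_mm2[sl][:, mask].mean(axis=1)
    p = field.pressure_mmhg[sl][:, mask].mean(axis=1)
    return ProbeSeries(
        location_id=location_id.lower(),
        time_s=field.time_s[sl],
        velocity_cm_s=v,
        area_mm2=a,
        pressure_mmhg=p,
        velocity_mean_cm_s=float(v.mean()),
        area_mean_mm2=float(a.mean()),
        pressure_mean_mmhg=float(p.mean()),
    )


def cycle_convergence(field: HemoField, geometry: VesselGeometry) -> float:
    """Max relative probe-area difference between the 2nd and 3rd cycles.

    The three-cycle protocol ramps loads during cycle 1; this metric verifies
    that the ramp transient has died out, i.e. cycles 2 and 3 coincide.
    """
    if field.metadata.get("n_cycles", 0) < 3:
        raise ValueError("cycle convergence requires at least 3 simulated cycles")
    worst = 0.0
    for loc in ("ioa", "eoa"):
        mask = _vicinity_mask(field, geometry, loc)
        a2 = field.area_mm2[field.cycle_slice(1)][:, mask].mean(axis=1)
        a3 = field.area_mm2[field.cycle_slice(2)][:, mask].mean(axis=1)
        worst = max(worst, float(np.max(np.abs(a3 - a2) / a2)))
    return worst


def poiseuille_pressure_drop(
    geometry: VesselGeometry,
    q_ml_s: float,
    viscosity_pa_s: float = 3.5e-3,
) -> float:
    """Analytic Hagen–Poiseuille drop (mmHg) between the two probes.

    ΔP = 8 μ L Q / (π r⁴) with L the inter-probe distance and r the mean of
    the two probe regions' reference radii.
    """
    if q_ml_s < 0:
        raise ValueError("flow must be non-negative")
    L = geometry.interprobe_length_mm * 1e-3
    r = 0.5 * (geometry.radius_mm[0] + geometry.radius_mm[2]) * 1e-3
    q = q_ml_s * 1e-6
    dp_pa = 8.0 * viscosity_pa_s * L * q / (np.pi * r**4)
    return float(dp_pa / MMHG_TO_PA)


def volume_budget(field: HemoField) -> float:
    """Relative volume imbalance over the final cycle.

    |∫(q_in − q_out) dt − ΔV_stored| / ∫ q_in dt, with stored volume computed
    from the recorded areas on the solver's cell partition.
    """
    sl = field.cycle_slice(-1)
    dt = float(field.time_s[1] - field.time_s[0])
    dx = float(field.x_mm[1] - field.x_mm[0])
    w = np.full(field.x_mm.shape, dx)
    w[0] = w[-1] = dx / 2.0
    vol = field.area_mm2 @ w / 1000.0  # mm³ → mL
    start = sl.start
    v_prev = vol[start - 1] if start > 0 else vol[start]
    net_in = float(np.sum(field.q_in_ml_s[sl] - field.q_out_ml_s[sl]) * dt)
    stored = float(vol[sl.stop - 1] - v_prev)
    throughput = float(np.sum(field.q_in_ml_s[sl]) * dt)
    return abs(net_in - stored) / throughput
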