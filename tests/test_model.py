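"""Tube law and the 1-D pulsatile solver: oracles and physical invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oasense import (
    HemoField,
    PressureLoad,
    SimConfig,
    cycle_convergence,
    poiseuille_pressure_drop,
    probe,
    simulate,
    tube_law_area,
    volume_budget,
)

A_REF = float(np.pi * 0.7**2)  # mm², canonical 0.7 mm radius
P_REF = 40.0  # default reference transmural pressure, mmHg


class TestTubeLaw:
    def test_reference_transmural_gives_reference_area(self):
        a = tube_law_area(P_REF + 10.0, 10.0, 0.7, 0.003)
        assert a == pytest.approx(A_REF, rel=1e-9)

    def test_rigid_region_always_reference(self):
        for p_lumen, p_ext in [(0, 0), (200, 0), (0, 200), (60, 20)]:
            assert tube_law_area(p_lumen, p_ext, 0.7, 0.0) == pytest.approx(A_REF)

    def test_slope_at_reference_matches_compliance(self):
        # finite-difference dA/dp at the reference transmural pressure
        c = 0.003
        h = 1e-4
        fd = (
            tube_law_area(P_REF + h, 0.0, 0.7, c)
            - tube_law_area(P_REF - h, 0.0, 0.7, c)
        ) / (2 * h)
        assert fd == pytest.approx(A_REF * c, rel=1e-2)

    @settings(derandomize=True, max_examples=50)
    @given(
        p1=st.floats(-200, 400),
        p2=st.floats(-200, 400),
        c=st.floats(1e-4, 0.01),
    )
    def test_monotone_and_floored(self, p1, p2, c):
        lo, hi = sorted([p1, p2])
        a_lo = tube_law_area(lo, 0.0, 0.7, c)
        a_hi = tube_law_area(hi, 0.0, 0.7, c)
        assert a_hi >= a_lo > 0.049 * A_REF  # strictly positive, above floor


class TestSolverOracles:
    def test_rigid_steady_matches_poiseuille(self, geometry, config):
        """Zero compliance + steady inflow → the closed-form resistive solution."""
        rigid = geometry.with_(compliance_per_mmhg=(0.0, 0.0, 0.0))
        load = PressureLoad(icp_mmhg=10.0, pio_mmhg=4.0, inlet_amplitude_mmhg=0.0)
        field = simulate(rigid, load, config)
        sl = field.cycle_slice(-1)
        v = field.velocity_cm_s[sl]
        assert np.ptp(v[-1]) / v[-1].mean() < 1e-3  # uniform velocity
        p_ioa = probe(field, rigid, "ioa")
        p_eoa = probe(field, rigid, "eoa")
        q = float(field.q_in_ml_s[sl].mean())
        simulated_drop = p_ioa.pressure_mean_mmhg - p_eoa.pressure_mean_mmhg
        analytic = poiseuille_pressure_drop(rigid, q, config.blood_viscosity_pa_s)
        assert simulated_drop == pytest.approx(analytic, rel=1e-2)
        # pressure profile is linear in x within each uniform-radius run
        p_final = field.pressure_mmhg[-1]
        resid = p_final - np.polyval(np.polyfit(field.x_mm, p_final, 1), field.x_mm)
        assert np.max(np.abs(resid)) < 1e-2 * np.ptp(p_final)

    def test_volume_conservation(self, balance_run):
        assert volume_budget(balance_run["field"]) < 1e-3

    def test_cycle_convergence_below_protocol_bound(self, balance_run, geometry):
        assert balance_run["field"].metadata["convergence"] < 1e-4

    def test_determinism(self, geometry, config):
        load = PressureLoad(icp_mmhg=10.0, pe_mmhg=6.0)
        f1 = simulate(geometry, load, config)
        f2 = simulate(geometry, load, config)
        assert np.array_equal(f1.area_mm2, f2.area_mm2)
        assert np.array_equal(f1.velocity_cm_s, f2.velocity_cm_s)

    def test_canal_area_constant(self, balance_run, geometry):
        field = balance_run["field"]
        canal = (field.x_mm > geometry.ioa_end_mm + 1e-9) & (
            field.x_mm < geometry.canal_end_mm - 1e-9
        )
        assert np.allclose(field.area_mm2[:, canal], A_REF, rtol=1e-12)

    def test_eoa_monotone_response_to_pe(self, geometry, config):
        """More external orbital pressure → narrower EOA, faster EOA flow."""
        areas, velocities = [], []
        for pe in (4.0, 12.0, 20.0):
            load = PressureLoad(icp_mmhg=20.0, pio_mmhg=4.0, pe_mmhg=pe)
            field = simulate(geometry, load, config)
            p = probe(field, geometry, "eoa")
            areas.append(p.area_mean_mm2)
            velocities.append(p.velocity_mean_cm_s)
        assert areas[0] > areas[1] > areas[2]
        assert velocities[0] < velocities[1] < velocities[2]

    def test_symmetry_in_zero_flow_limit(self, geometry, config):
        """Equal external loads + no flow → identical probe areas."""
        load = PressureLoad(
            icp_mmhg=10.0,
            pio_mmhg=10.0,
            pe_mmhg=0.0,
            inlet_amplitude_mmhg=0.0,
            outlet_resistance_mmhg_s_ml=1e9,
        )
        field = simulate(geometry, load, config)
        a_ioa = probe(field, geometry, "ioa").area_mean_mm2
        a_eoa = probe(field, geometry, "eoa").area_mean_mm2
        assert a_ioa == pytest.approx(a_eoa, rel=1e-6)


class TestProbe:
    def test_probe_series_length_and_mean_identity(self, balance_run):
        p = balance_run["probe_ioa"]
        assert len(p.velocity_cm_s) == 250
        assert p.velocity_mean_cm_s == pytest.approx(p.velocity_cm_s.mean(), abs=0)
        assert p.area_mean_mm2 == pytest.approx(p.area_mm2.mean(), abs=0)

    def test_uniform_field_probe_returns_field_value(self, geometry):
        nt, nx = 750, 61
        x = np.linspace(0, 30.0, nx)
        field = HemoField(
            time_s=0.004 * np.arange(1, nt + 1),
            x_mm=x,
            area_mm2=np.full((nt, nx), 1.5),
            velocity_cm_s=np.full((nt, nx), 17.0),
            pressure_mmhg=np.full((nt, nx), 60.0),
            cycle_index=np.repeat(np.arange(3), 250),
            q_in_ml_s=np.zeros(nt),
            q_out_ml_s=np.zeros(nt),
            metadata={"samples_per_cycle": 250, "n_cycles": 3},
        )
        p = probe(field, geometry, "ioa")
        assert np.allclose(p.velocity_cm_s, 17.0)
        assert p.area_mean_mm2 == pytest.approx(1.5)

    def test_probe_vicinity_outside_region_rejected(self, balance_run, geometry):
        wide = geometry.with_(probe_halfwidth_mm=6.0)  # IOA probe at 5 mm
        with pytest.raises(ValueError, match="vicinity"):
            probe(balance_run["field"], wide, "ioa")


class TestCycleConvergence:
    def _synthetic_field(self, cycle3_scale):
        nt, nx = 750, 61
        a = np.full((nt, nx), 1.5)
        a[500:] *= cycle3_scale
        return HemoField(
            time_s=0.004 * np.arange(1, nt + 1),
            x_mm=np.linspace(0, 30.0, nx),
            area_mm2=a,
            velocity_cm_s=np.zeros((nt, nx)),
            pressure_mmhg=np.zeros((nt, nx)),
            cycle_index=np.repeat(np.arange(3), 250),
            q_in_ml_s=np.zeros(nt),
            q_out_ml_s=np.zeros(nt),
            metadata={"samples_per_cycle": 250, "n_cycles": 3},
        )

    def test_periodic_field_converged(self, geometry):
        assert cycle_convergence(self._synthetic_field(1.0), geometry) == 0.0

    def test_known_relative_difference(self, geometry):
        metric = cycle_convergence(self._synthetic_field(1.0001), geometry)
        assert metric == pytest.approx(1e-4, rel=1e-6)

    def test_two_cycles_rejected(self, geometry):
        f = self._synthetic_field(1.0)
        f.metadata["n_cycles"] = 2
        with pytest.raises(ValueError):
            cycle_convergence(f, geometry)


class TestConfigValidation:
    def test_period_mismatch_rejected(self, geometry):
        from oasense.errors import SimulationError

        cfg = SimConfig(time_step_s=0.005)  # 0.005 × 250 ≠ 1.0 s
        with pytest.raises(SimulationError):
            simulate(geometry, PressureLoad(), cfg)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cycles=1)
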