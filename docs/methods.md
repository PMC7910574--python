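# Methods

This document records the model equations, canonical parameters, numerical
choices, and the scope and limitations of the synthetic data generators.

## 1. Physical picture

The ophthalmic artery (OA) is modeled as a single straight compliant tube of
total length 30 mm divided into three axial regions:

1. **IOA** (0–10 mm): intracranial segment, externally loaded by the
   intracranial pressure ICP;
2. **optic canal** (10–14 mm): bony, treated as rigid (zero compliance),
   external pressure irrelevant;
3. **EOA** (14–30 mm): intraorbital/extraorbital segment, externally loaded
   by the intraorbital tissue pressure Pio plus any externally applied
   orbital pressure Pe.

Doppler probe volumes sit at 5 mm (IOA) and 22 mm (EOA), each averaging over
± 1 mm, giving an inter-probe distance of L = 17 mm.

### Snapshot measurement principle

Pe is swept while the cycle-averaged probe velocities are compared. Because
the two compliant segments share one lumen and obey the same tube law, the
cycle-mean velocities coincide when the external loads produce equal mean
cross-sections, i.e. when the *transmural* pressures match. Accounting for
the intraluminal pressure falling by the viscous drop ΔP between the probes,
the balance condition is

```
ICP − Pe* = Pio + ΔP_HP + residual,
```

with ΔP_HP the Hagen–Poiseuille drop `8 μ L Q / (π r⁴)` at the cycle-mean
flow Q. With the canonical parameters (Pio = 4 mmHg, ΔP_HP ≈ 1.23 mmHg) the
total offset is ≈ 5.2 mmHg ("about 6"), and the unexplained residual is
on the order of 0.01–0.1 mmHg (`oasense.snapshot.decompose_error`).

## 2. Governing equations

The flow is a 1-D cross-sectionally averaged incompressible network: with
A(x,t) the lumen area, Q(x,t) the volumetric flow, p(x,t) the intraluminal
pressure,

```
C(p) ∂p/∂t + ∂Q/∂x = 0                      (mass, C = dA/dp)
∂Q/∂t = −(A/ρ) ∂p/∂x − 8πμ Q/(ρA)           (momentum)
```

The convective momentum term is dropped: at the canonical mean velocity
(~0.17 m/s) and pressure scale (tens of mmHg) it is second-order relative to
the pressure-gradient and friction terms, and the quantities of interest are
cycle averages. Friction is the Poiseuille (fully developed, quasi-steady)
value `8πμQ/(ρA)`, consistent with the analytic decomposition target.

### Tube law

Each compliant region follows an exponential area–pressure relation about a
physiological reference state:

```
A(Δp) = A_ref · g( c · (Δp − Δp_ref) ),     g(s) ≈ exp(s) with a smooth floor
```

where Δp = p − p_ext is the transmural pressure, `c` the fractional
compliance (per mmHg), and Δp_ref = 40 mmHg the **reference transmural
pressure** at which the vessel has its nominal radius. Referencing at a
physiological transmural load (rather than at zero) means the canonical
radius of 0.7 mm is the radius under normal operating conditions. A smooth
softplus-style floor at 5% of A_ref (`collapse_floor`) keeps the law
strictly positive and C¹, preventing numerical collapse at strongly negative
transmural pressures; a warning is emitted if any node approaches the floor.
The rigid canal uses c = 0 (area identically A_ref).

## 3. Canonical parameters

All defaults are fixed by `build_default_geometry()`, `PressureLoad()` and
`SimConfig()`; they are the study conditions, not tunables.

| Parameter | Value | Rationale |
| --- | --- | --- |
| vessel radius | 0.7 mm (all regions) | nominal human OA radius |
| region bounds | 0–10 / 10–14 / 14–30 mm | IOA / optic canal / EOA |
| probe centers | 5 mm and 22 mm (± 1 mm) | inter-probe distance 17 mm |
| compliance c | 0.003 /mmHg (IOA, EOA); 0 (canal) | few-percent area change over tens of mmHg |
| reference transmural | 40 mmHg | physiological operating point |
| blood density ρ | 1050 kg/m³ | standard |
| blood viscosity μ | 3.5 mPa·s | standard |
| inlet pressure | 60 ± 20 mmHg, mean-corrected rectified sine, period 1 s | pulsatile arterial surrogate; `p_in = 60 + 20(|sin πt/T| − 2/π)` keeps the cycle mean at 60 mmHg |
| outlet resistance | 223 mmHg·s/mL | calibrated **once** so the cycle-mean velocity is ≈ 17 cm/s, which puts the analytic inter-probe drop at ≈ 1.23 mmHg; not re-tuned thereafter |
| Pio | 4 mmHg | canonical intraorbital tissue pressure |
| Pe grid (snapshot) | 0 : 2 : 34 mmHg | spans balance for ICP 10–30 |

## 4. Numerical scheme

- **Staggered grid**: 61 pressure nodes, flows at the 61 interfaces
  (inlet boundary face plus internodal faces); Δx = 0.5 mm.
- **Semi-implicit time stepping** (Δt = 4 ms, 250 samples per 1-s cycle):
  the friction term and the pressure gradient driving `Q^{n+1}` are treated
  implicitly, giving one symmetric tridiagonal solve per step
  (`scipy.linalg.solve_banded`). The elastic wave speed
  `√(A/(ρC)) ≈ 6.5 m/s` would force an explicit CFL limit of Δt ≲ 0.08 ms;
  the implicit treatment is unconditionally stable at Δt = 4 ms, and cycle
  averages are converged at this resolution.
- **Areas** are updated from the tube law after the pressure solve
  (pointwise, no extra linearization error enters the mass balance because
  the capacitance uses the current tube-law slope).
- **Outlet**: resistive boundary `Q_out = p_N / R_out` folded into the last
  row of the tridiagonal system.
- **Ramp protocol**: 3 cycles are simulated; during the first cycle all
  driving pressures are scaled by the smoothstep `u²(3 − 2u)`, `u = t/T`.
  The smoothstep (rather than a linear ramp) has zero slope at the cycle
  boundary, so no slope-discontinuity transient is injected; the measured
  cycle-2 vs cycle-3 probe-area difference is ≈ 5 × 10⁻⁶ relative
  (protocol bound: 10⁻⁴, i.e. 0.01%). Cycle 3 is the analysis cycle.
- **Diagnostics**: `volume_budget()` checks the final-cycle net-inflow vs
  storage closure (< 10⁻³ relative); `cycle_convergence()` implements the
  cycle-2/cycle-3 probe-area criterion; metadata records both plus a config
  hash.
- **Determinism**: the solver is noise-free and bitwise deterministic;
  every stochastic component elsewhere takes an explicit seed.

### Balance finding

`sweep_pe` runs one simulation per grid Pe and records
Δv = v̄_IOA − v̄_EOA. `find_balance_pe` fits a quadratic (linear for < 4
points) to (Pe, Δv) and returns the polynomial root nearest the raw
sign-change interval; absence of a sign change raises
`BalanceNotBracketedError` rather than extrapolating.

## 5. Doppler synthesis and the BFF

Ultrasound signal power from a probe volume is taken proportional to the
instantaneous lumen cross-section: `Ps = gain · A · (1 + ε)`,
ε ~ N(0, σ²) i.i.d. per sample (multiplicative noise, clipped to keep Ps
positive). No acoustic propagation, angle dependence or spectral processing
is modeled — the two-channel *ratio* over a cardiac-cycle-scale window is
the quantity of interest.

The **blood-flow factor** over a 10-s non-overlapping window is the
time-normalized integral of the log intensity ratio:

```
BFF = (1/T_w) ∫ ln( Ps_IOA / Ps_EOA ) dt
```

computed by trapezoidal quadrature over valid samples; a window with < 50%
valid samples is masked (NaN + valid=False), not an error. Properties used
by the test suite: invariance to common gain, shift by ln k under
single-channel scaling, antisymmetry under channel swap.

**Sign convention.** Under the area-proportional intensity model, raising
ICP compresses the IOA and *lowers* the IOA/EOA ratio, so raw BFF decreases
with ICP. Any fixed affine transformation of the BFF is absorbed exactly by
the per-subject calibration `ICP = a·BFF + b` (verified by an invariance
test), so the sign convention has no effect downstream; the package keeps
the literal `ln(Ps_IOA/Ps_EOA)` definition.

The **artifact filter** masks (never unmasks) samples that are > 5 robust
SDs from a 1-s rolling median (spikes) or below 5% of the channel median
(dropouts); removed-sample counts are recorded in trace metadata. A centered
60-s moving average (partial windows at the edges, valid-sample weighting)
is available for display smoothing; monitoring statistics apply it to both
series or neither, so differences are not biased.

## 6. Calibration and monitoring

Per-subject calibration is ordinary least squares of invasive ICP on BFF
over the first `n_points` (default 30, i.e. 5 min) valid pairs of a session;
degenerate inputs (constant BFF, < 2 points) raise `CalibrationError`. The
residual SD uses n − 2 degrees of freedom. The session is then monitored to
its end (≤ 1 h, strict 10-s sampling enforced by `MonitoringSession`)
without recalibration; `run_monitoring` returns paired
invasive/non-invasive estimates and summary statistics.

## 7. Evaluation statistics

- `bland_altman`: differences fixed as invasive − non-invasive; limits of
  agreement mean ± 1.96 SD (sample SD, ddof = 1); empirical 2.5/97.5
  percentiles reported alongside.
- `pooled_stats`: combines per-subject (mean, SD, n) by the exact
  combined-variance identity
  `SD² = [Σ(nᵢ−1)sdᵢ² + Σnᵢ(meanᵢ−m̄)²]/(N−1)`, reproducing the statistics
  of the concatenated sample. Applied to the six published per-subject rows
  it returns N = 1928, mean 0.0855 mmHg, SD 1.346 mmHg.
- `agreement_regression`: OLS of non-invasive on invasive ICP with Pearson r.

## 8. Synthetic cohort: scope and limitations

`default_cohort()` encodes six subject profiles whose published summary
parameters are matched exactly: ICP ranges {12–22, 16–19, 8–11, 10–19,
8–10, 13–17} mmHg, calibration pairs (a, b) = {(56.3, 10.1), (263.8, 11.8),
(70.4, 6.2), (218.9, 4.5), (109.8, 3.8), (586.2, 6.9)}, difference SDs
{0.91, 1.23, 1.07, 1.61, 0.64, 1.20} mmHg, and pair counts {223, 360, 356,
280, 360, 349} (Σ = 1928).

Each session is generated as:

1. **ICP trajectory** (invented surrogate): mid-range start, Gaussian random
   walk (step SD 0.03 × range span per 10 s) plus a sinusoidal slow-wave
   component (amplitude 0.35 × span, period uniform in 60–180 s — a B-wave
   surrogate), reflected at the range bounds. These two fractions are fixed
   by the generator's published-envelope requirement (end-to-end pooled mean
   within ± 0.5 mmHg and pooled SD within 0.6–2.0 mmHg across master seeds)
   and are not otherwise tuned. The surrogate reproduces the slow, strongly
   autocorrelated character of ICP at 0.1 Hz — not any patient's waveform,
   pulse/respiratory components, or plateau-wave pathology.
2. **BFF channel**: `bff = (icp_true − b)/a + η/a`, η ~ N(0, diff_sd²), so
   the invasive-minus-estimated difference SD under the true calibration is
   the profile's target by construction. The invasive channel records
   `icp_true` exactly (reference-sensor noise is folded into diff_sd).
3. **Seeding**: `numpy.random.SeedSequence(master_seed)` spawned per
   subject, then per stream (trajectory vs noise); identical master seeds
   give bitwise-identical cohorts.

**Statistical caveat**: because the generator puts all noise in the BFF
regressor, the forward OLS fit ICP ~ BFF is attenuated (errors-in-variables)
for subjects whose ICP span is small relative to their difference SD. This
is a faithful property of the measurement situation, is absorbed by the
affine calibration at the agreement level, and is why coefficient-recovery
tests use the inverse regression (BFF on ICP, noise in the dependent
variable), which is consistent and has valid standard errors.

## 9. Problem sizes

Chosen so the full acceptance computation runs in well under a minute of CPU
per criterion: 61 spatial nodes × 750 time steps per simulation (~0.15 s),
18-point Pe sweeps × 3 ICP levels (~7 s), 100-seed cohort envelopes (~1 s).
These sizes are the package's own defaults; finer grids change the reported
quantities by less than the convergence metric (10⁻⁴ relative).
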