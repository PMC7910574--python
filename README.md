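# oasense

Reduced-order modeling and measurement tooling for using the **human
ophthalmic artery (OA) as a pressure sensor for non-invasive intracranial
pressure (ICP) monitoring**.

The OA runs from the skull interior, through the rigid optic canal, into the
eye orbit. Its intracranial segment (IOA) is loaded externally by ICP; its
extraorbital segment (EOA) is loaded by the intraorbital tissue pressure
(Pio) plus any externally applied orbital pressure (Pe). Because the two
segments share one lumen, applying external pressure to the orbit until the
blood-flow conditions in the two segments **balance** turns the artery into a
null-detector for ICP: at balance, `Pe* ≈ ICP` up to a small, decomposable
systematic offset. Continuous monitoring then tracks a two-depth Doppler
intensity statistic (the *blood-flow factor*, BFF) through a per-subject
linear calibration `ICP = a·BFF + b`.

The package provides:

| Module | Purpose |
| --- | --- |
| `oasense.geometry`, `oasense.loads` | Canonical three-segment vessel geometry and pressure loading |
| `oasense.model` | 1-D pulsatile compliant-vessel hemodynamic simulator (semi-implicit, unconditionally stable) |
| `oasense.snapshot` | Pe sweep → velocity-balance point → systematic-error decomposition |
| `oasense.doppler` | Two-depth Doppler intensity synthesis, artifact filtering, 0.1 Hz BFF series, moving average |
| `oasense.calibration` | Per-subject OLS calibration and one-hour monitoring without recalibration |
| `oasense.evaluation` | Bland–Altman, pooled combined-variance statistics, agreement regression, plots |
| `oasense.cohort` | Seeded six-subject synthetic cohort matching published per-subject summaries |
| `oasense.pipeline` | End-to-end synthesize → calibrate → monitor → evaluate run |
| `oasense.io`, `oasense.cli` | YAML/JSON configs, tidy CSV formats, `oasense` command-line interface |

## Worked example: the snapshot balance measurement

Sweep the externally applied orbital pressure Pe at a fixed true ICP of
20 mmHg, find the Pe at which the cycle-averaged IOA and EOA probe
velocities are equal, and decompose the systematic offset:

```python
import numpy as np
from oasense import (
    SimConfig, build_default_geometry, sweep_pe, find_balance_pe,
    balance_mean_flow, decompose_error,
)

geometry = build_default_geometry()
config = SimConfig()
sweep = sweep_pe(20.0, 4.0, np.arange(0.0, 35.0, 2.0), geometry, config)
balance = find_balance_pe(sweep)
dec = decompose_error(20.0, balance, 4.0, geometry,
                      balance_mean_flow(sweep, balance))
print(f"balance Pe*           = {balance:.2f} mmHg")
print(f"offset ICP - Pe*      = {dec.total_offset_mmhg:.2f} mmHg")
print(f"  intraorbital Pio    = {dec.pio_component_mmhg:.2f} mmHg")
print(f"  Poiseuille gradient = {dec.gradient_component_mmhg:.2f} mmHg")
print(f"  residual            = {dec.residual_mmhg:.2f} mmHg")
```

Output (runs in ≈ 5 s on one CPU):

```
balance Pe*           = 14.76 mmHg
offset ICP - Pe*      = 5.24 mmHg
  intraorbital Pio    = 4.00 mmHg
  Poiseuille gradient = 1.23 mmHg
  residual            = 0.01 mmHg
```

The offset of about 5–6 mmHg is almost entirely explained by the
intraorbital tissue pressure plus the viscous (Hagen–Poiseuille) pressure
drop between the two measurement depths; the unexplained patient-specific
residual is far below 1 mmHg. In practice both known components are
subtracted, so the snapshot estimate is `ICP ≈ Pe* + Pio + ΔP_HP`.

## Worked example: synthetic-cohort monitoring

```bash
oasense pipeline-demo --seed 0 --out demo/
```

```
n = 1928, pooled diff -0.036 ± 0.86 mmHg, r = 0.971
```

This synthesizes the default six-subject cohort (1928 paired 10-second
points in total), calibrates each subject on the first 30 pairs, monitors
the rest of each session without recalibration, and writes a paired CSV plus
a JSON agreement report (Bland–Altman, pooled statistics, regression).

Other CLI entry points: `oasense simulate-oa`, `oasense snapshot`,
`oasense bff`, `oasense monitor`, `oasense evaluate`, `oasense synth-cohort`.
Run any of them with `--help` for options.

## Reproduction

The quantitative claims the package reproduces, each covered by a dedicated
acceptance test in `tests/test_acceptance.py`:

1. **Pooled agreement arithmetic** — pooling the six published per-subject
   difference summaries gives N = 1928 pairs, mean 0.086 mmHg, SD 1.34 mmHg.
2. **Balance offset** — mean (ICP − Pe*) over ICP ∈ {10, 20, 30} mmHg is
   ≈ 6 mmHg (± 1) with Pio = 4 mmHg.
3. **Error decomposition** — the residual after removing Pio and the
   Poiseuille gradient is < 1 mmHg at every tested ICP.
4. **Gradient closure** — the simulated inter-probe pressure difference at
   balance (≈ 1.23 mmHg) agrees within 5% with the analytic
   Hagen–Poiseuille value (≈ 1.23 mmHg) at the same cycle-mean flow.
5. **Convergence protocol** — with a three-cycle ramped simulation, probe
   areas in cycles 2 and 3 differ by < 0.01%.
6. **Clinical-figure substitutes** — the raw patient data behind the
   clinical agreement figures are unavailable, so property-based substitutes
   check end-to-end synthetic-cohort recovery (calibration coefficients
   within 3 standard errors in the statistically consistent inverse
   parametrization, pooled statistics inside their analytic envelope,
   correlation r > 0.9).

To recompute all acceptance-target values from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes a JSON mapping of target ids (`t1`…`t8`) to `{"value": …,
"n": …}` in about 7 s. To run the test suite:

```bash
pytest -q
```

All simulations, sweeps and synthetic cohorts are deterministic given their
explicit seeds; the model defaults in `build_default_geometry()`,
`PressureLoad()` and `SimConfig()` are the canonical study conditions
documented in [docs/methods.md](docs/methods.md).

## Limitations

- The hemodynamic model is a 1-D cross-sectionally averaged reduction of a
  3-D fluid–structure-interaction problem; it reproduces cycle-averaged
  balance behavior, not detailed waveforms or wall mechanics.
- The synthetic cohort emulates published per-subject *summary* parameters
  (ICP range, calibration coefficients, difference SD, pair counts); the ICP
  trajectories themselves are an invented surrogate (bounded random walk
  plus a slow B-wave-like oscillation), not clinical recordings.
- Doppler intensities are synthesized as noisy area-proportional signals;
  no acoustic propagation or spectral processing is modeled.

See [docs/methods.md](docs/methods.md) for model equations, canonical
parameters, numerical choices, and generator limitations.
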