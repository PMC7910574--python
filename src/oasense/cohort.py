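"""Seeded synthetic patient cohort emulating the six-subject pilot study.

No raw clinical monitoring series are publicly available, so downstream
stages are exercised on a synthetic cohort whose published per-subject
parameters — invasive ICP range, calibration slope/intercept, difference-SD
and paired-point count — match the pilot study's summary table. The ICP
trajectory surrogate (bounded random walk plus a slow B-wave-like
oscillation) is invented plumbing: it reproduces the slow, strongly
autocorrelated character of ICP at 0.1 Hz, not any specific patient's
waveform.

Noise is injected additively in pressure units and mapped through 1/slope
into the BFF channel, so the per-subject invasive-vs-non-invasive difference
SD is directly controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import MonitoringSession
from .evaluation import GroupSummary

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "default_cohort",
    "pilot_difference_summaries",
    "generate_icp_trajectory",
    "generate_session",
    "generate_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Generating parameters for one synthetic subject.

    ``slope``/``intercept`` define the true BFF→ICP map (ICP = a·BFF + b);
    ``diff_sd_mmhg`` is the target SD of invasive-minus-non-invasive
    differences under the true calibration. Trajectory parameters default to
    fractions of the subject's ICP span.
    """

    subject_id: str
    icp_min_mmhg: float
    icp_max_mmhg: float
    slope: float
    intercept: float
    diff_sd_mmhg: float
    n_points: int
    walk_step_sd_mmhg: float | None = None
    bwave_amplitude_mmhg: float | None = None
    bwave_period_s: float | None = None  # drawn in [60, 180] s if None

    def __post_init__(self) -> None:
        if self.icp_min_mmhg >= self.icp_max_mmhg:
            raise ValueError("icp range must have min < max")
        if self.slope == 0:
            raise ValueError("true calibration slope must be non-zero")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.diff_sd_mmhg < 0:
            raise ValueError("difference SD must be non-negative")

    @property
    def span_mmhg(self) -> float:
        return self.icp_max_mmhg - self.icp_min_mmhg

    @property
    def duration_s(self) -> float:
        return (self.n_points - 1) * 10.0

    def with_(self, **kwargs) -> "SubjectProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """A list of subject profiles plus the master seed splitting policy."""

    subjects: tuple
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")


# Published per-subject summary of the six-patient pilot cohort:
# (ICP range min–max, calibration slope/intercept, difference mean ± SD, n).
_PILOT_ROWS = (
    ("1", 12.0, 22.0, 56.3, 10.1, 0.43, 0.91, 223),
    ("2", 16.0, 19.0, 263.8, 11.8, -0.22, 1.23, 360),
    ("3", 8.0, 11.0, 70.4, 6.2, -0.65, 1.07, 356),
    ("4", 10.0, 19.0, 218.9, 4.5, 1.61, 1.61, 280),
    ("5", 8.0, 10.0, 109.8, 3.8, 0.18, 0.64, 360),
    ("6", 13.0, 17.0, 586.2, 6.9, -0.39, 1.20, 349),
)


def default_cohort(master_seed: int = 0) -> CohortSpec:
    """The six-subject synthetic cohort mirroring the pilot study table."""
    subjects = tuple(
        SubjectProfile(
            subject_id=sid,
            icp_min_mmhg=lo,
            icp_max_mmhg=hi,
            slope=a,
            intercept=b,
            diff_sd_mmhg=sd,
            n_points=n,
        )
        for sid, lo, hi, a, b, _mean, sd, n in _PILOT_ROWS
    )
    return CohortSpec(subjects=subjects, master_seed=master_seed)


def pilot_difference_summaries() -> list[GroupSummary]:
    """The pilot study's printed per-subject difference summaries (mean, SD, n)."""
    return [
        GroupSummary(subject_id=sid, mean=m, sd=sd, n=n)
        for sid, _lo, _hi, _a, _b, m, sd, n in _PILOT_ROWS
    ]


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at both bounds."""
    span = hi - lo
    z = np.mod(values - lo, 2.0 * span)
    return lo + np.where(z > span, 2.0 * span - z, z)


def generate_icp_trajectory(profile: SubjectProfile, seed) -> np.ndarray:
    """Slow synthetic ICP trajectory (mmHg) at 0.1 Hz, length ``n_points``.

    Mid-range start + Gaussian random walk (drift) + a sinusoidal slow-wave
    (B-wave surrogate, period 1–3 min), reflected into the subject's ICP
    range. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = profile.n_points
    t = np.arange(n) * 10.0
    step = (
        profile.walk_step_sd_mmhg
        if profile.walk_step_sd_mmhg is not None
        else 0.03 * profile.span_mmhg
    )
    amp = (
        profile.bwave_amplitude_mmhg
        if profile.bwave_amplitude_mmhg is not None
        else 0.35 * profile.span_mmhg
    )
    period = (
        profile.bwave_period_s
        if profile.bwave_period_s is not None
        else float(rng.uniform(60.0, 180.0))
    )
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    mid = 0.5 * (profile.icp_min_mmhg + profile.icp_max_mmhg)
    walk = np.cumsum(rng.normal(0.0, step, size=n))
    raw = mid + walk + amp * np.sin(2.0 * np.pi * t / period + phase)
    return _reflect(raw, profile.icp_min_mmhg, profile.icp_max_mmhg)


def generate_session(profile: SubjectProfile, seed) -> MonitoringSession:
    """One synthetic monitoring session at strict 10 s spacing.

    ``bff(t) = (icp_true(t) − b)/a + η(t)/a`` with η zero-mean Gaussian of
    the profile's difference SD; the invasive channel records ``icp_true``
    exactly (reference-sensor noise is not modeled separately — it is folded
    into the difference SD).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    traj_seed, noise_seed = ss.spawn(2)
    icp_true = generate_icp_trajectory(profile, traj_seed)
    rng = np.random.default_rng(noise_seed)
    eta = rng.normal(0.0, profile.diff_sd_mmhg, size=profile.n_points)
    bff = (icp_true - profile.intercept) / profile.slope + eta / profile.slope
    return MonitoringSession(
        subject_id=profile.subject_id,
        time_s=np.arange(profile.n_points) * 10.0,
        icp_inv_mmhg=icp_true,
        bff=bff,
    )


def generate_cohort(spec: CohortSpec) -> list[MonitoringSession]:
    """Generate all sessions with per-subject seeds split from the master seed."""
    children = np.random.SeedSequence(spec.master_seed).spawn(len(spec.subjects))
    return [
        generate_session(profile, child)
        for profile, child in zip(spec.subjects, children)
    ]
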