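"""Two-depth Doppler intensity synthesis and the blood flow factor (BFF).

The two-depth transcranial Doppler insonates the intracranial (IOA) and
extracranial (EOA) ophthalmic-artery segments simultaneously. The received
signal intensity from each depth scales with the insonated lumen
cross-section, so the *blood flow factor*

    BFF = (1 / T_w) ∫ ln( Ps_ioa(t) / Ps_eoa(t) ) dt

over a 10 s window compares the compression states of the two segments in a
gain-free way: any multiplicative channel gain cancels in the log ratio, and
any residual affine ambiguity is absorbed by the per-subject linear
calibration downstream. One BFF value per window gives the 0.1 Hz monitoring
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "DopplerTrace",
    "BFFSeries",
    "synthesize_intensity",
    "synthesize_trace",
    "compute_bff",
    "artifact_filter",
    "moving_average",
]


@dataclass
class DopplerTrace:
    """Paired IOA/EOA Doppler-intensity time series (arbitrary linear units)."""

    fs_hz: float
    ps_ioa: np.ndarray
    ps_eoa: np.ndarray
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ps_ioa = np.asarray(self.ps_ioa, dtype=float)
        self.ps_eoa = np.asarray(self.ps_eoa, dtype=float)
        if self.ps_ioa.shape != self.ps_eoa.shape or self.ps_ioa.ndim != 1:
            raise ValueError("channels must be 1-D arrays of equal length")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.valid is None:
            self.valid = np.ones(self.ps_ioa.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.ps_ioa.shape:
                raise ValueError("validity mask shape mismatch")
        both = np.concatenate([self.ps_ioa[self.valid], self.ps_eoa[self.valid]])
        if both.size and np.any(both <= 0):
            raise ValueError("valid intensity samples must be strictly positive")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.ps_ioa)) / self.fs_hz


@dataclass
class BFFSeries:
    """0.1 Hz blood-flow-factor series with artifact mask."""

    time_s: np.ndarray
    bff: np.ndarray
    valid: np.ndarray
    window_s: float = 10.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bff = np.asarray(self.bff, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time_s.shape == self.bff.shape == self.valid.shape):
            raise ValueError("inconsistent series shapes")
        if len(self.time_s) > 1 and not np.allclose(
            np.diff(self.time_s), self.window_s
        ):
            raise ValueError("timestamps must be spaced by the window length")


def synthesize_intensity(area_series, gain: float, noise_sd_fraction: float, seed):
    """Synthetic Doppler intensity from a lumen-area series.

    ``Ps(t) = gain · A(t) · (1 + ε(t))`` with ε zero-mean Gaussian of the
    given fractional SD, truncated (clipped) just above −1 so intensities
    stay positive. Deterministic given the seed.
    """
    area = np.asarray(area_series, dtype=float)
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if noise_sd_fraction < 0:
        raise ValueError("noise SD fraction must be non-negative")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd_fraction, size=area.shape) if noise_sd_fraction else 0.0
    return gain * area * np.clip(1.0 + eps, 1e-6, None)


def synthesize_trace(
    area_ioa,
    area_eoa,
    fs_hz: float,
    gain_ioa: float = 1.0,
    gain_eoa: float = 1.0,
    noise_sd_fraction: float = 0.0,
    seed=None,
) -> DopplerTrace:
    """Convenience: build a two-channel trace from two area series."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    return DopplerTrace(
        fs_hz=fs_hz,
        ps_ioa=synthesize_intensity(area_ioa, gain_ioa, noise_sd_fraction, s1),
        ps_eoa=synthesize_intensity(area_eoa, gain_eoa, noise_sd_fraction, s2),
        meta={
            "gain_ioa": gain_ioa,
            "gain_eoa": gain_eoa,
            "noise_sd_fraction": noise_sd_fraction,
            "seed": repr(seed),
        },
    )


def compute_bff(trace: DopplerTrace, window_s: float = 10.0) -> BFFSeries:
    """Windowed time-normalized log-intensity-ratio → 0.1 Hz BFF series.

    Per non-overlapping window: trapezoidal quadrature of
    ``ln(Ps_ioa / Ps_eoa)`` over the window's valid samples, divided by the
    integration span. Windows with under 50% valid samples are emitted masked
    rather than raising.
    """
    n_win = int(round(window_s * trace.fs_hz))
    if n_win < 2:
        raise ValueError("window too short for the sampling rate")
    n = len(trace.ps_ioa)
    if n < n_win:
        raise ValueError("trace shorter than one window")
    n_out = n // n_win
    t = trace.time_s
    log_ratio = np.full(n, np.nan)
    log_ratio[trace.valid] = np.log(
        trace.ps_ioa[trace.valid] / trace.ps_eoa[trace.valid]
    )

    times = np.empty(n_out)
    values = np.full(n_out, np.nan)
    ok = np.zeros(n_out, dtype=bool)
    for w in range(n_out):
        sl = slice(w * n_win, (w + 1) * n_win)
        times[w] = t[sl.start]
        v = trace.valid[sl]
        if v.sum() < 0.5 * n_win or v.sum() < 2:
            continue
        tw, yw = t[sl][v], log_ratio[sl][v]
        values[w] = np.trapezoid(yw, tw) / (tw[-1] - tw[0])
        ok[w] = True
    return BFFSeries(time_s=times, bff=values, valid=ok, window_s=window_s)


def artifact_filter(
    trace: DopplerTrace,
    spike_z: float = 5.0,
    dropout_floor_fraction: float = 0.05,
    rolling_window_s: float = 1.0,
) -> DopplerTrace:
    """Mask dropout and spike artifacts in both channels.

    A sample is invalidated when, in either channel, it falls below
    ``dropout_floor_fraction`` × the channel median (probe lift-off /
    dropout) or deviates more than ``spike_z`` robust SDs (1.4826 × MAD)
    from a rolling median (motion/speckle spikes). Returns a new trace with
    the tightened mask; ``meta["artifact_samples_removed"]`` counts newly
    masked samples.
    """
    n_roll = max(3, int(round(rolling_window_s * trace.fs_hz)) | 1)  # odd
    bad = np.zeros(len(trace.ps_ioa), dtype=bool)
    for ch in (trace.ps_ioa, trace.ps_eoa):
        med = np.median(ch[trace.valid]) if trace.valid.any() else np.median(ch)
        rolling = median_filter(ch, size=n_roll, mode="nearest")
        resid = ch - rolling
        mad = np.median(np.abs(resid[trace.valid])) if trace.valid.any() else 0.0
        robust_sd = 1.4826 * mad
        bad |= ch < dropout_floor_fraction * med
        if robust_sd > 0:
            bad |= np.abs(resid) > spike_z * robust_sd
    new_valid = trace.valid & ~bad
    meta = dict(trace.meta)
    meta["artifact_samples_removed"] = int((trace.valid & bad).sum())
    return DopplerTrace(
        fs_hz=trace.fs_hz,
        ps_ioa=trace.ps_ioa,
        ps_eoa=trace.ps_eoa,
        valid=new_valid,
        meta=meta,
    )


def moving_average(values, sample_spacing_s: float, window_s: float = 60.0, valid=None):
    """Centered moving mean over valid samples; edges use the partial window.

    Returns ``(smoothed, valid_out)``. Output samples are invalid where the
    input was invalid or no valid neighbor falls in the window; elsewhere the
    mean is taken over the valid samples inside the centered window.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if sample_spacing_s <= 0 or window_s <= 0:
        raise ValueError("spacing and window must be positive")
    v = np.ones(x.shape, bool) if valid is None else np.asarray(valid, dtype=bool)
    half = int(round(window_s / 2.0 / sample_spacing_s))
    kernel = np.ones(2 * half + 1)
    xv = np.where(v, x, 0.0)
    num = np.convolve(xv, kernel, mode="same")
    den = np.convolve(v.astype(float), kernel, mode="same")
    out = np.full(x.shape, np.nan)
    has = den > 0
    out[has] = num[has] / den[has]
    valid_out = v & has
    out[~valid_out] = np.nan
    return out, valid_out
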