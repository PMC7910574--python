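"""Per-subject linear BFF→ICP calibration and continuous monitoring.

The monitoring signal (BFF) is mapped to pressure units by a per-subject
linear calibration ``ICP = a·BFF + b`` fitted against reference invasive ICP
readings at the start of a session; the session then runs without
recalibration. Because the calibration is affine, any affine renormalization
of the BFF statistic leaves the calibrated ICP estimates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .doppler import moving_average
from .errors import CalibrationError

__all__ = [
    "CalibrationModel",
    "MonitoringSession",
    "ICPEstimateSeries",
    "MonitoringResult",
    "fit_calibration",
    "fit_session_calibration",
    "apply_calibration",
    "run_monitoring",
]

SESSION_SPACING_S = 10.0
MAX_SESSION_S = 3600.0


@dataclass(frozen=True)
class CalibrationModel:
    """Per-subject linear map from mean-window BFF to ICP (mmHg)."""

    slope: float
    intercept: float
    n_points: int
    residual_sd_mmhg: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration coefficients must be finite")

    def predict(self, bff):
        return self.slope * np.asarray(bff, dtype=float) + self.intercept


@dataclass
class MonitoringSession:
    """One subject's paired invasive-ICP / BFF monitoring records at 0.1 Hz."""

    subject_id: str
    time_s: np.ndarray
    icp_inv_mmhg: np.ndarray
    bff: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.icp_inv_mmhg = np.asarray(self.icp_inv_mmhg, dtype=float)
        self.bff = np.asarray(self.bff, dtype=float)
        n = len(self.time_s)
        if not (len(self.icp_inv_mmhg) == len(self.bff) == n):
            raise ValueError("session columns must have equal length")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if n > 1 and not np.allclose(np.diff(self.time_s), SESSION_SPACING_S):
            raise ValueError("session must be sampled at strict 10 s steps")
        if self.duration_s > MAX_SESSION_S + SESSION_SPACING_S:
            raise ValueError("session exceeds the 1 h no-recalibration window")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self.time_s) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time_s": self.time_s,
                "icp_inv_mmhg": self.icp_inv_mmhg,
                "bff": self.bff,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class ICPEstimateSeries:
    """Calibrated non-invasive ICP estimates (mmHg)."""

    time_s: np.ndarray
    icp_noninv_mmhg: np.ndarray
    valid: np.ndarray
    model: CalibrationModel
    smoothed: bool = False


@dataclass
class MonitoringResult:
    """Aligned invasive/non-invasive pairs plus summary statistics."""

    pairs: pd.DataFrame  # time_s, icp_inv_mmhg, icp_noninv_mmhg, diff_mmhg
    model: CalibrationModel
    summary: dict


def fit_calibration(bff_values, icp_ref_values, timestamp_s: float = 0.0) -> CalibrationModel:
    """Ordinary least squares of reference ICP on BFF.

    Raises :class:`CalibrationError` for fewer than two points or a constant
    BFF regressor (uncalibratable).
    """
    x = np.asarray(bff_values, dtype=float)
    y = np.asarray(icp_ref_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("bff and icp arrays must be 1-D of equal length")
    if len(x) < 2:
        raise CalibrationError("need at least 2 calibration points")
    if np.ptp(x) == 0:
        raise CalibrationError("uncalibratable: constant BFF in calibration window")
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return CalibrationModel(slope, intercept, 2, 0.0, timestamp_s)
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    dof = len(x) - 2
    residual_sd = float(np.sqrt(np.sum((y - fitted) ** 2) / dof))
    return CalibrationModel(
        float(res.slope), float(res.intercept), len(x), residual_sd, timestamp_s
    )


def fit_session_calibration(
    session: MonitoringSession, n_points: int = 30
) -> CalibrationModel:
    """Calibrate on the first ``n_points`` valid pairs of a session (5 min at
    the default 30 points)."""
    idx = np.nonzero(session.valid)[0][:n_points]
    if idx.size < 2:
        raise CalibrationError("not enough valid points to calibrate")
    return fit_calibration(
        session.bff[idx],
        session.icp_inv_mmhg[idx],
        timestamp_s=float(session.time_s[idx[-1]]),
    )


def apply_calibration(model: CalibrationModel, bff_series) -> ICPEstimateSeries:
    """Map a BFF series (BFFSeries or array-like) through the linear model."""
    if hasattr(bff_series, "bff"):
        time_s = np.asarray(bff_series.time_s, float)
        values = np.asarray(bff_series.bff, float)
        valid = np.asarray(bff_series.valid, bool)
    else:
        values = np.asarray(bff_series, dtype=float)
        time_s = np.arange(len(values)) * SESSION_SPACING_S
        valid = np.isfinite(values)
    icp = np.full(values.shape, np.nan)
    icp[valid] = model.predict(values[valid])
    return ICPEstimateSeries(time_s=time_s, icp_noninv_mmhg=icp, valid=valid, model=model)


def run_monitoring(
    session: MonitoringSession,
    model: CalibrationModel,
    smooth_window_s: float = 60.0,
    smooth: bool = True,
) -> MonitoringResult:
    """Apply a calibration across a session and pair with the invasive record.

    With ``smooth=True`` (the display convention) BOTH series are passed
    through the same centered moving average before pairing, so smoothing
    never biases the comparison; statistics intended for Bland–Altman input
    are conventionally computed unsmoothed (``smooth=False``).
    """
    valid = session.valid & np.isfinite(session.bff)
    if not valid.any():
        raise ValueError("session has no valid records")
    est = apply_calibration(model, session.bff)
    inv = session.icp_inv_mmhg.astype(float)
    noninv = est.icp_noninv_mmhg
    pair_valid = valid & est.valid
    if smooth:
        inv, v1 = moving_average(inv, SESSION_SPACING_S, smooth_window_s, pair_valid)
        noninv, v2 = moving_average(
            noninv, SESSION_SPACING_S, smooth_window_s, pair_valid
        )
        pair_valid = v1 & v2
    diff = inv - noninv
    pairs = pd.DataFrame(
        {
            "time_s": session.time_s,
            "icp_inv_mmhg": inv,
            "icp_noninv_mmhg": noninv,
            "diff_mmhg": diff,
            "valid": pair_valid.astype(int),
        }
    )[pair_valid]
    d = pairs["diff_mmhg"].to_numpy()
    summary = {
        "subject_id": session.subject_id,
        "n": int(len(d)),
        "mean_diff_mmhg": float(np.mean(d)),
        "sd_diff_mmhg": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        "mean_abs_diff_mmhg": float(np.mean(np.abs(d))),
        "max_abs_diff_mmhg": float(np.max(np.abs(d))),
        "smoothed": bool(smooth),
    }
    return MonitoringResult(pairs=pairs.reset_index(drop=True), model=model, summary=summary)
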