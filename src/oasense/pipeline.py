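"""End-to-end cohort pipeline: synthesize → calibrate → monitor → evaluate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    MonitoringResult,
    fit_session_calibration,
    run_monitoring,
)
from .cohort import CohortSpec, generate_cohort
from .evaluation import (
    AgreementRegression,
    BlandAltmanResult,
    GroupSummary,
    agreement_regression,
    bland_altman,
    pooled_stats,
)

__all__ = ["CohortRun", "run_cohort_pipeline"]


@dataclass
class CohortRun:
    """Results of one full synthetic-cohort monitoring experiment."""

    models: dict[str, CalibrationModel]
    monitoring: dict[str, MonitoringResult]
    group_summaries: list[GroupSummary]
    pooled_mean_mmhg: float
    pooled_sd_mmhg: float
    n_pairs: int
    bland_altman: BlandAltmanResult
    regression: AgreementRegression

    def pairs_frame(self) -> pd.DataFrame:
        frames = []
        for sid, res in self.monitoring.items():
            df = res.pairs.copy()
            df.insert(0, "subject_id", sid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def report(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "pooled_mean_mmhg": self.pooled_mean_mmhg,
            "pooled_sd_mmhg": self.pooled_sd_mmhg,
            "bland_altman": vars(self.bland_altman).copy(),
            "regression": vars(self.regression).copy(),
            "per_subject": {
                sid: res.summary for sid, res in self.monitoring.items()
            },
            "calibration": {
                sid: {
                    "slope": m.slope,
                    "intercept": m.intercept,
                    "n_points": m.n_points,
                    "residual_sd_mmhg": m.residual_sd_mmhg,
                }
                for sid, m in self.models.items()
            },
        }


def run_cohort_pipeline(
    spec: CohortSpec,
    calib_points: int = 30,
    smooth: bool = False,
    exclude_calibration_window: bool = False,
) -> CohortRun:
    """Run the full monitoring pipeline over a synthetic cohort.

    Each subject is calibrated on the session's first ``calib_points`` valid
    pairs and then monitored across the whole session without recalibration
    (the calibration window stays in the comparison unless
    ``exclude_calibration_window``). Statistics are computed on unsmoothed
    pairs by default, matching the Bland–Altman input convention.
    """
    sessions = generate_cohort(spec)
    models: dict = {}
    monitoring: dict = {}
    groups: list[GroupSummary] = []
    inv_all, non_all = [], []
    for session in sessions:
        model = fit_session_calibration(session, n_points=calib_points)
        if exclude_calibration_window:
            keep = np.ones(len(session.time_s), dtype=bool)
            keep[np.nonzero(session.valid)[0][:calib_points]] = False
            session = MonitoringSessionView(session, keep)
        result = run_monitoring(session, model, smooth=smooth)
        models[result.summary["subject_id"]] = model
        monitoring[result.summary["subject_id"]] = result
        groups.append(
            GroupSummary(
                subject_id=result.summary["subject_id"],
                mean=result.summary["mean_diff_mmhg"],
                sd=result.summary["sd_diff_mmhg"],
                n=result.summary["n"],
            )
        )
        inv_all.append(result.pairs["icp_inv_mmhg"].to_numpy())
        non_all.append(result.pairs["icp_noninv_mmhg"].to_numpy())

    inv = np.concatenate(inv_all)
    non = np.concatenate(non_all)
    mean, sd, n = pooled_stats(groups)
    return CohortRun(
        models=models,
        monitoring=monitoring,
        group_summaries=groups,
        pooled_mean_mmhg=mean,
        pooled_sd_mmhg=sd,
        n_pairs=n,
        bland_altman=bland_altman(inv, non),
        regression=agreement_regression(inv, non),
    )


def MonitoringSessionView(session, keep):
    """Restrict a session to a boolean subset by masking validity."""
    from .calibration import MonitoringSession

    return MonitoringSession(
        subject_id=session.subject_id,
        time_s=session.time_s,
        icp_inv_mmhg=session.icp_inv_mmhg,
        bff=session.bff,
        valid=session.valid & keep,
    )
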