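"""Method-comparison statistics for paired invasive / non-invasive ICP data.

Bland–Altman agreement analysis (differences fixed as invasive minus
non-invasive), pooled cross-subject summaries via the combined-variance
identity, and a linear agreement regression testing the ophthalmic artery's
linearity as a pressure sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "GroupSummary",
    "AgreementRegression",
    "bland_altman",
    "pooled_stats",
    "agreement_regression",
    "plot_bland_altman",
    "plot_agreement",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman summary of paired differences (all pressures in mmHg).

    Limits of agreement are the parametric mean ± 1.96·SD; the empirical
    2.5th/97.5th percentiles are reported alongside since with non-Gaussian
    differences the two need not coincide.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    min_diff: float
    max_diff: float
    pct_2_5: float
    pct_97_5: float


@dataclass(frozen=True)
class GroupSummary:
    """Per-subject difference summary (mean, SD, count)."""

    subject_id: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class AgreementRegression:
    """OLS of non-invasive on invasive ICP plus Pearson correlation."""

    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def bland_altman(icp_inv, icp_noninv) -> BlandAltmanResult:
    """Bland–Altman statistics on paired series (difference = inv − noninv)."""
    a = np.asarray(icp_inv, dtype=float)
    b = np.asarray(icp_noninv, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D and equally long")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = np.percentile(d, [2.5, 97.5])
    return BlandAltmanResult(
        n=len(d),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        min_diff=float(np.min(d)),
        max_diff=float(np.max(d)),
        pct_2_5=float(lo),
        pct_97_5=float(hi),
    )


def pooled_stats(groups) -> tuple[float, float, int]:
    """Pool per-group (mean, SD, n) into overall mean, SD and N.

    Uses the exact combined-variance identity

        SD² = [ Σ (nᵢ−1)·sdᵢ² + Σ nᵢ·(meanᵢ − mean)² ] / (N − 1),

    which reproduces the direct sample statistics of the concatenated data.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one group")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    N = n.sum()
    mean = float(np.sum(n * m) / N)
    if N < 2:
        return mean, 0.0, int(N)
    ss = np.sum((n - 1) * s**2) + np.sum(n * (m - mean) ** 2)
    return mean, float(np.sqrt(ss / (N - 1))), int(N)


def agreement_regression(icp_inv, icp_noninv) -> AgreementRegression:
    """Fit icp_noninv = slope·icp_inv + intercept and report Pearson r."""
    x = np.asarray(icp_inv, dtype=float)
    y = np.asarray(icp_noninv, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired series must be 1-D and equally long")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for the regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the invasive series")
    res = stats.linregress(x, y)
    return AgreementRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Plots (thin matplotlib wrappers used by the CLI)
# ---------------------------------------------------------------------------

def plot_bland_altman(pairs_by_subject: dict, path=None, ax=None):
    """Bland–Altman scatter, one color per subject.

    ``pairs_by_subject`` maps subject id → (icp_inv, icp_noninv) arrays.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    all_inv, all_non = [], []
    for sid, (inv, non) in pairs_by_subject.items():
        inv = np.asarray(inv, float)
        non = np.asarray(non, float)
        ax.scatter((inv + non) / 2, inv - non, s=6, label=str(sid), alpha=0.6)
        all_inv.append(inv)
        all_non.append(non)
    res = bland_altman(np.concatenate(all_inv), np.concatenate(all_non))
    ax.axhline(res.mean_diff, color="k", lw=1.5)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of ICP$_{inv}$ and ICP$_{non-inv}$ (mmHg)")
    ax.set_ylabel("ICP$_{inv}$ − ICP$_{non-inv}$ (mmHg)")
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_agreement(pairs_by_subject: dict, path=None, ax=None):
    """Regression scatter of non-invasive on invasive ICP, colored by subject."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    all_inv, all_non = [], []
    for sid, (inv, non) in pairs_by_subject.items():
        ax.scatter(inv, non, s=6, label=str(sid), alpha=0.6)
        all_inv.append(np.asarray(inv, float))
        all_non.append(np.asarray(non, float))
    x = np.concatenate(all_inv)
    reg = agreement_regression(x, np.concatenate(all_non))
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, reg.slope * xs + reg.intercept, "k-", lw=1.5,
            label=f"y = {reg.slope:.2f}x + {reg.intercept:.2f} (r = {reg.r:.2f})")
    ax.set_xlabel("ICP$_{inv}$ (mmHg)")
    ax.set_ylabel("ICP$_{non-inv}$ (mmHg)")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
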