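"""Method-agreement statistics: Bland-Altman analysis, predicted-vs-true
linear regression, and the paired two-sided Student t-test.

Sign convention: differences are predicted - reference, so a negative bias
means the method underestimates.  Limits of agreement use the standard
bias +/- 1.96 * SD with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "AgreementReport",
    "bland_altman",
    "linfit",
    "paired_t",
    "agreement_report",
    "bland_altman_plot",
    "scatter_plot",
]


@dataclass
class AgreementReport:
    """Bland-Altman summary plus optional regression / paired-t fields (mm)."""

    bias: float
    loa_low: float
    loa_high: float
    n_outliers: int
    n_total: int
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    t_p_value: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _paired(pred: Sequence[float], gt: Sequence[float], n_min: int) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.ndim != 1 or p.shape != g.shape:
        raise InvalidInputError(f"inputs must be equal-length 1-D, got {p.shape} vs {g.shape}")
    if p.size < n_min:
        raise InsufficientDataError(f"need at least {n_min} paired observations, got {p.size}")
    return p, g


def bland_altman(pred: Sequence[float], gt: Sequence[float]) -> AgreementReport:
    """Bias, 95% limits of agreement, and count of points strictly outside them."""
    p, g = _paired(pred, gt, 3)
    diffs = p - g
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = int(((diffs < lo) | (diffs > hi)).sum())
    return AgreementReport(
        bias=bias, loa_low=lo, loa_high=hi, n_outliers=outliers, n_total=int(p.size)
    )


def linfit(pred: Sequence[float], gt: Sequence[float]) -> tuple[float, float, float]:
    """OLS of predictions on reference values: (slope, intercept, r^2)."""
    p, g = _paired(pred, gt, 3)
    if np.ptp(g) == 0:
        raise InvalidInputError("reference values are all equal; regression undefined")
    res = stats.linregress(g, p)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def paired_t(errors_a: Sequence[float], errors_b: Sequence[float]) -> float:
    """Two-sided paired Student t-test p-value on (a - b).

    Degenerate conventions: all differences zero -> p = 1 (no evidence of a
    difference); constant nonzero differences (zero variance, nonzero mean)
    -> p = 0 (infinite t statistic).
    """
    a, b = _paired(errors_a, errors_b, 3)
    d = a - b
    if np.all(d == d[0]):
        return 1.0 if d[0] == 0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def agreement_report(
    pred: Sequence[float],
    gt: Sequence[float],
    other_errors: Sequence[float] | None = None,
) -> AgreementReport:
    """Full agreement summary for one method's predictions.

    If ``other_errors`` (per-case absolute errors of a competing method) is
    given, a paired t-test against this method's absolute errors is added.
    """
    rep = bland_altman(pred, gt)
    rep.slope, rep.intercept, rep.r2 = linfit(pred, gt)
    if other_errors is not None:
        own = np.abs(np.asarray(pred, float) - np.asarray(gt, float))
        rep.t_p_value = paired_t(own, other_errors)
    return rep


def bland_altman_plot(pred: Sequence[float], gt: Sequence[float], path: str) -> None:
    """Scatter of differences vs. means with bias and 95% limits, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(pred, float)
    g = np.asarray(gt, float)
    rep = bland_altman(p, g)
    mean = (p + g) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, p - g, s=12, alpha=0.7)
    ax.axhline(rep.bias, color="green", ls=":", label=f"bias {rep.bias:.2f} mm")
    for y in (rep.loa_low, rep.loa_high):
        ax.axhline(y, color="red", ls="-", lw=1)
    ax.set_xlabel("mean of predicted and reference HC (mm)")
    ax.set_ylabel("predicted - reference HC (mm)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(pred: Sequence[float], gt: Sequence[float], path: str) -> None:
    """Predicted vs. reference HC with the identity line, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(pred, float)
    g = np.asarray(gt, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(g, p, s=12, alpha=0.7)
    lims = [min(g.min(), p.min()), max(g.max(), p.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("reference HC (mm)")
    ax.set_ylabel("predicted HC (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
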