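"""Bland-Altman agreement between paired angle measurements.

Classical construction: pairwise differences ``d = a - b`` are summarized by
their mean (bias), sample standard deviation (n-1 denominator), and limits of
agreement at mean +/- 1.96 SD. Because quartile conventions differ between
reports, the interquartile range of the differences (linear-interpolation
quantiles) is emitted alongside the limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, InsufficientDataError

__all__ = ["BlandAltmanResult", "bland_altman", "error_summary", "plot_bland_altman"]

LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    """Agreement summary plus the (mean, difference) pairs for plotting."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    q1_diff: float
    q3_diff: float
    outside_loa: int
    means: np.ndarray
    diffs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "q1_diff": self.q1_diff,
            "q3_diff": self.q3_diff,
            "outside_loa": self.outside_loa,
        }


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractViolationError("inputs must be 1D lists of equal length")
    if a.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {a.size}")
    return a, b


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman statistics for subject-aligned pairs (a, b).

    Differences are ``a - b``; limits of agreement are
    ``mean_diff +/- 1.96 * sd_diff`` with the sample (n-1) SD.
    """
    a, b = _paired(a, b)
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa_low = mean_diff - LOA_MULTIPLIER * sd_diff
    loa_high = mean_diff + LOA_MULTIPLIER * sd_diff
    outside = int(np.sum((diffs < loa_low) | (diffs > loa_high)))
    return BlandAltmanResult(
        n=int(a.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        q1_diff=float(np.quantile(diffs, 0.25)),
        q3_diff=float(np.quantile(diffs, 0.75)),
        outside_loa=outside,
        means=means,
        diffs=diffs,
    )


def error_summary(pred, manual) -> tuple[float, float, float]:
    """Mean and quartiles (Q1, Q3) of ``pred - manual``.

    Quartiles use linear interpolation between order statistics.
    """
    pred, manual = _paired(pred, manual)
    diffs = pred - manual
    return (
        float(diffs.mean()),
        float(np.quantile(diffs, 0.25)),
        float(np.quantile(diffs, 0.75)),
    )


def plot_bland_altman(result: BlandAltmanResult, path=None, ax=None, title: str | None = None):
    """Scatter of differences vs means with bias and limits-of-agreement lines."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.8)
    ax.axhline(result.mean_diff, color="k", lw=1.2, label=f"bias {result.mean_diff:.2f}")
    for y, name in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="r", ls="--", lw=1.0, label=f"{name} {y:.2f}")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
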