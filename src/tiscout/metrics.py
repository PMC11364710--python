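"""Agreement statistics between predicted and ground-truth inversion times.

The battery: accuracy within a tolerance (default 50 ms), MAE/MSE, Lin's
concordance correlation coefficient, Bland-Altman bias and 95% limits of
agreement, reduced major axis regression (RMAR), and a 2-D concordance
histogram in 25-ms bins.

Conventions, stated once and used everywhere:

* Bland-Altman differences are prediction - truth, so a positive bias means
  the method overestimates the inversion time.
* LCCC uses population (1/n) moments, Lin's original definition.
* Bland-Altman uses the sample (1/(n-1)) standard deviation.
* RMAR's slope is the sign-adjusted ratio of standard deviations, for which
  the moment convention cancels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "AgreementReport",
    "ConcordanceHistogram",
    "accuracy_within",
    "mae_mse",
    "lccc",
    "bland_altman",
    "rmar",
    "concordance_histogram",
    "evaluate",
]


def _paired(pred, truth, min_n=1):
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {truth.size} truths")
    if pred.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {pred.size}")
    return pred, truth


def accuracy_within(pred, truth, threshold: float = 50.0) -> float:
    """Percentage of predictions within ``threshold`` ms of truth (inclusive)."""
    pred, truth = _paired(pred, truth)
    return 100.0 * float(np.mean(np.abs(pred - truth) <= threshold))


def mae_mse(pred, truth) -> tuple[float, float]:
    """Mean absolute error (ms) and mean squared error (ms^2)."""
    pred, truth = _paired(pred, truth)
    d = pred - truth
    return float(np.mean(np.abs(d))), float(np.mean(d * d))


def lccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments):

        2 cov(x, y) / (var x + var y + (mean x - mean y)^2)
    """
    x, y = _paired(x, y, min_n=2)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # both constant and equal: perfect (degenerate) agreement
    return float(2 * cov / denom)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement for d = y - x
    (prediction minus truth): (mean d, mean d - 1.96 sd, mean d + 1.96 sd)."""
    x, y = _paired(x, y, min_n=2)
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def rmar(x, y) -> tuple[float, float]:
    """Reduced major axis regression of prediction ``y`` on truth ``x``:
    slope = sign(r) * sd(y)/sd(x), intercept = mean(y) - slope * mean(x)."""
    x, y = _paired(x, y, min_n=2)
    sx, sy = x.std(), y.std()
    if sx == 0:
        raise ValueError("degenerate input: truth values have zero variance")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    sign = 1.0 if cov >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept


@dataclass(frozen=True)
class ConcordanceHistogram:
    """2-D counts of (truth, prediction) pairs over half-open ms bins."""

    bin_width: float
    truth_edges: np.ndarray
    pred_edges: np.ndarray
    counts: np.ndarray  # (n_truth_bins, n_pred_bins)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def concordance_histogram(pred, truth, bin_width: float = 25.0) -> ConcordanceHistogram:
    """Bin predictions against truth in half-open intervals [k w, (k+1) w);
    a value exactly on an edge goes to the upper bin."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pred, truth = _paired(pred, truth)
    ti_bins = np.floor(truth / bin_width).astype(int)
    pi_bins = np.floor(pred / bin_width).astype(int)
    t0, t1 = ti_bins.min(), ti_bins.max()
    p0, p1 = pi_bins.min(), pi_bins.max()
    counts = np.zeros((t1 - t0 + 1, p1 - p0 + 1), dtype=int)
    np.add.at(counts, (ti_bins - t0, pi_bins - p0), 1)
    return ConcordanceHistogram(
        bin_width=float(bin_width),
        truth_edges=bin_width * np.arange(t0, t1 + 2, dtype=float),
        pred_edges=bin_width * np.arange(p0, p1 + 2, dtype=float),
        counts=counts,
    )


@dataclass(frozen=True)
class AgreementReport:
    """The full agreement battery for one prediction/truth pairing."""

    accuracy_within_threshold: float
    threshold: float
    mae: float
    mse: float
    lccc: float
    ba_mean: float
    ba_lo: float
    ba_hi: float
    rmar_slope: float
    rmar_intercept: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(**d)


def evaluate(pred, truth, threshold: float = 50.0) -> AgreementReport:
    """Assemble every agreement statistic into one report."""
    pred, truth = _paired(pred, truth, min_n=2)
    mae, mse = mae_mse(pred, truth)
    ba_mean, ba_lo, ba_hi = bland_altman(truth, pred)  # prediction - truth
    slope, intercept = rmar(truth, pred)
    return AgreementReport(
        accuracy_within_threshold=accuracy_within(pred, truth, threshold),
        threshold=float(threshold),
        mae=mae,
        mse=mse,
        lccc=lccc(truth, pred),
        ba_mean=ba_mean,
        ba_lo=ba_lo,
        ba_hi=ba_hi,
        rmar_slope=slope,
        rmar_intercept=intercept,
        n=int(pred.size),
    )
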