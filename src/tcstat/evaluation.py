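"""Scoring inference output against a putative ground truth.

A putative ground truth is a per-node effect-size map (Cohen's d)
discretized at a binarization threshold into positive, negative and
null nodes.  Sensitivity is the proportion of repeated inferences in
which a node was detected inside a significant cluster with the correct
sign.  Classifier quality is summarized by bookmaker informedness
``BM = TPR + TNR - 1`` (chance level 0, perfect 1, total inversion -1),
optionally aggregated over a range of binarization thresholds by a
normalized partial area under the curve.  Analytic power bounds for the
underlying one-sample t test (uncorrected and Bonferroni-corrected)
frame the attainable sensitivity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

__all__ = [
    "GroundTruth",
    "ConfusionSummary",
    "PowerCurve",
    "PowerBound",
    "sensitivity_map",
    "power_curve",
    "informedness",
    "informedness_curve",
    "analytic_power_bounds",
    "minimal_detectable_d",
]

DEFAULT_THRESHOLD_RANGE = (0.06, 0.16)


@dataclass
class GroundTruth:
    """Per-node effect sizes with a binarization threshold.

    ``sign`` is +/-1 where ``|d| >= threshold`` (matching d's sign) and
    0 elsewhere -- a pure function of (d, threshold).
    """

    d: np.ndarray
    threshold: float

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    @property
    def sign(self):
        return (np.sign(self.d) * (np.abs(self.d) >= self.threshold)).astype(np.int8)

    @property
    def n_nodes(self):
        return self.d.size

    def at_threshold(self, threshold):
        return GroundTruth(self.d, threshold)


def _predicted_sign(result):
    """Accept an InferenceResult/Results wrapper or a raw sign array."""
    if hasattr(result, "predicted_sign"):
        return np.asarray(result.predicted_sign())
    return np.asarray(result)


def sensitivity_map(results, truth):
    """Per-node detection rate across repetitions, sign-checked.

    ``power(i)`` = fraction of repetitions in which node ``i`` lies in a
    significant cluster whose sign agrees with the ground-truth sign.
    For truth-null nodes (sign 0) the returned value is the rate of
    *any*-sign detection, i.e. the node-level false-positive rate.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    ts = truth.sign
    acc = np.zeros(truth.n_nodes)
    for r in results:
        pred = _predicted_sign(r)
        if pred.size != truth.n_nodes:
            raise ValueError("result / truth dimension mismatch")
        acc += np.where(ts != 0, pred == ts, pred != 0)
    return acc / len(results)


@dataclass
class PowerCurve:
    """Moving-average power versus effect size with a cubic-spline fit."""

    effect_grid: np.ndarray
    mean_power: np.ndarray
    window: float
    spline: CubicSpline

    def __call__(self, d):
        return np.clip(self.spline(np.clip(d, self.effect_grid[0],
                                           self.effect_grid[-1])), 0.0, 1.0)


def power_curve(power_map, truth_d, window=0.05, absolute=False):
    """Moving-window mean of per-node power over effect size.

    Windows of width ``window`` (in d units) advance with 50% overlap; a
    cubic spline through the window means gives a continuous power
    curve.  ``absolute=True`` pools signs by |d|.
    """
    power_map = np.asarray(power_map, dtype=float)
    d = np.abs(truth_d) if absolute else np.asarray(truth_d, dtype=float)
    if power_map.size != d.size:
        raise ValueError("power map / effect size length mismatch")
    if power_map.size < 10:
        raise ValueError("need at least 10 nodes")
    lo, hi = float(d.min()), float(d.max())
    if window >= hi - lo:
        raise ValueError("window wider than the observed effect range")
    centers = np.arange(lo + window / 2, hi - window / 2 + 1e-12, window / 2)
    grid, means = [], []
    for c in centers:
        m = (d >= c - window / 2) & (d <= c + window / 2)
        if m.any():
            grid.append(c)
            means.append(power_map[m].mean())
    grid = np.asarray(grid)
    means = np.asarray(means)
    if grid.size < 2:
        raise ValueError("too few populated windows")
    kind = "natural" if grid.size >= 4 else "not-a-knot"
    return PowerCurve(effect_grid=grid, mean_power=means, window=window,
                      spline=CubicSpline(grid, means, bc_type=kind))


@dataclass
class ConfusionSummary:
    """Confusion counts with rates and bookmaker informedness."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def TPR(self):
        denom = self.TP + self.FN
        return self.TP / denom if denom else np.nan

    @property
    def TNR(self):
        denom = self.TN + self.FP
        return self.TN / denom if denom else np.nan

    @property
    def BM(self):
        return self.TPR + self.TNR - 1.0

    @property
    def n_assessed(self):
        return self.TP + self.FP + self.TN + self.FN


def informedness(predicted, truth):
    """Confusion summary of a signed prediction against the ground truth.

    Truth-signal nodes count as TP when detected with the correct sign
    (otherwise FN, including wrong-sign detections); truth-null nodes
    count as FP when detected at all (otherwise TN).

    Degenerate case: when the truth contains no null nodes, the two
    signed classes take the roles of the binary classes (positives =
    truth +1, negatives = truth -1), so the textbook anchors still hold:
    perfect prediction gives BM = 1 and total sign inversion BM = -1.
    """
    pred = _predicted_sign(predicted)
    ts = truth.sign
    if pred.size != ts.size:
        raise ValueError("prediction / truth dimension mismatch")
    signal = ts != 0
    if signal.all() and np.any(ts == -1) and np.any(ts == 1):
        tp = int(np.sum((ts == 1) & (pred == 1)))
        fn = int(np.sum(ts == 1)) - tp
        tn = int(np.sum((ts == -1) & (pred == -1)))
        fp = int(np.sum(ts == -1)) - tn
    else:
        tp = int(np.sum(signal & (pred == ts)))
        fn = int(np.sum(signal)) - tp
        fp = int(np.sum(~signal & (pred != 0)))
        tn = int(np.sum(~signal)) - fp
    return ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn)


def informedness_curve(results, truth_d, thresholds=None):
    """Mean BM per binarization threshold plus the normalized partial AUC.

    ``thresholds`` defaults to 21 points over 0.06..0.16.  The truth is
    re-discretized at every threshold; BM is averaged over results; the
    partial AUC is the trapezoidal integral over the grid divided by the
    grid span.
    """
    if thresholds is None:
        thresholds = np.linspace(*DEFAULT_THRESHOLD_RANGE, 21)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    results = [_predicted_sign(r) for r in (results if isinstance(results, (list, tuple)) else [results])]
    bm = np.empty(thresholds.size)
    for k, thr in enumerate(thresholds):
        gt = GroundTruth(truth_d, thr)
        bm[k] = float(np.mean([informedness(p, gt).BM for p in results]))
    if thresholds.size == 1:
        auc = float(bm[0])
    else:
        auc = float(np.trapezoid(bm, thresholds) / (thresholds[-1] - thresholds[0]))
    return bm, auc


# ----------------------------------------------------------------------
# analytic power bounds
@dataclass
class PowerBound:
    """Two-sided one-sample t-test power at a fixed level."""

    alpha: float
    n: int
    d_grid: np.ndarray
    power: np.ndarray
    d_min: float


def minimal_detectable_d(n, alpha, d_max=2.0, step=1e-4):
    """Smallest d on a fine grid whose t statistic ``d sqrt(n)`` exceeds
    the two-sided critical t value at level alpha (df = n - 1)."""
    tcrit = stats.t.isf(alpha / 2.0, n - 1)
    grid = np.arange(0.0, d_max + step, step)
    exceeding = np.flatnonzero(grid * np.sqrt(n) > tcrit)
    if exceeding.size == 0:
        raise ValueError("no grid point exceeds the critical value; raise d_max")
    return float(grid[exceeding[0]])


def analytic_power_bounds(n, alpha=0.05, n_tests=1, d_grid=None):
    """Uncorrected and Bonferroni-corrected t-test power curves.

    Returns ``(uncorrected, bonferroni)`` PowerBound objects: two-sided
    one-sample t-test power over ``d_grid`` at levels ``alpha`` and
    ``alpha / n_tests``, each with its minimal detectable effect size.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if d_grid is None:
        d_grid = np.linspace(0.0, 1.0, 201)
    d_grid = np.asarray(d_grid, dtype=float)

    def curve(level):
        # noncentral-t closed form: P(|T| > t_crit), T ~ nct(n-1, d sqrt(n));
        # stays finite at Bonferroni-small levels
        tcrit = stats.t.isf(level / 2.0, n - 1)
        nc = d_grid * np.sqrt(n)
        # opposite-tail term can underflow to NaN in scipy for large nc;
        # it is <= 1e-13 there, so treat it as zero
        opp = np.nan_to_num(stats.nct.cdf(-tcrit, n - 1, nc), nan=0.0)
        power = stats.nct.sf(tcrit, n - 1, nc) + opp
        return PowerBound(alpha=level, n=int(n), d_grid=d_grid, power=power,
                          d_min=minimal_detectable_d(n, level))

    return curve(alpha), curve(alpha / n_tests)
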