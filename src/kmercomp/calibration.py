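"""Score-distribution calibration: histograms, overlap, cut-offs, probabilities.

Raw similarity scores only become interpretable through their empirical
distributions.  Two histograms drive everything here:

* the **all-scores** distribution, from every query-reference comparison
  (dominated by negatives), and
* the **positive-only** distribution, restricted to known true pairs.

The *overlapping index* eta(A, B) = sum_bins min(f_A, f_B) summarises how
separable the two are (1 = identical, 0 = disjoint; low overlap predicts
high accuracy).  Subtracting the cumulative all-scores curve from the
cumulative positive-only curve yields the *cumulative difference* curve; the
score at its maximum is a natural cut-off below which most true positives
but few negatives lie.  Finally, sweeping a cut-off across the score range
and measuring the fraction of retained top hits that are correct produces a
*calibration curve* that maps any score onto an empirical probability of the
prediction being correct, partitioned into high / variable / low accuracy
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import TruthSet
from .metrics import MetricId, get_metric
from .search import ScoreRecord

__all__ = [
    "ScoreHistogram",
    "CumulativeDifference",
    "CalibrationCurve",
    "build_histogram",
    "overlapping_index",
    "cumulative_difference",
    "calibration_curve",
    "score_to_probability",
    "annotate_records",
]

DEFAULT_BINS = 100


@dataclass(frozen=True)
class ScoreHistogram:
    """Binned score-frequency distribution f(s) over a metric's score range.

    Bins are equal-width, left-closed right-open, the last bin closed, and
    frequencies sum to one whenever any score was binned.
    """

    metric: str
    lo: float
    hi: float
    bin_freqs: np.ndarray
    n_scores: int

    @property
    def n_bins(self) -> int:
        return self.bin_freqs.size

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    def compatible(self, other: "ScoreHistogram") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.lo, other.lo)
            and np.isclose(self.hi, other.hi)
        )


def build_histogram(
    scores: Sequence[float],
    metric: MetricId | str,
    n_bins: int = DEFAULT_BINS,
    score_range: tuple[float, float] | None = None,
) -> ScoreHistogram:
    """Bin scores into ``n_bins`` equal-width bins over the metric's range.

    Scores outside the range are clipped into the terminal bins with a
    warning; a score exactly at the upper edge falls in the last bin.
    """
    metric = get_metric(metric) if isinstance(metric, str) else metric
    scores_arr = np.asarray(list(scores), dtype=float)
    if scores_arr.size == 0:
        raise ValueError("cannot build a histogram from an empty score collection")
    lo, hi = score_range if score_range is not None else metric.score_range
    if not np.isfinite(hi):
        raise ValueError(f"metric {metric.name!r} has an unbounded range; pass score_range")
    if np.any(scores_arr < lo) or np.any(scores_arr > hi):
        warnings.warn(f"{metric.name}: scores outside [{lo}, {hi}] clipped into terminal bins")
        scores_arr = np.clip(scores_arr, lo, hi)
    width = (hi - lo) / n_bins
    idx = np.minimum(((scores_arr - lo) / width).astype(int), n_bins - 1)
    freqs = np.bincount(idx, minlength=n_bins).astype(float) / scores_arr.size
    return ScoreHistogram(metric.name, lo, hi, freqs, int(scores_arr.size))


def overlapping_index(a: ScoreHistogram, b: ScoreHistogram) -> float:
    """eta(A, B): sum over bins of the pointwise minimum of the two frequencies."""
    if not a.compatible(b):
        raise ValueError("histograms must share binning to be compared")
    return float(np.minimum(a.bin_freqs, b.bin_freqs).sum())


@dataclass(frozen=True)
class CumulativeDifference:
    """Cumulative positive-minus-all difference curve and its argmax cut-off."""

    bin_edges: np.ndarray
    cum_pos: np.ndarray
    cum_all: np.ndarray
    diff: np.ndarray
    cutoff_score: float


def cumulative_difference(
    all_scores: ScoreHistogram, positives: ScoreHistogram
) -> CumulativeDifference:
    """Cumulative difference between positive-only and all-scores histograms.

    ``diff = cum_pos - cum_all`` peaks at the score below which the positive
    mass most exceeds the background mass; the cut-off is the upper edge of
    the first bin attaining that maximum (first-max tie-break for
    determinism).
    """
    if not all_scores.compatible(positives):
        raise ValueError("histograms must share binning")
    cum_pos = np.cumsum(positives.bin_freqs)
    cum_all = np.cumsum(all_scores.bin_freqs)
    diff = cum_pos - cum_all
    argmax = int(np.argmax(diff))
    edges = all_scores.bin_edges
    return CumulativeDifference(
        bin_edges=edges,
        cum_pos=cum_pos,
        cum_all=cum_all,
        diff=diff,
        cutoff_score=float(edges[argmax + 1]),
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Accuracy as a function of applied cut-off score.

    ``frac_correct[i]``: among top hits with score <= eval_scores[i], the
    fraction that are true (0 when none are retained).  ``frac_excluded[i]``:
    the fraction of all true top hits removed by that cut-off.  ``regions``
    labels each grid point high / variable / low.
    """

    eval_scores: np.ndarray
    frac_correct: np.ndarray
    frac_excluded: np.ndarray
    regions: tuple[str, ...]
    overall_accuracy: float


def calibration_curve(
    top_hits: Sequence[ScoreRecord],
    truth: TruthSet,
    grid_size: int = DEFAULT_BINS,
    score_range: tuple[float, float] | None = None,
    high_accuracy: float = 0.95,
    low_mass: float = 0.99,
) -> CalibrationCurve:
    """Sweep cut-off scores over the metric range and measure top-hit accuracy.

    ``high`` region: grid points where the retained accuracy is at least
    ``high_accuracy``.  ``low`` region: scores above the point by which a
    fraction ``low_mass`` of all true top-hit scores has accumulated (beyond
    it, further predictions are unlikely to be true).  Everything else is
    ``variable``.
    """
    if not top_hits:
        raise ValueError("empty top-hit set")
    metric = get_metric(top_hits[0].metric)
    lo, hi = score_range if score_range is not None else metric.score_range
    scores = np.array([r.score for r in top_hits], dtype=float)
    labels = np.array([truth.is_positive(r.query_id, r.ref_id) for r in top_hits], dtype=bool)
    n_true = int(labels.sum())
    grid = np.linspace(lo, hi, grid_size + 1)[1:]  # upper edges of grid cells

    frac_correct = np.zeros(grid.size)
    frac_excluded = np.zeros(grid.size)
    for i, s in enumerate(grid):
        retained = scores <= s
        n_ret = int(retained.sum())
        n_ret_true = int((retained & labels).sum())
        frac_correct[i] = n_ret_true / n_ret if n_ret else 0.0
        frac_excluded[i] = (n_true - n_ret_true) / n_true if n_true else 0.0
    overall = n_true / labels.size

    if n_true:
        true_scores = np.sort(scores[labels])
        low_threshold = float(true_scores[min(int(np.ceil(low_mass * n_true)) - 1, n_true - 1)])
    else:
        low_threshold = lo
    regions = tuple(
        "high" if fc >= high_accuracy else ("low" if s > low_threshold else "variable")
        for s, fc in zip(grid, frac_correct)
    )
    return CalibrationCurve(grid, frac_correct, frac_excluded, regions, overall)


def score_to_probability(score: float, curve: CalibrationCurve) -> tuple[float, str]:
    """Map a score onto its empirical probability of correctness + region label.

    Step interpolation: the probability is the curve value at the first grid
    point covering the score; no extrapolation beyond the range.
    """
    grid = curve.eval_scores
    if score > grid[-1] + 1e-12:
        raise ValueError(f"score {score} outside calibrated range (max {grid[-1]})")
    idx = int(np.searchsorted(grid, score, side="left"))
    idx = min(idx, grid.size - 1)
    return float(curve.frac_correct[idx]), curve.regions[idx]


def annotate_records(
    records: Sequence[ScoreRecord], curve: CalibrationCurve, path: str | Path
) -> None:
    """Write a score table with probability and region columns appended."""
    with open(path, "w") as out:
        out.write("query_id\tref_id\tmetric\tscore\trank\tprobability\tregion\n")
        for r in records:
            prob, region = score_to_probability(r.score, curve)
            out.write(
                f"{r.query_id}\t{r.ref_id}\t{r.metric}\t{r.score:.10g}\t{r.rank}"
                f"\t{prob:.6g}\t{region}\n"
            )
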