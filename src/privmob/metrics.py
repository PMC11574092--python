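"""Utility metrics comparing private releases with non-private truth.

Matrix-level error uses the absolute per-cell error and a symmetric
relative error (twice the absolute error divided by the sum of the two
counts, which lies in [0, 2]).  Decision-level error treats the
non-private intervention grid as ground truth and scores the private
grid by per-region accuracy, precision, and recall.  Aid-targeting error
uses percent error on totals and daily top-k overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .mechanism import PrivateODMatrix
from .mobility import ODMatrix
from .targeting import top_k_flows

__all__ = [
    "MatrixErrorSummary",
    "DecisionMetrics",
    "matrix_error_summary",
    "decision_metrics",
    "percent_error",
    "topk_accuracy",
]

AnyODMatrix = Union[ODMatrix, PrivateODMatrix]


@dataclass(frozen=True)
class MatrixErrorSummary:
    abs_errors: np.ndarray
    rel_errors: np.ndarray
    median_abs_error: float
    median_rel_error: float


def matrix_error_summary(
    private: AnyODMatrix, nonprivate: ODMatrix
) -> MatrixErrorSummary:
    """Per-cell absolute and symmetric relative errors, with their medians.

    ``abs(i,j) = |private - nonprivate|`` with suppressed cells read as
    0; ``rel(i,j) = 2 * abs / (private + nonprivate)``, defined as 0
    when both counts are 0.  Medians are over off-diagonal cells.
    """
    if private.regions.region_ids != nonprivate.regions.region_ids:
        raise ValueError("matrices must share one region index")
    p = np.asarray(private.counts, dtype=np.float64)
    q = np.asarray(nonprivate.counts, dtype=np.float64)
    abs_err = np.abs(p - q)
    denom = p + q
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_err = np.where(denom > 0, 2.0 * abs_err / np.where(denom > 0, denom, 1.0), 0.0)
    off = ~np.eye(len(private.regions), dtype=bool)
    return MatrixErrorSummary(
        abs_errors=abs_err,
        rel_errors=rel_err,
        median_abs_error=float(np.median(abs_err[off])),
        median_rel_error=float(np.median(rel_err[off])),
    )


@dataclass(frozen=True)
class DecisionMetrics:
    """Per-region decision agreement plus mean and std across regions."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracy.std())

    @property
    def mean_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def std_precision(self) -> float:
        return float(self.precision.std())

    @property
    def mean_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def std_recall(self) -> float:
        return float(self.recall.std())


def decision_metrics(
    private_decisions: np.ndarray, nonprivate_decisions: np.ndarray
) -> DecisionMetrics:
    """Score private intervention decisions against non-private ground truth.

    Both inputs are boolean grids of shape (days, regions).  Per region,
    accuracy is the fraction of days on which the decisions agree;
    precision and recall treat non-private positives as ground truth.
    Degenerate conventions: a region with no true positives scores
    recall 1, and precision 1 when it also predicts no positives.  A
    region predicting no positives while true positives exist scores
    precision 0.
    """
    pred = np.asarray(private_decisions, dtype=bool)
    truth = np.asarray(nonprivate_decisions, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 2:
        raise ValueError("decision grids must be equal-shape (days, regions) arrays")

    tp = (pred & truth).sum(axis=0).astype(np.float64)
    fp = (pred & ~truth).sum(axis=0).astype(np.float64)
    fn = (~pred & truth).sum(axis=0).astype(np.float64)
    days = pred.shape[0]

    accuracy = (pred == truth).sum(axis=0) / days
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.where(fn == 0, 1.0, 0.0))
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 1.0)
    return DecisionMetrics(accuracy=accuracy, precision=precision, recall=recall)


def percent_error(private_total: float, nonprivate_total: float) -> float:
    """``100 * |nonprivate - private| / nonprivate``."""
    if not nonprivate_total > 0:
        raise ValueError("non-private total must be positive")
    return 100.0 * abs(nonprivate_total - private_total) / nonprivate_total


def topk_accuracy(
    private_matrices: Sequence[AnyODMatrix],
    nonprivate_matrices: Sequence[AnyODMatrix],
    affected: str,
    k: int,
    mode: str = "destinations",
) -> float:
    """Mean daily overlap (%) between private and non-private top-k sets.

    For each day the k highest-flow regions are selected from the
    private and the non-private matrix separately; the day's score is
    the fraction of the private set also in the non-private set, and the
    result is the average over days, as a percentage.
    """
    if len(private_matrices) != len(nonprivate_matrices):
        raise ValueError("windows must have the same number of days")
    overlaps = []
    for priv, nonpriv in zip(private_matrices, nonprivate_matrices):
        top_priv = set(top_k_flows([priv], affected, k, mode=mode))
        top_true = set(top_k_flows([nonpriv], affected, k, mode=mode))
        overlaps.append(len(top_priv & top_true) / k)
    return 100.0 * float(np.mean(overlaps))
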