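"""Privacy-accuracy calculators and privacy-loss accounting.

Two calculators translate a policymaker's error tolerance into a minimal
privacy-loss parameter epsilon: a moment heuristic based on the Laplace
standard deviation (``sqrt(2) T / alpha``), and a tail bound giving a
confidence guarantee on the per-cell error of non-suppressed counts.
A companion helper adapts an organizational suppression standard ``s``
into a threshold ``tau`` that accounts for the injected noise.

Privacy losses compose linearly across releases.  Under trip-level
protection an individual who contributes ``n_j`` trips to release ``j``
incurs total loss ``epsilon * sum_j n_j``; under individual-level
protection each censored release costs exactly ``epsilon`` regardless of
trip count, so ``J`` releases cost ``epsilon * J``.  The
:class:`PrivacyLedger` records either regime and is additive under
concatenation.

Finally, :func:`empirical_dp_audit` checks the mechanism's epsilon-DP
guarantee from the outside: it runs the release mechanism many times on
two neighboring datasets (differing in one trip) and verifies that the
output histograms never differ by more than a factor ``e**epsilon``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "PrivacyLedger",
    "heuristic_epsilon_for_error",
    "epsilon_for_error_bound",
    "laplace_cell_std",
    "tau_from_standard",
    "total_privacy_loss",
    "expected_privacy_loss",
    "suppression_probability",
    "difference_detection_error",
    "empirical_dp_audit",
]


def heuristic_epsilon_for_error(alpha: float, T: int = 1) -> float:
    """Minimal epsilon so the Laplace noise standard deviation is <= alpha.

    The Laplace scale is ``T / epsilon`` and its standard deviation is
    ``T * sqrt(2) / epsilon``; requiring a typical per-cell error of at
    most ``alpha`` gives ``epsilon >= sqrt(2) * T / alpha``.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return math.sqrt(2.0) * T / alpha


def epsilon_for_error_bound(alpha: float, delta: float, T: int = 1) -> float:
    """Minimal epsilon guaranteeing P(|released - true| > alpha) <= delta.

    Tail bound for non-suppressed cells: the released value differs from
    the true count by Laplace(T/epsilon) noise plus at most 0.5 of
    rounding, so requiring the Laplace tail beyond ``alpha + 0.5`` to
    have mass at most ``delta`` gives
    ``epsilon >= -T * ln(delta) / (alpha + 0.5)``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return -T * math.log(delta) / (alpha + 0.5)


def laplace_cell_std(T: int, epsilon: float) -> float:
    """Standard deviation ``T * sqrt(2) / epsilon`` of the per-cell noise."""
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return T * math.sqrt(2.0) / epsilon


TauDirection = Literal["unchanged", "minimize-suppression", "maximize-protection"]


def tau_from_standard(
    s: float, epsilon: float, direction: TauDirection = "unchanged"
) -> int:
    """Derive a suppression threshold from an organizational standard ``s``.

    ``unchanged`` keeps ``tau = s`` (the noise has zero mean).  The other
    directions shift by one noise standard deviation ``sqrt(2)/epsilon``:
    ``minimize-suppression`` subtracts it (clamped at 0) so fewer cells
    are withheld; ``maximize-protection`` adds it so small
    sub-populations surfaced by noise stay hidden.
    """
    if s < 0:
        raise ValueError(f"standard s must be >= 0, got {s}")
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    shift = math.sqrt(2.0) / epsilon
    if direction == "unchanged":
        value = s
    elif direction == "minimize-suppression":
        value = max(0.0, s - shift)
    elif direction == "maximize-protection":
        value = s + shift
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class PrivacyLedger:
    """Accumulated privacy loss over a sequence of releases.

    In the ``trip-level`` regime, ``releases`` holds the number of trips
    an individual contributed to each release; in the
    ``individual-level`` regime it holds one entry per censored release
    (its value is ignored; each release costs epsilon).
    """

    regime: Literal["trip-level", "individual-level"]
    epsilon: float
    releases: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.regime not in ("trip-level", "individual-level"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        releases = tuple(float(n) for n in self.releases)
        if any(n < 0 for n in releases):
            raise ValueError("per-release contributions must be non-negative")
        object.__setattr__(self, "releases", releases)

    def record(self, contribution: float = 1.0) -> "PrivacyLedger":
        """Return a new ledger with one more release appended."""
        return PrivacyLedger(self.regime, self.epsilon, self.releases + (contribution,))

    def __add__(self, other: "PrivacyLedger") -> "PrivacyLedger":
        if (self.regime, self.epsilon) != (other.regime, other.epsilon):
            raise ValueError("can only concatenate ledgers with matching regime and epsilon")
        return PrivacyLedger(self.regime, self.epsilon, self.releases + other.releases)

    @property
    def total_loss(self) -> float:
        return total_privacy_loss(self)


def total_privacy_loss(ledger: PrivacyLedger) -> float:
    """Accumulated loss: ``epsilon * sum(n_j)`` (trip-level) or ``epsilon * J``."""
    if ledger.regime == "trip-level":
        return ledger.epsilon * float(sum(ledger.releases))
    return ledger.epsilon * len(ledger.releases)


def expected_privacy_loss(epsilon: float, mean_trips_total: float) -> float:
    """Average individual's loss over a window: epsilon times mean trip count."""
    if mean_trips_total < 0:
        raise ValueError("mean trip count must be >= 0")
    return epsilon * mean_trips_total


def suppression_probability(
    true_count: float, tau: float, epsilon: float, T: int = 1
) -> float:
    """Probability that a cell with the given true count is suppressed.

    The cell is suppressed when ``count + Laplace(T/epsilon) < tau``;
    this is the Laplace CDF evaluated at ``tau`` with location
    ``true_count`` and scale ``T/epsilon``.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return float(stats.laplace.cdf(tau, loc=true_count, scale=T / epsilon))


def _privatize_counts(
    counts: np.ndarray, epsilon: float, T: int, tau: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized single-cell release rule (noise, threshold, round, clamp)."""
    noisy = counts + rng.laplace(scale=T / epsilon, size=counts.shape)
    released = np.maximum(np.floor(noisy + 0.5), tau)
    released[noisy < tau] = 0.0
    return released


def difference_detection_error(
    count_pair: tuple[float, float],
    epsilon: float,
    T: int = 1,
    reps: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo mean absolute error of a privatized count difference.

    Privatizes the two counts independently (no suppression, ``tau=0``)
    ``reps`` times and returns the mean absolute deviation of the
    released difference from the true difference.  Used to study how the
    error of change detection between two periods decays with epsilon.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    c1, c2 = count_pair
    rng = np.random.default_rng(seed)
    p1 = _privatize_counts(np.full(reps, float(c1)), epsilon, T, 0, rng)
    p2 = _privatize_counts(np.full(reps, float(c2)), epsilon, T, 0, rng)
    return float(np.mean(np.abs((p1 - p2) - (c1 - c2))))


@dataclass(frozen=True)
class DpAuditReport:
    """Result of an empirical differential-privacy audit."""

    epsilon: float
    max_abs_log_ratio: float
    bound: float
    tolerance: float
    n_reps: int
    support: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return self.max_abs_log_ratio <= self.bound + self.tolerance


def empirical_dp_audit(
    count: int,
    neighbor_count: int,
    epsilon: float,
    tau: int = 2,
    T: int = 1,
    reps: int = 1_000_000,
    seed: int | None = None,
    min_bin_count: int = 100,
) -> DpAuditReport:
    """Empirically audit the epsilon-DP bound on a single-cell release.

    Runs the release rule ``reps`` times on each of two neighboring true
    counts (differing by one trip at ``T=1``), histograms the integer
    outputs, and measures the largest absolute log-ratio of output
    probabilities over values observed at least ``min_bin_count`` times
    in both histograms.  For an epsilon-DP mechanism this log-ratio is
    bounded by ``epsilon`` up to Monte-Carlo error; the report carries a
    3-sigma sampling tolerance.
    """
    if abs(count - neighbor_count) != T:
        raise ValueError("neighboring datasets must differ by exactly T in the cell")
    rng = np.random.default_rng(seed)
    a = _privatize_counts(np.full(reps, float(count)), epsilon, T, tau, rng)
    b = _privatize_counts(np.full(reps, float(neighbor_count)), epsilon, T, tau, rng)

    values = np.union1d(np.unique(a), np.unique(b)).astype(np.int64)
    ca = np.array([(a == v).sum() for v in values], dtype=np.float64)
    cb = np.array([(b == v).sum() for v in values], dtype=np.float64)
    keep = (ca >= min_bin_count) & (cb >= min_bin_count)

    log_ratio = np.abs(np.log(ca[keep] / cb[keep]))
    # binomial standard error of a log-proportion: sqrt((1-p)/(n p)) per side
    se = np.sqrt((1.0 - ca[keep] / reps) / ca[keep] + (1.0 - cb[keep] / reps) / cb[keep])
    slack = float(np.max(3.0 * se)) if se.size else 0.0
    return DpAuditReport(
        epsilon=epsilon,
        max_abs_log_ratio=float(np.max(log_ratio)) if log_ratio.size else 0.0,
        bound=epsilon,
        tolerance=slack,
        n_reps=reps,
        support=tuple(int(v) for v in values[keep]),
    )
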