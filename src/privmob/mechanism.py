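"""The private O-D matrix mechanism: censoring, Laplace noise, thresholding.

The release pipeline has three steps.  Step 1 counts trips into a daily
O-D matrix (``privmob.mobility``).  Step 2 adds independent Laplace noise
with scale ``T / epsilon`` to every off-diagonal cell, where ``T`` is the
sensitivity: ``T = 1`` protects individual trips, while ``T > 1`` caps
each subscriber's contribution after random censoring and thereby
protects whole individuals.  Step 3 post-processes for disclosure
control: noisy values below the suppression threshold ``tau`` are
withheld (released as 0 and flagged), and surviving values are rounded
half-up and clamped to at least ``tau``, so every released non-suppressed
count is a non-negative integer no smaller than the threshold.

Steps 2-3 are pure post-processing of a single Laplace release per cell,
so the whole pipeline satisfies epsilon-differential privacy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mobility import ODMatrix, PopulationVector, RegionIndex, Trip

__all__ = [
    "PrivacyParams",
    "PrivateODMatrix",
    "sample_laplace",
    "censor_trips",
    "privatize_od_matrix",
    "privatize_count_vector",
]


@dataclass(frozen=True)
class PrivacyParams:
    """Parameters of one private release.

    epsilon
        Privacy-loss parameter; smaller means stronger privacy and more
        noise.  Must be positive.
    T
        Sensitivity cap.  ``1`` gives trip-level protection; larger
        values give individual-level protection once the input has been
        censored to at most ``T`` trips per subscriber.
    tau
        Suppression threshold (non-negative integer).  Noisy counts
        below ``tau`` are withheld.
    seed
        Seed for the noise generator; fixing it makes a release
        reproducible.
    """

    epsilon: float
    T: int = 1
    tau: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if int(self.T) != self.T or self.T < 1:
            raise ValueError(f"T must be a positive integer, got {self.T}")
        if int(self.tau) != self.tau or self.tau < 0:
            raise ValueError(f"tau must be a non-negative integer, got {self.tau}")
        object.__setattr__(self, "T", int(self.T))
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def noise_scale(self) -> float:
        """Laplace scale lambda = T / epsilon."""
        return self.T / self.epsilon


@dataclass(frozen=True)
class PrivateODMatrix:
    """A released private O-D matrix with per-cell suppression flags.

    Suppressed cells carry a released count of 0 *and* a flag, so
    downstream consumers can distinguish a true zero from a withheld
    value; sums treat both as zero.
    """

    day: object
    regions: RegionIndex
    counts: np.ndarray
    suppressed: np.ndarray
    params: PrivacyParams

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        suppressed = np.asarray(self.suppressed, dtype=bool)
        k = len(self.regions)
        if counts.shape != (k, k) or suppressed.shape != (k, k):
            raise ValueError("counts and suppression flags must both be k x k")
        if (counts < 0).any():
            raise ValueError("released counts must be non-negative")
        if counts[suppressed].any():
            raise ValueError("suppressed cells must be released as 0")
        off = ~np.eye(k, dtype=bool)
        visible = off & ~suppressed
        if (counts[visible] < self.params.tau).any():
            raise ValueError("non-suppressed off-diagonal counts must be >= tau")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "suppressed", suppressed)

    def total(self) -> int:
        return int(self.counts.sum())


def sample_laplace(
    scale: float, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. zero-centered Laplace samples with the given scale."""
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.laplace(loc=0.0, scale=scale, size=n)


def censor_trips(
    trips: Sequence[Trip], T: int, seed: int | np.random.Generator | None = None
) -> list[Trip]:
    """Cap each subscriber at ``T`` trips, dropping extras uniformly at random.

    Subscribers with at most ``T`` trips keep them all; otherwise ``T``
    of their trips are retained uniformly without replacement.  Required
    preprocessing for individual-level protection at sensitivity ``T``.
    """
    if int(T) != T or T < 1:
        raise ValueError(f"T must be a positive integer, got {T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    by_subscriber: dict[str, list[Trip]] = defaultdict(list)
    for trip in trips:
        by_subscriber[trip.subscriber_id].append(trip)

    kept: list[Trip] = []
    for subscriber in sorted(by_subscriber):  # deterministic iteration order
        own = by_subscriber[subscriber]
        if len(own) <= T:
            kept.extend(own)
        else:
            idx = rng.choice(len(own), size=T, replace=False)
            kept.extend(own[i] for i in sorted(idx))
    return kept


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def privatize_od_matrix(m: ODMatrix, params: PrivacyParams) -> PrivateODMatrix:
    """Apply Laplace noise and threshold post-processing to an O-D matrix.

    Per off-diagonal cell: ``noisy = count + Laplace(T / epsilon)``.  If
    ``noisy < tau`` the cell is suppressed (flag set, released value 0);
    otherwise the released value is ``round-half-up(noisy)`` clamped to
    at least ``tau``.  The diagonal stays at 0.  Noise is independent per
    cell and the whole release is reproducible under ``params.seed``.
    """
    k = len(m.regions)
    rng = np.random.default_rng(params.seed)
    noise = rng.laplace(loc=0.0, scale=params.noise_scale, size=(k, k))
    off = ~np.eye(k, dtype=bool)

    noisy = m.counts.astype(np.float64) + noise
    suppressed = off & (noisy < params.tau)
    released = np.where(off, np.maximum(_round_half_up(noisy), params.tau), 0.0)
    released[suppressed] = 0.0
    released[~off] = 0.0
    return PrivateODMatrix(
        day=m.day,
        regions=m.regions,
        counts=released.astype(np.int64),
        suppressed=suppressed,
        params=params,
    )


def privatize_count_vector(
    values: np.ndarray | PopulationVector, params: PrivacyParams
) -> np.ndarray:
    """Privatize a vector of per-region counts (e.g. home populations).

    Adds Laplace(T/epsilon) noise per entry (T should be 1: one person
    contributes one home region), rounds half-up, and clamps to >= 1 so
    the output remains usable as a population denominator.  There is no
    suppression step.
    """
    if isinstance(values, PopulationVector):
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(params.seed)
    noisy = values + rng.laplace(loc=0.0, scale=params.noise_scale, size=values.shape)
    return np.maximum(_round_half_up(noisy), 1.0).astype(np.int64)
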