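"""Core mobility types: regions, CDR events, trips, O-D matrices.

A trip is recorded whenever a subscriber produces two consecutive phone
events (calls or texts) in different administrative regions.  Daily
origin-destination (O-D) matrices count those inter-region trips over a
fixed region index, and home regions are inferred from each subscriber's
modal nighttime tower.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import date, datetime, time
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegionIndex",
    "CdrEvent",
    "TowerMap",
    "Trip",
    "ODMatrix",
    "PopulationVector",
    "extract_trips",
    "build_od_matrix",
    "build_daily_matrices",
    "infer_home_regions",
]


@dataclass(frozen=True)
class RegionIndex:
    """Ordered set of region identifiers defining O-D matrix axes.

    The ordering is fixed: row/column ``i`` of every matrix built against
    this index refers to ``region_ids[i]``.
    """

    region_ids: tuple[str, ...]
    admin_level: str = "admin-2"

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "_pos", {r: i for i, r in enumerate(ids)})

    def __len__(self) -> int:
        return len(self.region_ids)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._pos

    def index_of(self, region_id: str) -> int:
        try:
            return self._pos[region_id]
        except KeyError:
            raise KeyError(f"unknown region {region_id!r}") from None


@dataclass(frozen=True)
class CdrEvent:
    """One phone transaction: who, when, through which tower."""

    subscriber_id: str
    timestamp: datetime
    tower_id: str


@dataclass(frozen=True)
class TowerMap:
    """Mapping from cell towers to the regions that contain them."""

    mapping: Mapping[str, str]
    regions: RegionIndex

    def __post_init__(self) -> None:
        for tower, region in self.mapping.items():
            if region not in self.regions:
                raise ValueError(
                    f"tower {tower!r} maps to region {region!r} "
                    "which is not in the region index"
                )

    def region_of(self, tower_id: str) -> str:
        try:
            return self.mapping[tower_id]
        except KeyError:
            raise KeyError(f"tower {tower_id!r} is not in the tower map") from None


@dataclass(frozen=True)
class Trip:
    """A single inter-region movement by one subscriber on one day."""

    subscriber_id: str
    day: date
    origin: str
    destination: str

    def __post_init__(self) -> None:
        if self.origin == self.destination:
            raise ValueError("trips are inter-region: origin must differ from destination")


@dataclass(frozen=True)
class ODMatrix:
    """Daily k x k matrix of inter-region trip counts.

    ``counts[i, j]`` is the number of trips from region ``i`` to region
    ``j`` on ``day``.  The diagonal is identically zero because a trip is
    by definition a change of region.
    """

    day: date
    regions: RegionIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.regions)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diagonal(counts).any():
            raise ValueError("diagonal must be zero (trips are inter-region)")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PopulationVector:
    """Time-invariant per-region population counts N_1..N_k."""

    regions: RegionIndex
    values: np.ndarray
    time_invariant: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.regions),):
            raise ValueError("one population value per region required")
        if (values < 0).any():
            raise ValueError("populations must be non-negative")
        object.__setattr__(self, "values", values)

    def total(self) -> float:
        return float(self.values.sum())


def _event_sort_key(e: CdrEvent):
    # tower id as final tie-break so equal-timestamp events order deterministically
    return (e.subscriber_id, e.timestamp, e.tower_id)


def extract_trips(
    events: Iterable[CdrEvent],
    towers: TowerMap,
    within_day_only: bool = False,
) -> list[Trip]:
    """Extract inter-region trips from a CDR event stream.

    Events are sorted per subscriber by timestamp; every consecutive pair
    of events located in different regions yields one trip, dated by the
    day of the *later* event (the arrival).  With ``within_day_only`` set,
    pairs whose two events fall on different calendar days are skipped.

    Raises ``KeyError`` naming the tower if an event references a tower
    absent from the tower map.
    """
    ordered = sorted(events, key=_event_sort_key)
    trips: list[Trip] = []
    prev: CdrEvent | None = None
    for event in ordered:
        region = towers.region_of(event.tower_id)  # raises on unmapped tower
        if prev is not None and prev.subscriber_id == event.subscriber_id:
            prev_region = towers.region_of(prev.tower_id)
            same_day = prev.timestamp.date() == event.timestamp.date()
            if prev_region != region and (same_day or not within_day_only):
                trips.append(
                    Trip(
                        subscriber_id=event.subscriber_id,
                        day=event.timestamp.date(),
                        origin=prev_region,
                        destination=region,
                    )
                )
        prev = event
    return trips


def build_od_matrix(trips: Sequence[Trip], regions: RegionIndex, day: date) -> ODMatrix:
    """Count trips taken on ``day`` into a k x k O-D matrix."""
    k = len(regions)
    counts = np.zeros((k, k), dtype=np.int64)
    for trip in trips:
        if trip.day != day:
            continue
        i = regions.index_of(trip.origin)
        j = regions.index_of(trip.destination)
        counts[i, j] += 1
    return ODMatrix(day=day, regions=regions, counts=counts)


def build_daily_matrices(trips: Sequence[Trip], regions: RegionIndex) -> list[ODMatrix]:
    """One O-D matrix per distinct trip day, in chronological order."""
    by_day: dict[date, list[Trip]] = defaultdict(list)
    for t in trips:
        by_day[t.day].append(t)
    return [build_od_matrix(by_day[d], regions, d) for d in sorted(by_day)]


def _in_night_window(t: time, night_start: time, night_end: time) -> bool:
    # window wraps midnight when night_start > night_end: [start, 24h) u [0, end)
    if night_start <= night_end:
        return night_start <= t < night_end
    return t >= night_start or t < night_end


def infer_home_regions(
    events: Iterable[CdrEvent],
    towers: TowerMap,
    night_start: time = time(20, 0),
    night_end: time = time(6, 0),
) -> tuple[dict[str, str], PopulationVector]:
    """Infer each subscriber's home region and tally regional populations.

    A subscriber's home is the region of the tower they used most often
    during the nighttime window (default 8pm-6am).  Subscribers with no
    nighttime events fall back to their modal tower over all hours.  Ties
    are broken by the lexicographically smallest tower id.  The returned
    population vector counts subscribers per home region.
    """
    night_counts: dict[str, Counter] = defaultdict(Counter)
    all_counts: dict[str, Counter] = defaultdict(Counter)
    for event in events:
        towers.region_of(event.tower_id)  # validate early
        all_counts[event.subscriber_id][event.tower_id] += 1
        if _in_night_window(event.timestamp.time(), night_start, night_end):
            night_counts[event.subscriber_id][event.tower_id] += 1

    homes: dict[str, str] = {}
    for subscriber, counter in all_counts.items():
        source = night_counts[subscriber] if night_counts[subscriber] else counter
        # max count first, then smallest tower id
        best = min(source.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        homes[subscriber] = towers.region_of(best)

    values = np.zeros(len(towers.regions), dtype=np.float64)
    for region in homes.values():
        values[towers.regions.index_of(region)] += 1
    return homes, PopulationVector(regions=towers.regions, values=values)
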