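"""Synthetic CDR-style mobility scenarios.

Real call-detail-record datasets are proprietary, so this module
generates synthetic regions, populations, trips, and event streams with
the statistical structure the rest of the package assumes:

* heavy-tailed region populations (log-uniform over ~10^3-10^6);
* per-subscriber daily trip counts that are Poisson with gamma
  rate heterogeneity across subscribers — marginally negative binomial,
  giving the long upper tail seen in telecom data, where the 95th
  percentile of trips per subscriber is an order of magnitude above the
  mean and the 5th percentile is zero;
* gravity-model destination choice: flow to region j proportional to
  N_j / d_ij**gamma from the subscriber's current location;
* an optional shock (earthquake, battle, flood) that multiplies the
  trip rate of subscribers homed in the affected region from the shock
  day onward, producing an out-migration surge.

Each subscriber moves along a daily chain starting at home, so the
optional event stream (one event per visited location, plus a nightly
event at home) reproduces the generated trips exactly under
within-day trip extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np

from .mobility import CdrEvent, PopulationVector, RegionIndex, TowerMap, Trip

__all__ = [
    "Shock",
    "SyntheticScenario",
    "SyntheticDataset",
    "generate_regions",
    "generate_trips",
]


@dataclass(frozen=True)
class Shock:
    """A localized event multiplying out-migration from one region."""

    affected_region: str
    start_day: int
    outflow_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.outflow_multiplier < 0:
            raise ValueError("outflow multiplier must be non-negative")


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic mobility scenario.

    Defaults emulate a one-week disaster-response window over a
    provincial administrative layer: ~30 regions with populations
    spanning 10^3-10^6 and a mean of roughly 0.05 inter-region trips
    per subscriber per day (weekly means of a few tenths of a trip,
    as in sparse CDR panels), with strong subscriber heterogeneity.
    """

    k: int = 30
    pop_min: float = 1e3
    pop_max: float = 1e6
    n_subscribers: int = 2000
    mean_daily_trips: float = 0.05
    trip_rate_shape: float = 0.3
    home_pop_exponent: float = 1.0
    dest_pop_exponent: float = 1.0
    distance_decay: float = 1.0
    days: int = 7
    start_date: date = date(2020, 1, 1)
    admin_level: str = "admin-2"
    shock: Shock | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two regions")
        if self.mean_daily_trips < 0 or self.trip_rate_shape <= 0:
            raise ValueError("trip-rate parameters must be positive")
        if self.shock is not None and not 0 <= self.shock.start_day < self.days:
            raise ValueError("shock day must fall inside the scenario window")


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything a scenario realizes, ready for the pipeline."""

    scenario: SyntheticScenario
    regions: RegionIndex
    populations: PopulationVector
    distances: np.ndarray
    homes: dict[str, str]
    trips: list[Trip]
    towers: TowerMap
    events: list[CdrEvent] = field(default_factory=list)


def generate_regions(
    k: int, pop_min: float, pop_max: float, seed: int | np.random.Generator | None = None
) -> tuple[RegionIndex, PopulationVector, np.ndarray]:
    """Sample k regions with log-uniform populations and planar distances."""
    if k < 2:
        raise ValueError("need at least two regions")
    if not 0 < pop_min <= pop_max:
        raise ValueError("need 0 < pop_min <= pop_max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = RegionIndex(tuple(f"R{i:03d}" for i in range(k)))
    pops = np.exp(rng.uniform(np.log(pop_min), np.log(pop_max), size=k))
    pops = np.maximum(np.round(pops), 1.0)
    coords = rng.uniform(0.0, 1.0, size=(k, 2))
    diff = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((diff**2).sum(axis=-1))
    return regions, PopulationVector(regions=regions, values=pops), distances


def _destination_weights(
    populations: np.ndarray, distances: np.ndarray, dest_exp: float, decay: float
) -> np.ndarray:
    """Row-normalized gravity kernel: W[i, j] ~ N_j**dest_exp / d_ij**decay."""
    with np.errstate(divide="ignore"):
        w = populations[None, :] ** dest_exp / np.where(distances > 0, distances, np.inf) ** decay
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def generate_trips(scenario: SyntheticScenario, with_events: bool = False) -> SyntheticDataset:
    """Realize a scenario into subscribers, trips, and (optionally) events.

    Subscribers are homed proportionally to population.  Each draws a
    personal daily trip rate from a gamma distribution (mean
    ``mean_daily_trips``, shape ``trip_rate_shape``); each day their
    Poisson number of trips chains gravity-sampled destinations starting
    from home.  A shock multiplies the daily rate of subscribers homed
    in the affected region from its start day onward.

    With ``with_events`` the dataset also carries a CDR stream: one
    nighttime event at home (02:00) every day plus one daytime event per
    visited location, through one synthetic tower per region.
    """
    rng = np.random.default_rng(scenario.seed)
    regions, populations, distances = generate_regions(
        scenario.k, scenario.pop_min, scenario.pop_max, rng
    )
    k = scenario.k
    pops = populations.values

    home_weights = pops**scenario.home_pop_exponent
    home_idx = rng.choice(k, size=scenario.n_subscribers, p=home_weights / home_weights.sum())
    subscriber_ids = [f"S{i:06d}" for i in range(scenario.n_subscribers)]
    homes = {sid: regions.region_ids[h] for sid, h in zip(subscriber_ids, home_idx)}

    # gamma heterogeneity across subscribers -> negative binomial daily counts
    rates = rng.gamma(
        shape=scenario.trip_rate_shape,
        scale=scenario.mean_daily_trips / scenario.trip_rate_shape,
        size=scenario.n_subscribers,
    )
    dest_w = _destination_weights(
        pops, distances, scenario.dest_pop_exponent, scenario.distance_decay
    )
    cum_w = np.cumsum(dest_w, axis=1)

    shock = scenario.shock
    shock_home = regions.index_of(shock.affected_region) if shock is not None else -1

    towers = TowerMap(
        mapping={f"T-{r}": r for r in regions.region_ids}, regions=regions
    )
    tower_of = {r: f"T-{r}" for r in regions.region_ids}

    trips: list[Trip] = []
    events: list[CdrEvent] = []
    for day_offset in range(scenario.days):
        day = scenario.start_date + timedelta(days=day_offset)
        mult = np.ones(scenario.n_subscribers)
        if shock is not None and day_offset >= shock.start_day:
            mult[home_idx == shock_home] = shock.outflow_multiplier
        n_trips = rng.poisson(rates * mult)
        for s in np.nonzero(n_trips)[0]:
            sid = subscriber_ids[s]
            loc = home_idx[s]
            visited = [loc]
            for _ in range(n_trips[s]):
                dest = int(np.searchsorted(cum_w[loc], rng.random()))
                trips.append(
                    Trip(
                        subscriber_id=sid,
                        day=day,
                        origin=regions.region_ids[loc],
                        destination=regions.region_ids[dest],
                    )
                )
                loc = dest
                visited.append(loc)
            if with_events:
                for hop, region_idx in enumerate(visited):
                    events.append(
                        CdrEvent(
                            subscriber_id=sid,
                            timestamp=datetime.combine(day, time(8, 0))
                            + timedelta(hours=hop),
                            tower_id=tower_of[regions.region_ids[region_idx]],
                        )
                    )
        if with_events:
            # nightly home event: anchors home inference, never creates
            # a same-day region change
            for s in range(scenario.n_subscribers):
                events.append(
                    CdrEvent(
                        subscriber_id=subscriber_ids[s],
                        timestamp=datetime.combine(day, time(2, 0)),
                        tower_id=tower_of[regions.region_ids[home_idx[s]]],
                    )
                )

    return SyntheticDataset(
        scenario=scenario,
        regions=regions,
        populations=populations,
        distances=distances,
        homes=homes,
        trips=trips,
        towers=towers,
        events=events,
    )
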