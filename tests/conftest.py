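from datetime import date, datetime

import numpy as np
import pytest

from privmob import (
    CdrEvent,
    ODMatrix,
    PopulationVector,
    RegionIndex,
    TowerMap,
    Trip,
)


@pytest.fixture
def regions3() -> RegionIndex:
    return RegionIndex(("A", "B", "C"))


@pytest.fixture
def towers3(regions3) -> TowerMap:
    return TowerMap(mapping={"t1": "A", "t2": "B", "t3": "C"}, regions=regions3)


@pytest.fixture
def day0() -> date:
    return date(2020, 1, 1)


def make_trip(origin, destination, day=date(2020, 1, 1), subscriber="s1") -> Trip:
    return Trip(subscriber_id=subscriber, day=day, origin=origin, destination=destination)


@pytest.fixture
def od3(regions3, day0) -> ODMatrix:
    counts = np.array([[0, 2, 1], [1, 0, 0], [0, 3, 0]])
    return ODMatrix(day=day0, regions=regions3, counts=counts)


@pytest.fixture
def pops3(regions3) -> PopulationVector:
    return PopulationVector(regions=regions3, values=np.array([1000.0, 500.0, 2000.0]))


def event(subscriber, ts, tower) -> CdrEvent:
    return CdrEvent(
        subscriber_id=subscriber, timestamp=datetime.fromisoformat(ts), tower_id=tower
    )
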