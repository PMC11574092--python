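"""CSV / JSON dialects for events, trips, matrices, and reports.

All tabular files are plain delimited text handled through pandas.
O-D matrices travel in long form (day, origin, destination, count); a
private release additionally carries a ``suppressed`` 0/1 column and a
JSON sidecar with the release parameters, so a private file can always
be re-associated with its epsilon, T, tau, and seed.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .guarantees import PrivacyLedger
from .mechanism import PrivacyParams, PrivateODMatrix
from .mobility import (
    CdrEvent,
    ODMatrix,
    PopulationVector,
    RegionIndex,
    TowerMap,
    Trip,
)

__all__ = [
    "read_events_csv",
    "write_events_csv",
    "read_towers_csv",
    "write_towers_csv",
    "read_trips_csv",
    "write_trips_csv",
    "read_od_csv",
    "write_od_csv",
    "read_private_od_csv",
    "write_private_od_csv",
    "read_populations_csv",
    "write_populations_csv",
    "write_ledger_json",
]


def read_events_csv(path: str | Path) -> list[CdrEvent]:
    df = pd.read_csv(path, dtype={"subscriber_id": str, "tower_id": str})
    return [
        CdrEvent(
            subscriber_id=row.subscriber_id,
            timestamp=datetime.fromisoformat(str(row.timestamp)),
            tower_id=row.tower_id,
        )
        for row in df.itertuples()
    ]


def write_events_csv(events: Sequence[CdrEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subscriber_id": [e.subscriber_id for e in events],
            "timestamp": [e.timestamp.isoformat() for e in events],
            "tower_id": [e.tower_id for e in events],
        }
    ).to_csv(path, index=False)


def read_towers_csv(path: str | Path, admin_level: str = "admin-2") -> TowerMap:
    """Read a tower map; region column is ``region_id_<level-suffix>``."""
    df = pd.read_csv(path, dtype=str)
    column = "region_id_" + admin_level.replace("-", "")
    if column not in df.columns:
        raise ValueError(f"tower file has no column {column!r}")
    region_ids = tuple(dict.fromkeys(df[column]))
    regions = RegionIndex(region_ids, admin_level=admin_level)
    return TowerMap(mapping=dict(zip(df["tower_id"], df[column])), regions=regions)


def write_towers_csv(towers: TowerMap, path: str | Path) -> None:
    column = "region_id_" + towers.regions.admin_level.replace("-", "")
    pd.DataFrame(
        {
            "tower_id": list(towers.mapping),
            column: [towers.mapping[t] for t in towers.mapping],
        }
    ).to_csv(path, index=False)


def read_trips_csv(path: str | Path) -> list[Trip]:
    df = pd.read_csv(path, dtype={"subscriber_id": str, "origin": str, "destination": str})
    return [
        Trip(
            subscriber_id=row.subscriber_id,
            day=date.fromisoformat(str(row.day)),
            origin=row.origin,
            destination=row.destination,
        )
        for row in df.itertuples()
    ]


def write_trips_csv(trips: Sequence[Trip], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subscriber_id": [t.subscriber_id for t in trips],
            "day": [t.day.isoformat() for t in trips],
            "origin": [t.origin for t in trips],
            "destination": [t.destination for t in trips],
        }
    ).to_csv(path, index=False)


def _matrix_long_frame(m: ODMatrix | PrivateODMatrix, with_flags: bool) -> pd.DataFrame:
    k = len(m.regions)
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            row = {
                "day": m.day.isoformat(),
                "origin": m.regions.region_ids[i],
                "destination": m.regions.region_ids[j],
                "count": int(m.counts[i, j]),
            }
            if with_flags:
                row["suppressed"] = int(m.suppressed[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def write_od_csv(matrices: Sequence[ODMatrix], path: str | Path) -> None:
    pd.concat([_matrix_long_frame(m, with_flags=False) for m in matrices]).to_csv(
        path, index=False
    )


def read_od_csv(
    path: str | Path, regions: RegionIndex | None = None
) -> list[ODMatrix]:
    df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    if regions is None:
        ids = sorted(set(df["origin"]) | set(df["destination"]))
        regions = RegionIndex(tuple(ids))
    matrices = []
    k = len(regions)
    for day_str, group in df.groupby("day", sort=True):
        counts = np.zeros((k, k), dtype=np.int64)
        oi = [regions.index_of(o) for o in group["origin"]]
        dj = [regions.index_of(d) for d in group["destination"]]
        counts[oi, dj] = group["count"].to_numpy(dtype=np.int64)
        matrices.append(ODMatrix(day=date.fromisoformat(str(day_str)), regions=regions, counts=counts))
    return matrices


def write_private_od_csv(
    matrices: Sequence[PrivateODMatrix], path: str | Path
) -> None:
    """Write private matrices plus a ``<path>.meta.json`` parameter sidecar."""
    pd.concat([_matrix_long_frame(m, with_flags=True) for m in matrices]).to_csv(
        path, index=False
    )
    params = matrices[0].params
    meta = {
        "epsilon": params.epsilon,
        "T": params.T,
        "tau": params.tau,
        "seed": params.seed,
        "admin_level": matrices[0].regions.admin_level,
        "days": [m.day.isoformat() for m in matrices],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_private_od_csv(
    path: str | Path, regions: RegionIndex | None = None
) -> list[PrivateODMatrix]:
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    params = PrivacyParams(
        epsilon=meta["epsilon"], T=meta["T"], tau=meta["tau"], seed=meta["seed"]
    )
    df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    if regions is None:
        ids = sorted(set(df["origin"]) | set(df["destination"]))
        regions = RegionIndex(tuple(ids), admin_level=meta.get("admin_level", "admin-2"))
    matrices = []
    k = len(regions)
    for day_str, group in df.groupby("day", sort=True):
        counts = np.zeros((k, k), dtype=np.int64)
        suppressed = np.zeros((k, k), dtype=bool)
        oi = [regions.index_of(o) for o in group["origin"]]
        dj = [regions.index_of(d) for d in group["destination"]]
        counts[oi, dj] = group["count"].to_numpy(dtype=np.int64)
        suppressed[oi, dj] = group["suppressed"].to_numpy(dtype=bool)
        matrices.append(
            PrivateODMatrix(
                day=date.fromisoformat(str(day_str)),
                regions=regions,
                counts=counts,
                suppressed=suppressed,
                params=params,
            )
        )
    return matrices


def read_populations_csv(path: str | Path, admin_level: str = "admin-2") -> PopulationVector:
    df = pd.read_csv(path, dtype={"region": str})
    regions = RegionIndex(tuple(df["region"]), admin_level=admin_level)
    return PopulationVector(regions=regions, values=df["population"].to_numpy(dtype=float))


def write_populations_csv(populations: PopulationVector, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region": populations.regions.region_ids,
            "population": populations.values.astype(np.int64),
        }
    ).to_csv(path, index=False)


def write_ledger_json(ledger: PrivacyLedger, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "regime": ledger.regime,
                "epsilon": ledger.epsilon,
                "releases": list(ledger.releases),
                "total_loss": ledger.total_loss,
            },
            indent=2,
        )
    )
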