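"""Post-shock aid targeting from O-D matrices.

After a natural disaster or violent event, out-migration over the
following response window (typically one week of daily matrices)
identifies where displaced people went.  Two statistics drive aid
allocation: the total out-migration from the affected region, and the
top-k regions receiving the most migrants.  Both work identically on
private and non-private matrices; suppressed cells contribute zero.
"""

from __future__ import annotations

from typing import Literal, Sequence, Union

import numpy as np

from .mechanism import PrivateODMatrix
from .mobility import ODMatrix

__all__ = ["total_out_migration", "top_k_flows"]

AnyODMatrix = Union[ODMatrix, PrivateODMatrix]


def _stack(matrices: Sequence[AnyODMatrix]) -> np.ndarray:
    if len(matrices) == 0:
        raise ValueError("window must contain at least one O-D matrix")
    first = matrices[0].regions.region_ids
    for m in matrices[1:]:
        if m.regions.region_ids != first:
            raise ValueError("all matrices in the window must share one region index")
    return np.stack([np.asarray(m.counts, dtype=np.int64) for m in matrices])


def total_out_migration(
    matrices: Sequence[AnyODMatrix], affected: str | None = None
) -> int:
    """Total out-trips over the window.

    With ``affected`` set, sums the affected region's row (all flows
    leaving it) across days; with ``affected=None`` returns the grand
    total of all matrices.
    """
    stacked = _stack(matrices)
    if affected is None:
        return int(stacked.sum())
    row = matrices[0].regions.index_of(affected)
    return int(stacked[:, row, :].sum())


def top_k_flows(
    matrices: Sequence[AnyODMatrix],
    affected: str,
    k: int,
    mode: Literal["destinations", "origins"] = "destinations",
) -> list[str]:
    """The k regions with the largest migration flows over the window.

    ``destinations`` (default) ranks regions by total flow *received
    from* the affected region — the places migrants went.  ``origins``
    ranks all regions by their total out-flow.  Ties break by region id
    ascending, so the ranking is deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    regions = matrices[0].regions
    stacked = _stack(matrices)
    if mode == "destinations":
        row = regions.index_of(affected)
        flows = stacked[:, row, :].sum(axis=0)
        eligible = [i for i in range(len(regions)) if i != row]
    elif mode == "origins":
        regions.index_of(affected)  # validate the region id
        flows = stacked.sum(axis=(0, 2))
        eligible = list(range(len(regions)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds the {len(eligible)} eligible regions")
    ranked = sorted(eligible, key=lambda i: (-flows[i], regions.region_ids[i]))
    return [regions.region_ids[i] for i in ranked[:k]]
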