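"""Mobility-informed SIR metapopulation model.

Each region ``i`` carries compartments ``S_i, I_i, R_i`` with fixed
population ``N_i = S_i + I_i + R_i``.  Transmission has an intra-region
term ``beta * S_i * I_i / N_i`` and an inter-region term in which the
force of infection imported through mobility is weighted by the daily
O-D matrix ``M``:

    dS_i/dt = - beta S_i I_i / N_i
              - alpha beta S_i * sum_j (M_ij I_j / N_j) / (N_i + sum_j M_ij)
    dR_i/dt = mu I_i / N_i            (``as-printed`` recovery form)
            = mu I_i                  (``classic`` recovery form)
    dI_i/dt = -dS_i/dt - dR_i/dt

``beta`` is the within-region contact/transmission rate, ``alpha`` the
mixing ratio of visitors relative to residents, and ``mu`` the recovery
rate.  ``dI`` is defined as the negative sum of the other derivatives so
each region's population is conserved exactly.  Two recovery forms are
selectable: ``as-printed`` divides by ``N_i`` (recovery slows in large
regions), ``classic`` is the standard SIR recovery ``mu * I`` in which
``mu`` is the fraction of infected individuals recovering per day.

Integration is forward Euler with a one-day step, matching the daily
cadence of the mobility matrices.  Private matrices plug in directly:
suppressed cells contribute zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np

from .mechanism import PrivateODMatrix
from .mobility import ODMatrix, PopulationVector, RegionIndex

__all__ = [
    "SirParams",
    "EpidemicState",
    "EpidemicResult",
    "sir_step",
    "run_epidemic",
    "policy_decisions",
]

AnyODMatrix = Union[ODMatrix, PrivateODMatrix]


@dataclass(frozen=True)
class SirParams:
    """Rates of the mobility-informed SIR model (defaults COVID-19-like)."""

    beta: float = 0.10
    alpha_mix: float = 1.0
    mu: float = 0.04
    recovery_form: Literal["as-printed", "classic"] = "as-printed"
    step_size: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.alpha_mix < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.recovery_form not in ("as-printed", "classic"):
            raise ValueError(f"unknown recovery form {self.recovery_form!r}")
        if not self.step_size > 0:
            raise ValueError("step size must be positive")


@dataclass(frozen=True)
class EpidemicState:
    """Per-region S/I/R compartments at one time point."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    N: PopulationVector
    t: int = 0

    def __post_init__(self) -> None:
        k = len(self.N.regions)
        S = np.asarray(self.S, dtype=np.float64)
        I = np.asarray(self.I, dtype=np.float64)
        R = np.asarray(self.R, dtype=np.float64)
        for name, arr in (("S", S), ("I", I), ("R", R)):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per region")
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if (self.N.values <= 0).any():
            raise ValueError("all populations must be positive for SIR dynamics")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "R", R)

    @property
    def prevalence(self) -> np.ndarray:
        return self.I / self.N.values


def _matrix_counts(m: AnyODMatrix) -> np.ndarray:
    # released counts of a private matrix already carry 0 in suppressed cells
    return np.asarray(m.counts, dtype=np.float64)


def sir_step(state: EpidemicState, m: AnyODMatrix, params: SirParams) -> EpidemicState:
    """Advance the epidemic by one day using the day's mobility matrix."""
    if m.regions.region_ids != state.N.regions.region_ids:
        raise ValueError("matrix regions do not match epidemic state regions")
    M = _matrix_counts(m)
    N = state.N.values
    S, I, R = state.S, state.I, state.R

    imported = M @ (I / N)  # sum_j M_ij I_j / N_j
    out_trips = M.sum(axis=1)
    dS = -params.beta * S * I / N - params.alpha_mix * params.beta * S * imported / (
        N + out_trips
    )
    if params.recovery_form == "as-printed":
        dR = params.mu * I / N
    else:
        dR = params.mu * I
    dI = -dS - dR  # population conserved by construction

    h = params.step_size
    return EpidemicState(
        S=np.maximum(S + h * dS, 0.0),
        I=np.maximum(I + h * dI, 0.0),
        R=np.maximum(R + h * dR, 0.0),
        N=state.N,
        t=state.t + 1,
    )


@dataclass(frozen=True)
class EpidemicResult:
    """Trajectories of a simulation: arrays of shape (days + 1, k)."""

    regions: RegionIndex
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    N: PopulationVector

    @property
    def prevalence(self) -> np.ndarray:
        return self.I / self.N.values[None, :]


def run_epidemic(
    daily_matrices: Sequence[AnyODMatrix],
    populations: PopulationVector,
    seed_region: str,
    init_frac: float = 0.01,
    params: SirParams = SirParams(),
) -> EpidemicResult:
    """Simulate an epidemic seeded in one region over a sequence of days.

    Day 0 places ``init_frac`` of the seed region's population in the
    infected compartment; every other region starts fully susceptible.
    One Euler step is taken per daily matrix, so the returned
    trajectories have ``len(daily_matrices) + 1`` rows.
    """
    if len(daily_matrices) == 0:
        raise ValueError("at least one daily O-D matrix is required")
    if not 0 <= init_frac <= 1:
        raise ValueError("init_frac must be in [0, 1]")
    regions = populations.regions
    seed_idx = regions.index_of(seed_region)

    I0 = np.zeros(len(regions))
    I0[seed_idx] = init_frac * populations.values[seed_idx]
    state = EpidemicState(S=populations.values - I0, I=I0, R=np.zeros(len(regions)), N=populations)

    S_hist, I_hist, R_hist = [state.S], [state.I], [state.R]
    for m in daily_matrices:
        state = sir_step(state, m, params)
        S_hist.append(state.S)
        I_hist.append(state.I)
        R_hist.append(state.R)
    return EpidemicResult(
        regions=regions,
        S=np.vstack(S_hist),
        I=np.vstack(I_hist),
        R=np.vstack(R_hist),
        N=populations,
    )


def policy_decisions(prevalence_series: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Binary intervention grid: act where prevalence meets the threshold.

    ``decision[t, i]`` is True when region ``i``'s estimated prevalence
    on day ``t`` is at least ``threshold`` (default 20%).
    """
    prevalence = np.asarray(prevalence_series, dtype=np.float64)
    if (prevalence < 0).any() or (prevalence > 1).any():
        raise ValueError("prevalence values must lie in [0, 1]")
    return prevalence >= threshold
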