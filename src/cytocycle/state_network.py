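"""Three-state cell-cycle transition network with division.

The population model is a discrete-time (1 h) jump process over the three
cell-cycle macro-states G0/G1 (state 1), late G1/S (state 2) and G2/M
(state 3).  Each hour a proportion ``m_i`` of the cells in state ``i``
advances to the next state in the cycle; the G2/M -> G0/G1 transition is the
division edge, where every transitioning cell produces two G0/G1 daughters.
An optional per-state death probability ``phi_i`` removes cells from the
system.  The hourly expected-value update is

    x1' = (1 - m1 - phi1) x1 + 2 m3 x3
    x2' = (1 - m2 - phi2) x2 + m1 x1
    x3' = (1 - m3 - phi3) x3 + m2 x2

which this module propagates deterministically over real-valued counts.
Integer stochastic sampling of the same process lives in
:mod:`cytocycle.synthetic_plates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIVISION_FACTOR",
    "STATE_NAMES",
    "TransitionParams",
    "DeathRates",
    "PopulationState",
    "Trajectory",
    "update_matrix",
    "step",
    "simulate",
    "growth_eigensystem",
    "doubling_time",
]

#: Daughter cells produced per G2/M -> G0/G1 transition.
DIVISION_FACTOR = 2.0

#: Canonical state order used everywhere in the package.
STATE_NAMES = ("G0/G1", "lateG1/S", "G2/M")


def _check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0 or not math.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TransitionParams:
    """Hourly forward-transition probabilities of the three-state cycle.

    ``m1``: G0/G1 -> lateG1/S, ``m2``: lateG1/S -> G2/M,
    ``m3``: G2/M -> G0/G1 (division edge).  The self-transition proportion
    of state ``i`` is ``1 - m_i``.
    """

    m1: float
    m2: float
    m3: float

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3"):
            _check_unit_interval(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "TransitionParams":
        v = np.asarray(values, dtype=float)
        if v.shape != (3,):
            raise ValueError("expected exactly three transition probabilities")
        return cls(*v)


@dataclass(frozen=True)
class DeathRates:
    """Hourly death probabilities per state (default: no death)."""

    phi1: float = 0.0
    phi2: float = 0.0
    phi3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi1", "phi2", "phi3"):
            _check_unit_interval(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.phi1, self.phi2, self.phi3], dtype=float)


NO_DEATH = DeathRates()


@dataclass(frozen=True)
class PopulationState:
    """Real-valued cell counts per state at an integer hour ``t``."""

    x1: float
    x2: float
    x3: float
    t: int = 0

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite nonnegative count, got {v!r}")

    @property
    def total(self) -> float:
        return self.x1 + self.x2 + self.x3

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            return np.full(3, np.nan)
        return self.as_array() / tot


def update_matrix(params: TransitionParams, death: DeathRates = NO_DEATH) -> np.ndarray:
    """Hourly population update matrix ``A`` with ``x_{t+1} = A x_t``."""
    m = params.as_array()
    phi = death.as_array()
    retained = 1.0 - m - phi
    if np.any(retained < -1e-12):
        bad = int(np.argmin(retained)) + 1
        raise ValueError(
            f"m{bad} + phi{bad} exceeds 1; the retained fraction would be negative"
        )
    retained = np.clip(retained, 0.0, 1.0)
    return np.array(
        [
            [retained[0], 0.0, DIVISION_FACTOR * m[2]],
            [m[0], retained[1], 0.0],
            [0.0, m[1], retained[2]],
        ]
    )


def step(
    state: PopulationState,
    params: TransitionParams,
    death: DeathRates = NO_DEATH,
) -> PopulationState:
    """Advance the population by one hour."""
    x = update_matrix(params, death) @ state.as_array()
    return PopulationState(x[0], x[1], x[2], t=state.t + 1)


@dataclass(frozen=True)
class Trajectory:
    """Hourly population states from ``t=0`` through the horizon."""

    counts: np.ndarray  # (horizon+1, 3)
    t0: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 3:
            raise ValueError("trajectory counts must have shape (horizon+1, 3)")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self))

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> np.ndarray:
        totals = self.totals
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / totals[:, None]

    @property
    def final(self) -> PopulationState:
        x = self.counts[-1]
        return PopulationState(x[0], x[1], x[2], t=int(self.times[-1]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, per-state counts, total, per-state proportions."""
        props = self.proportions
        return pd.DataFrame(
            {
                "time_h": self.times,
                "x_g0g1": self.counts[:, 0],
                "x_lateg1s": self.counts[:, 1],
                "x_g2m": self.counts[:, 2],
                "total": self.totals,
                "p_g0g1": props[:, 0],
                "p_lateg1s": props[:, 1],
                "p_g2m": props[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    params: TransitionParams,
    death: DeathRates = NO_DEATH,
    x0: PopulationState | Sequence[float] = (100.0, 0.0, 0.0),
    horizon: int = 72,
) -> Trajectory:
    """Propagate the hourly update for ``horizon`` hours.

    ``x0`` may be a :class:`PopulationState` or a 3-sequence of counts.
    """
    if not float(horizon).is_integer() or horizon < 0:
        raise ValueError(f"horizon must be a nonnegative integer number of hours, got {horizon!r}")
    horizon = int(horizon)
    if isinstance(x0, PopulationState):
        t0, x = x0.t, x0.as_array()
    else:
        t0, x = 0, np.asarray(x0, dtype=float)
        if x.shape != (3,) or np.any(x < 0):
            raise ValueError("x0 must be three nonnegative counts")
    A = update_matrix(params, death)
    counts = np.empty((horizon + 1, 3))
    counts[0] = x
    for k in range(horizon):
        x = A @ x
        counts[k + 1] = x
    return Trajectory(counts, t0=t0)


def growth_eigensystem(
    params: TransitionParams, death: DeathRates = NO_DEATH
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and stationary composition of the update matrix.

    Returns the hourly population growth factor ``lambda`` and the
    normalized (sum = 1) dominant right eigenvector, i.e. the constant
    state-fraction vector during balanced exponential growth.  For a
    degenerate network (some ``m_i = 0`` breaks the cycle) the dominant
    eigenvalue is <= 1 and is returned as-is rather than raising.
    """
    A = update_matrix(params, death)
    eigvals, eigvecs = np.linalg.eig(A)
    # The update matrix is nonnegative, so the spectral radius is attained
    # by a real eigenvalue with a nonnegative eigenvector (Perron-Frobenius).
    idx = int(np.argmax(eigvals.real - 1e3 * np.abs(eigvals.imag)))
    lam = float(eigvals[idx].real)
    vec = eigvecs[:, idx].real
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    s = vec.sum()
    vec = vec / s if s > 0 else np.full(3, 1.0 / 3.0)
    return lam, vec


def doubling_time(growth_factor: float) -> float:
    """Population doubling time (hours) for an hourly growth factor.

    Returns ``math.inf`` for a non-dividing population (factor <= 1).
    """
    if growth_factor <= 1.0:
        return math.inf
    return math.log(2.0) / math.log(growth_factor)
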