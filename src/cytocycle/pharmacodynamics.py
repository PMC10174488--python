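"""Dose-dependent transition inhibition, drug-induced death, and the
treated-vs-control relative cell count.

Each drug acts on exactly one cell-cycle state: it inhibits that state's
forward transition with a sigmoidal Hill function of dose,

    m_i(D) = m_i0 * (1 - (D/EC50)^n / (1 + (D/EC50)^n)),

and adds an hourly death probability from the same state that saturates
hyperbolically (Hill coefficient fixed at 1),

    phi_i(D) = Emax_phi * (D/EC50_phi) / (1 + (D/EC50_phi)).

The model readout is the relative cell count: total live cells at the
72-h endpoint of a treated simulation divided by the untreated control,
both started from the no-drug stationary composition (cells settle
overnight before dosing, so the population is in balanced growth when the
drug arrives).  By linearity the initial total cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .state_network import (
    NO_DEATH,
    DeathRates,
    TransitionParams,
    growth_eigensystem,
    update_matrix,
)

__all__ = [
    "DrugParams",
    "CellLineModel",
    "transition_inhibition",
    "death_rate",
    "effective_rates",
    "relative_cell_count",
    "relative_cell_counts",
]

DoseAssignment = Mapping[str, float]


@dataclass(frozen=True)
class DrugParams:
    """One drug's four dose-response parameters and its target state.

    ``ec50`` (uM) and ``hill_n`` shape the transition inhibition; the death
    term saturates at ``emax_phi`` (per hour) with half-max at ``ec50_phi``
    (uM).  ``target_state`` uses the canonical indices 1 = G0/G1,
    2 = lateG1/S, 3 = G2/M.
    """

    name: str
    target_state: int
    ec50: float
    hill_n: float
    emax_phi: float = 0.0
    ec50_phi: float = 1.0

    def __post_init__(self) -> None:
        if self.target_state not in (1, 2, 3):
            raise ValueError(f"target_state must be 1, 2 or 3, got {self.target_state!r}")
        if not self.ec50 > 0 or not self.ec50_phi > 0:
            raise ValueError("ec50 and ec50_phi must be positive")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be positive")
        if not 0.0 <= self.emax_phi <= 1.0:
            raise ValueError("emax_phi must lie in [0, 1]")


@dataclass(frozen=True)
class CellLineModel:
    """Calibrated base transition probabilities plus the drugs acting on them."""

    name: str
    base: TransitionParams
    drugs: tuple[DrugParams, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        targets = [d.target_state for d in self.drugs]
        if len(set(targets)) != len(targets):
            raise ValueError("each cell-cycle state may be targeted by at most one drug")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in model")

    def drug(self, name: str) -> DrugParams:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(f"drug {name!r} not in model {self.name!r}")

    def with_drugs(self, drugs: Sequence[DrugParams]) -> "CellLineModel":
        return CellLineModel(self.name, self.base, tuple(drugs))


def transition_inhibition(m_base: float, dose: float, ec50: float, hill_n: float) -> float:
    """Inhibited transition probability ``m_base * (1 - D^n/(EC50^n + D^n))``."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if dose == 0:
        return m_base
    ratio = (dose / ec50) ** hill_n
    return m_base * (1.0 - ratio / (1.0 + ratio))


def death_rate(dose: float, emax_phi: float, ec50_phi: float) -> float:
    """Saturating drug-induced hourly death probability (Hill coefficient 1)."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    ratio = dose / ec50_phi
    return emax_phi * ratio / (1.0 + ratio)


def effective_rates(
    model: CellLineModel, doses: DoseAssignment
) -> tuple[TransitionParams, DeathRates]:
    """Per-state transition and death probabilities under a dose assignment.

    Doses map drug name -> uM; a drug absent from the map contributes dose 0.
    Each state's rates depend only on the dose of the drug targeting it.
    """
    unknown = set(doses) - {d.name for d in model.drugs}
    if unknown:
        raise KeyError(f"doses given for drugs not in model: {sorted(unknown)}")
    m = list(model.base.as_array())
    phi = [0.0, 0.0, 0.0]
    for drug in model.drugs:
        dose = float(doses.get(drug.name, 0.0))
        i = drug.target_state - 1
        m[i] = transition_inhibition(m[i], dose, drug.ec50, drug.hill_n)
        phi[i] = death_rate(dose, drug.emax_phi, drug.ec50_phi)
        if m[i] + phi[i] > 1.0 + 1e-12:
            raise ValueError(
                f"{drug.name} at {dose} uM gives m+phi > 1 in state {drug.target_state}"
            )
    return TransitionParams(*m), DeathRates(*phi)


def _stacked_matrix_power(mats: np.ndarray, k: int) -> np.ndarray:
    """Binary exponentiation of a stack of square matrices."""
    result = np.broadcast_to(np.eye(mats.shape[-1]), mats.shape).copy()
    base = mats.copy()
    while k:
        if k & 1:
            result = base @ result
        base = base @ base
        k >>= 1
    return result


def relative_cell_counts(
    model: CellLineModel,
    assignments: Sequence[DoseAssignment],
    horizon: int = 72,
) -> np.ndarray:
    """Vectorized relative cell counts for many dose assignments.

    Treated and control populations both start from the no-drug stationary
    composition; the returned ratio is treated total / control total at the
    horizon.
    """
    if not float(horizon).is_integer() or horizon < 0:
        raise ValueError("horizon must be a nonnegative integer number of hours")
    horizon = int(horizon)
    _, x0 = growth_eigensystem(model.base)
    mats = np.empty((len(assignments) + 1, 3, 3))
    mats[0] = update_matrix(model.base, NO_DEATH)
    for j, doses in enumerate(assignments):
        params, death = effective_rates(model, doses)
        mats[j + 1] = update_matrix(params, death)
    powers = _stacked_matrix_power(mats, horizon)
    totals = (powers @ x0).sum(axis=1)
    return totals[1:] / totals[0]


def relative_cell_count(
    model: CellLineModel, doses: DoseAssignment, horizon: int = 72
) -> float:
    """Treated / control total live-cell count at the horizon (72 h default)."""
    return float(relative_cell_counts(model, [doses], horizon=horizon)[0])
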