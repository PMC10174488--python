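"""Synthetic 96-well plate generator for the full analysis pipeline.

Emulates the wet-lab workflow behind the dose-response data: 500 cells are
seeded per well, settle overnight to the stationary cell-cycle composition,
are dosed, and after 72 h all nuclei are counted via a total stain
(Hoechst) and dead nuclei via a dead-cell stain (propidium iodide); the
live count is their difference.  Single-drug plates use ten doses in
biological duplicate with technical triplicates; combination plates use an
8x8 dose grid in biological triplicate.

Cell fate is sampled exactly: each hour every cell independently stays,
transitions, or dies with the model's per-state probabilities (multinomial
draws), so the expectation over wells equals the deterministic engine.
Measurement noise on top of the birth-death sampling: each nucleus is
detected with probability ``detection_p`` modulated by a per-well
multiplicative lognormal factor, and only a fraction of cumulative dead
cells remains attached to be stained.  All randomness derives from one
user seed via ``numpy.random.SeedSequence`` spawning (one child stream per
well, in layout order), so a plate is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    CELL_LINE_CONSTRAINTS,
    DRUG_NAMES,
    combination_doses_uM,
    reference_model,
    single_drug_doses_uM,
)
from .growth_calibration import GrowthConstraints
from .pharmacodynamics import CellLineModel, effective_rates
from .state_network import DeathRates, NO_DEATH, TransitionParams, growth_eigensystem

__all__ = [
    "PlateSpec",
    "WellRecord",
    "stochastic_simulate",
    "generate_plate",
    "single_drug_plate",
    "combination_plate",
    "end_to_end_fixture",
    "EndToEndFixture",
]


def stochastic_simulate(
    params: TransitionParams,
    death: DeathRates = NO_DEATH,
    x0: Sequence[int] = (500, 0, 0),
    horizon: int = 72,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-count sampling of the hourly jump process.

    Each hour the cells of state ``i`` are partitioned by a multinomial
    draw among {stay, transition, die} with probabilities
    (1 - m_i - phi_i, m_i, phi_i); a transitioning G2/M cell contributes
    two G0/G1 daughters.  Returns the (horizon+1, 3) integer trajectory and
    the cumulative dead count per time point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x0, dtype=np.int64)
    if x.shape != (3,) or np.any(x < 0):
        raise ValueError("x0 must be three nonnegative integer counts")
    m = params.as_array()
    phi = death.as_array()
    stay = 1.0 - m - phi
    if np.any(stay < -1e-12):
        raise ValueError("m_i + phi_i must not exceed 1")
    probs = np.clip(np.stack([stay, m, phi], axis=1), 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)

    traj = np.zeros((int(horizon) + 1, 3), dtype=np.int64)
    dead = np.zeros(int(horizon) + 1, dtype=np.int64)
    traj[0] = x
    for t in range(int(horizon)):
        draws = [rng.multinomial(int(x[i]), probs[i]) for i in range(3)]
        died = draws[0][2] + draws[1][2] + draws[2][2]
        x = np.array(
            [
                draws[0][0] + 2 * draws[2][1],
                draws[1][0] + draws[0][1],
                draws[2][0] + draws[1][1],
            ],
            dtype=np.int64,
        )
        traj[t + 1] = x
        dead[t + 1] = dead[t] + died
    return traj, dead


@dataclass(frozen=True)
class PlateSpec:
    """Everything needed to synthesize one plate reproducibly."""

    model: CellLineModel  # ground truth
    layout: Literal["single_drug", "combination"]
    drugs: tuple[str, ...]  # one drug (single_drug) or two (combination)
    doses_a: np.ndarray  # includes the 0 control
    doses_b: np.ndarray | None = None
    seeded_cells: int = 500
    horizon: int = 72
    n_bio: int = 2
    n_tech: int = 3
    detection_p: float = 0.95
    noise_cv: float = 0.10
    dead_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses_a", np.asarray(self.doses_a, dtype=float))
        if self.doses_b is not None:
            object.__setattr__(self, "doses_b", np.asarray(self.doses_b, dtype=float))
        if self.layout == "single_drug" and len(self.drugs) != 1:
            raise ValueError("single_drug layout takes exactly one drug")
        if self.layout == "combination":
            if len(self.drugs) != 2 or self.doses_b is None:
                raise ValueError("combination layout takes two drugs and doses_b")
        if self.seed is None:
            raise ValueError("a seed is mandatory for plate generation")


@dataclass(frozen=True)
class WellRecord:
    """One well's dose assignment and stain counts."""

    well: str
    doses: dict[str, float]
    bio_rep: int
    tech_rep: int
    hoechst_count: int
    pi_count: int

    @property
    def live_count(self) -> int:
        return self.hoechst_count - self.pi_count


def _measure_well(
    model: CellLineModel,
    doses: dict[str, float],
    spec: PlateSpec,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Simulate one well and return (hoechst, pi) counts."""
    params, death = effective_rates(model, doses)
    _, stationary = growth_eigensystem(model.base)
    x0 = rng.multinomial(spec.seeded_cells, stationary)
    traj, dead = stochastic_simulate(params, death, x0, spec.horizon, seed=rng)
    live = int(traj[-1].sum())
    dead_retained = int(rng.binomial(int(dead[-1]), spec.dead_retention))
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        factor = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma)
    else:
        factor = 1.0
    p_eff = float(np.clip(spec.detection_p * factor, 0.0, 1.0))
    live_detected = int(rng.binomial(live, p_eff))
    pi_count = int(rng.binomial(dead_retained, p_eff))
    return live_detected + pi_count, pi_count


def _well_assignments(spec: PlateSpec):
    """Layout order defining the per-well seed-stream derivation."""
    wells = []
    if spec.layout == "single_drug":
        drug = spec.drugs[0]
        for bio in range(1, spec.n_bio + 1):
            for tech in range(1, spec.n_tech + 1):
                for k, dose in enumerate(spec.doses_a):
                    wells.append((f"b{bio}t{tech}d{k}", {drug: float(dose)}, bio, tech))
    else:
        da, db = spec.drugs
        for bio in range(1, spec.n_bio + 1):
            for i, dose_a in enumerate(spec.doses_a):
                for j, dose_b in enumerate(spec.doses_b):
                    wells.append(
                        (
                            f"b{bio}r{i}c{j}",
                            {da: float(dose_a), db: float(dose_b)},
                            bio,
                            1,
                        )
                    )
    return wells


def generate_plate(spec: PlateSpec) -> pd.DataFrame:
    """Synthesize every well of a plate into a tidy table.

    Columns: cell_line, drug doses (``drug``/``dose_uM`` for single-drug
    layouts, ``drug_a``/``dose_a_uM``/``drug_b``/``dose_b_uM`` for
    combinations), replicate ids, stain counts, live counts, and the
    relative count normalized to the mean vehicle-control live count within
    the same biological replicate.
    """
    wells = _well_assignments(spec)
    streams = np.random.SeedSequence(spec.seed).spawn(len(wells))
    records = []
    for (well_id, doses, bio, tech), stream in zip(wells, streams):
        rng = np.random.default_rng(stream)
        hoechst, pi = _measure_well(spec.model, doses, spec, rng)
        rec = WellRecord(well_id, doses, bio, tech, hoechst, pi)
        row = {
            "cell_line": spec.model.name,
            "well": rec.well,
            "bio_rep": bio,
            "tech_rep": tech,
            "replicate_id": f"b{bio}t{tech}",
            "hoechst_count": rec.hoechst_count,
            "pi_count": rec.pi_count,
            "live_count": rec.live_count,
        }
        if spec.layout == "single_drug":
            drug = spec.drugs[0]
            row["drug"] = drug
            row["dose_uM"] = doses[drug]
        else:
            row["drug_a"], row["drug_b"] = spec.drugs
            row["dose_a_uM"] = doses[spec.drugs[0]]
            row["dose_b_uM"] = doses[spec.drugs[1]]
        records.append(row)
    frame = pd.DataFrame(records)

    # Relative counts: normalize to the vehicle-control mean of each
    # biological replicate (all-zero dose wells).
    if spec.layout == "single_drug":
        is_control = frame["dose_uM"] == 0.0
    else:
        is_control = (frame["dose_a_uM"] == 0.0) & (frame["dose_b_uM"] == 0.0)
    control_mean = (
        frame[is_control].groupby("bio_rep")["live_count"].mean().rename("control_mean")
    )
    frame = frame.join(control_mean, on="bio_rep")
    frame["relative_count"] = frame["live_count"] / frame["control_mean"]
    return frame.drop(columns="control_mean")


def single_drug_plate(
    model: CellLineModel,
    drug: str,
    seed: int,
    doses: Sequence[float] | None = None,
    **overrides,
) -> pd.DataFrame:
    """Single-drug plate with the experimental layout (10 doses, 2 bio x 3 tech)."""
    spec = PlateSpec(
        model=model,
        layout="single_drug",
        drugs=(drug,),
        doses_a=single_drug_doses_uM() if doses is None else np.asarray(doses, float),
        seed=seed,
        **overrides,
    )
    return generate_plate(spec)


def combination_plate(
    model: CellLineModel,
    drug_a: str,
    drug_b: str,
    seed: int,
    doses_a: Sequence[float] | None = None,
    doses_b: Sequence[float] | None = None,
    **overrides,
) -> pd.DataFrame:
    """8x8 combination plate in biological triplicate."""
    overrides.setdefault("n_bio", 3)
    overrides.setdefault("n_tech", 1)
    spec = PlateSpec(
        model=model,
        layout="combination",
        drugs=(drug_a, drug_b),
        doses_a=combination_doses_uM(drug_a) if doses_a is None else np.asarray(doses_a, float),
        doses_b=combination_doses_uM(drug_b) if doses_b is None else np.asarray(doses_b, float),
        seed=seed,
        **overrides,
    )
    return generate_plate(spec)


@dataclass(frozen=True)
class EndToEndFixture:
    """One-call synthetic dataset driving the whole pipeline."""

    cell_line: str
    constraints: GrowthConstraints
    truth: CellLineModel
    single_drug: dict[str, pd.DataFrame]  # drug -> tidy plate
    combinations: dict[tuple[str, str], pd.DataFrame]  # (drug_a, drug_b) -> tidy plate


def end_to_end_fixture(seed: int, cell_line: str = "U87", **plate_overrides) -> EndToEndFixture:
    """Generate growth constraints, single-drug plates for all three drugs,
    and the three pairwise combination plates from one ground-truth model."""
    constraints = CELL_LINE_CONSTRAINTS[cell_line]
    truth = reference_model(cell_line)
    children = np.random.SeedSequence(seed).spawn(6)

    def child_seed(k: int) -> int:
        return int(children[k].generate_state(1)[0] % 2**31)

    singles = {
        drug: single_drug_plate(truth, drug, seed=child_seed(k), **plate_overrides)
        for k, drug in enumerate(DRUG_NAMES)
    }
    pairs = [
        ("Abemaciclib", "PD0325901"),
        ("Abemaciclib", "TAK-960"),
        ("PD0325901", "TAK-960"),
    ]
    combos = {
        pair: combination_plate(truth, *pair, seed=child_seed(3 + k), **plate_overrides)
        for k, pair in enumerate(pairs)
    }
    return EndToEndFixture(
        cell_line=cell_line,
        constraints=constraints,
        truth=truth,
        single_drug=singles,
        combinations=combos,
    )
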