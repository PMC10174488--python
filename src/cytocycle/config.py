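"""Run configuration: YAML schema and validated defaults.

The default configuration reproduces the published analysis settings:
U87/U251 growth constraints with their literature min/max variants, the
fixed drug-to-state mapping, the experimental dose series, 72-h horizon,
death terms enabled, and the standard fitting/EOB options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datasets import (
    CELL_LINE_CONSTRAINTS,
    CONSTRAINT_VARIANTS,
    DRUG_TARGET_STATE,
    combination_doses_uM,
    single_drug_doses_uM,
)
from .growth_calibration import GrowthConstraints

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass
class RunConfig:
    """Validated pipeline settings."""

    cell_lines: dict[str, GrowthConstraints]
    constraint_variants: dict[str, dict[str, GrowthConstraints]]
    drug_targets: dict[str, int]
    single_drug_doses: np.ndarray
    combo_doses: dict[str, np.ndarray]
    seed: int = 0
    horizon: int = 72
    calibration_starts: int = 5
    fit_starts: int = 20
    include_death: bool = True
    eob_include_zero_dose_cells: bool = True
    single_drug_csv: str | None = None  # measured data; None -> synthetic
    combination_csv: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for drug, state in self.drug_targets.items():
            if state not in (1, 2, 3):
                raise ValueError(f"drug {drug!r} maps to invalid state {state!r}")
        self.single_drug_doses = np.asarray(self.single_drug_doses, dtype=float)
        if self.horizon <= 0 or int(self.horizon) != self.horizon:
            raise ValueError("horizon must be a positive integer number of hours")
        self.combo_doses = {k: np.asarray(v, dtype=float) for k, v in self.combo_doses.items()}
        missing = set(self.combo_doses) - set(self.drug_targets)
        if missing:
            raise ValueError(f"combo doses given for unmapped drugs: {sorted(missing)}")


def default_config(**overrides) -> RunConfig:
    cfg = RunConfig(
        cell_lines=dict(CELL_LINE_CONSTRAINTS),
        constraint_variants={k: dict(v) for k, v in CONSTRAINT_VARIANTS.items()},
        drug_targets=dict(DRUG_TARGET_STATE),
        single_drug_doses=single_drug_doses_uM(),
        combo_doses={d: combination_doses_uM(d) for d in DRUG_TARGET_STATE},
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


def _constraints_from_mapping(entry: dict) -> GrowthConstraints:
    return GrowthConstraints(float(entry["doubling_time_h"]), tuple(entry["ratios"]))


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration, filling unset fields with defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    overrides: dict = {}
    if "cell_lines" in raw:
        cell_lines = {}
        variants: dict[str, dict[str, GrowthConstraints]] = {}
        for name, entry in raw["cell_lines"].items():
            cell_lines[name] = _constraints_from_mapping(entry)
            for tag in ("min", "max"):
                if tag in entry:
                    variants.setdefault(name, {})[tag] = _constraints_from_mapping(entry[tag])
        overrides["cell_lines"] = cell_lines
        overrides["constraint_variants"] = variants
    if "drug_targets" in raw:
        overrides["drug_targets"] = {k: int(v) for k, v in raw["drug_targets"].items()}
    if "single_drug_doses_uM" in raw:
        overrides["single_drug_doses"] = raw["single_drug_doses_uM"]
    if "combo_doses_uM" in raw:
        overrides["combo_doses"] = raw["combo_doses_uM"]
    for key in (
        "seed",
        "horizon",
        "calibration_starts",
        "fit_starts",
        "include_death",
        "eob_include_zero_dose_cells",
        "single_drug_csv",
        "combination_csv",
        "out_dir",
    ):
        if key in raw:
            overrides[key] = raw[key]
    return default_config(**overrides)
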