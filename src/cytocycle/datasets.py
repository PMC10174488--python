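"""Published growth constraints, best-fit drug parameters and dose series.

Built-in reference values for the two glioma cell lines (U87, U251) and the
three cell-cycle-targeted inhibitors studied with this model:

* PD0325901 — MEK1/2 inhibitor, blocks the G0/G1 exit (state 1)
* Abemaciclib — CDK4/6 inhibitor, blocks the lateG1/S exit (state 2)
* TAK-960 — PLK1 inhibitor, blocks the G2/M exit (state 3)

These literature-derived constants serve as ground truth for synthetic-data
generation and as defaults for the pipeline; they are inputs, not outputs,
of this package.
"""

from __future__ import annotations

import numpy as np

from .growth_calibration import GrowthConstraints
from .pharmacodynamics import CellLineModel, DrugParams
from .state_network import TransitionParams

__all__ = [
    "CELL_LINE_CONSTRAINTS",
    "CONSTRAINT_VARIANTS",
    "DRUG_TARGET_STATE",
    "DRUG_NAMES",
    "drug_params",
    "drug_params_table",
    "single_drug_doses_uM",
    "combination_doses_uM",
    "reference_model",
]

#: Doubling time (h) and steady-state phase fractions per cell line.
CELL_LINE_CONSTRAINTS: dict[str, GrowthConstraints] = {
    "U87": GrowthConstraints(31.13, (0.602, 0.235, 0.163)),
    "U251": GrowthConstraints(24.93, (0.581, 0.225, 0.194)),
}

#: Extreme literature values for the growth constraints (sensitivity sweeps).
CONSTRAINT_VARIANTS: dict[str, dict[str, GrowthConstraints]] = {
    "U87": {
        "max": GrowthConstraints(37.1, (0.668, 0.263, 0.069)),
        "min": GrowthConstraints(25.5, (0.54, 0.23, 0.23)),
    },
    "U251": {
        "max": GrowthConstraints(27.8, (0.716, 0.204, 0.08)),
        "min": GrowthConstraints(23.0, (0.482, 0.237, 0.281)),
    },
}

#: Which cell-cycle state each drug's action maps onto.
DRUG_TARGET_STATE: dict[str, int] = {
    "PD0325901": 1,
    "Abemaciclib": 2,
    "TAK-960": 3,
}

DRUG_NAMES = tuple(DRUG_TARGET_STATE)

# Best-fit dose-response parameters: (ec50_uM, hill_n, emax_phi_per_h, ec50_phi_uM).
_DRUG_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "U87": {
        "PD0325901": (0.10, 0.50, 0.011, 0.40),
        "Abemaciclib": (0.01, 0.65, 0.0028, 0.033),
        "TAK-960": (0.0073, 2.88, 0.0025, 0.28),
    },
    "U251": {
        "PD0325901": (0.56, 0.40, 0.034, 2.77),
        "Abemaciclib": (0.19, 0.76, 0.026, 0.042),
        "TAK-960": (0.0025, 1.69, 0.022, 0.0070),
    },
}


def drug_params(cell_line: str, drug: str) -> DrugParams:
    """Published best-fit :class:`DrugParams` for one cell line / drug."""
    ec50, n, emax_phi, ec50_phi = _DRUG_PARAMS[cell_line][drug]
    return DrugParams(
        name=drug,
        target_state=DRUG_TARGET_STATE[drug],
        ec50=ec50,
        hill_n=n,
        emax_phi=emax_phi,
        ec50_phi=ec50_phi,
    )


def drug_params_table():
    """All published drug parameters as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for cell_line, drugs in _DRUG_PARAMS.items():
        for drug, (ec50, n, emax_phi, ec50_phi) in drugs.items():
            rows.append(
                {
                    "cell_line": cell_line,
                    "drug": drug,
                    "target_state": DRUG_TARGET_STATE[drug],
                    "ec50_uM": ec50,
                    "hill_n": n,
                    "emax_phi_per_h": emax_phi,
                    "ec50_phi_uM": ec50_phi,
                }
            )
    return pd.DataFrame(rows)


def single_drug_doses_uM(n_doses: int = 9, top_uM: float = 10.0, factor: float = 3.16) -> np.ndarray:
    """Single-drug assay dose series in uM, ascending, vehicle control first.

    Defaults to the experimental series: nine 3.16-fold dilutions from a
    10 uM top dose (~1 nM lowest) plus the dose-0 vehicle control, ten
    wells in all.
    """
    doses = top_uM / factor ** np.arange(n_doses - 1, -1, -1, dtype=float)
    return np.concatenate([[0.0], doses])


#: Combination-grid dose series (uM, ascending, 4-fold spacing incl. 0).
_COMBO_DOSES_NM = {
    "PD0325901": [0.0, 1.22, 4.88, 19.53, 78.13, 312.5, 1250.0, 5000.0],
    "Abemaciclib": [0.0, 1.22, 4.88, 19.53, 78.13, 312.5, 1250.0, 5000.0],
    "TAK-960": [0.0, 0.012, 0.049, 0.20, 0.78, 3.13, 12.5, 50.0],
}


def combination_doses_uM(drug: str) -> np.ndarray:
    """8-point combination dose series for one drug in uM (includes 0)."""
    return np.asarray(_COMBO_DOSES_NM[drug], dtype=float) / 1000.0


def reference_model(cell_line: str, base: TransitionParams | None = None) -> CellLineModel:
    """Cell-line model with published drug parameters.

    ``base`` defaults to a fresh calibration against the published growth
    constraints (deterministic given the default seed).
    """
    if base is None:
        from .growth_calibration import fit_transition_params

        base = fit_transition_params(CELL_LINE_CONSTRAINTS[cell_line], seed=0).params
    return CellLineModel(
        name=cell_line,
        base=base,
        drugs=tuple(drug_params(cell_line, d) for d in DRUG_NAMES),
    )
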