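"""Predict 8x8 pairwise combination response surfaces with no refitting.

Once the base transition probabilities are calibrated and each drug's four
dose-response parameters are fitted from single-drug data alone, a
combination surface is pure prediction: cell (i, j) is the 72-h relative
cell count under the simultaneous dose assignment (dose_a[i], dose_b[j]).
Because the two drugs act on different states, no interaction parameter
exists to tune — agreement with measured grids is the test of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pharmacodynamics import CellLineModel, relative_cell_counts
from .single_drug_fit import goodness_of_fit

__all__ = ["DoseGrid", "predict_grid", "compare_grids"]


@dataclass(frozen=True)
class DoseGrid:
    """A combination dose grid of relative cell counts.

    Rows index ``doses_a`` (ascending, first entry 0), columns ``doses_b``.
    ``se`` carries per-cell standard errors for measured grids.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    values: np.ndarray
    cell_line: str = ""
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if np.any(np.diff(da) <= 0) or np.any(np.diff(db) <= 0):
            raise ValueError("dose vectors must be strictly ascending")
        if vals.shape != (da.size, db.size):
            raise ValueError(
                f"values shape {vals.shape} does not match doses ({da.size}, {db.size})"
            )
        if np.any(vals <= 0):
            raise ValueError("relative counts must be positive")
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "values", vals)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != vals.shape:
                raise ValueError("se must match the shape of values")
            object.__setattr__(self, "se", se)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transposed(self) -> "DoseGrid":
        return DoseGrid(
            drug_a=self.drug_b,
            drug_b=self.drug_a,
            doses_a=self.doses_b,
            doses_b=self.doses_a,
            values=self.values.T,
            cell_line=self.cell_line,
            se=None if self.se is None else self.se.T,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: dose_a_uM, dose_b_uM, relative_count (+ se)."""
        ia, ib = np.meshgrid(
            np.arange(self.doses_a.size), np.arange(self.doses_b.size), indexing="ij"
        )
        out = pd.DataFrame(
            {
                "cell_line": self.cell_line,
                "drug_a": self.drug_a,
                "dose_a_uM": self.doses_a[ia.ravel()],
                "drug_b": self.drug_b,
                "dose_b_uM": self.doses_b[ib.ravel()],
                "relative_count": self.values.ravel(),
            }
        )
        if self.se is not None:
            out["se"] = self.se.ravel()
        return out


def predict_grid(
    model: CellLineModel,
    drug_a: str,
    drug_b: str,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    horizon: int = 72,
) -> DoseGrid:
    """Model-predicted relative-count surface over all dose pairs."""
    pa, pb = model.drug(drug_a), model.drug(drug_b)
    if pa.target_state == pb.target_state:
        raise ValueError(f"{drug_a} and {drug_b} target the same state; not a combination")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    assignments = [
        {drug_a: da, drug_b: db} for da in doses_a for db in doses_b
    ]
    values = relative_cell_counts(model, assignments, horizon=horizon).reshape(
        doses_a.size, doses_b.size
    )
    return DoseGrid(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=doses_a,
        doses_b=doses_b,
        values=values,
        cell_line=model.name,
    )


def compare_grids(
    predicted: DoseGrid, measured: DoseGrid, rtol: float = 1e-6
) -> tuple[float, pd.DataFrame]:
    """Pearson r over all paired cells, plus the paired scatter table."""
    for name, dp, dm in (
        ("doses_a", predicted.doses_a, measured.doses_a),
        ("doses_b", predicted.doses_b, measured.doses_b),
    ):
        if dp.shape != dm.shape or not np.allclose(dp, dm, rtol=rtol, atol=1e-12):
            bad = (
                np.nonzero(~np.isclose(dp, dm, rtol=rtol, atol=1e-12))[0]
                if dp.shape == dm.shape
                else "all"
            )
            raise ValueError(f"{name} mismatch between grids at positions {bad}")
    scatter = predicted.to_frame().rename(columns={"relative_count": "predicted"})
    scatter["measured"] = measured.values.ravel()
    r = goodness_of_fit(predicted.values.ravel(), measured.values.ravel())
    return r, scatter
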