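"""CSV readers/writers for plate-level dose-response data.

Two tidy long-form schemas are supported and auto-detected:

single-drug:  cell_line, drug, dose_uM, replicate_id, relative_count
combination:  cell_line, drug_a, dose_a_uM, drug_b, dose_b_uM,
              replicate_id, relative_count

Doses may instead be given in a ``dose``/``dose_a``/``dose_b`` column with
a ``dose_unit`` column (nM or uM); they are converted to uM on read.
Replicates are aggregated to means with sd/se.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .combination_prediction import DoseGrid
from .single_drug_fit import DoseResponseData

__all__ = [
    "read_plate_csv",
    "write_dose_response_csv",
    "write_grid_csv",
    "grid_from_tidy",
]

_UNIT_TO_UM = {"uM": 1.0, "um": 1.0, "µM": 1.0, "nM": 1e-3, "nm": 1e-3}


class PlateFormatError(ValueError):
    """Raised for malformed plate CSV files; names the offending rows."""


def _bad_rows(frame: pd.DataFrame, column: str) -> list[int]:
    values = pd.to_numeric(frame[column], errors="coerce")
    # +2: one for the header line, one for 0- vs 1-based indexing.
    return [int(i) + 2 for i in frame.index[values.isna() | np.isinf(values)]]


def _numeric(frame: pd.DataFrame, column: str, path) -> pd.Series:
    bad = _bad_rows(frame, column)
    if bad:
        raise PlateFormatError(
            f"{path}: non-numeric value in column {column!r} at line(s) {bad}"
        )
    return pd.to_numeric(frame[column])


def _convert_units(frame: pd.DataFrame, dose_col: str, out_col: str, path) -> pd.DataFrame:
    if out_col in frame.columns:
        frame[out_col] = _numeric(frame, out_col, path)
        return frame
    if dose_col in frame.columns and "dose_unit" in frame.columns:
        factors = frame["dose_unit"].map(_UNIT_TO_UM)
        if factors.isna().any():
            bad = [int(i) + 2 for i in frame.index[factors.isna()]]
            raise PlateFormatError(f"{path}: unknown dose_unit at line(s) {bad}")
        frame[out_col] = _numeric(frame, dose_col, path) * factors
        return frame
    raise PlateFormatError(
        f"{path}: need column {out_col!r} or {dose_col!r} plus 'dose_unit'"
    )


def read_plate_csv(path) -> list[DoseResponseData] | list[DoseGrid]:
    """Read a tidy plate CSV; dispatches on the columns present.

    Returns one :class:`DoseResponseData` per (cell_line, drug) for
    single-drug files, or one :class:`DoseGrid` (replicate-averaged, with
    per-cell SE) per (cell_line, drug_a, drug_b) for combination files.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if {"drug_a", "drug_b"} <= cols:
        frame = _convert_units(frame, "dose_a", "dose_a_uM", path)
        frame = _convert_units(frame, "dose_b", "dose_b_uM", path)
        return _read_combination(frame, path)
    if "drug" in cols:
        frame = _convert_units(frame, "dose", "dose_uM", path)
        return _read_single(frame, path)
    raise PlateFormatError(
        f"{path}: expected a 'drug' column (single-drug) or 'drug_a'/'drug_b' (combination)"
    )


def _require(frame: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required column(s) {missing}")


def _read_single(frame: pd.DataFrame, path) -> list[DoseResponseData]:
    _require(frame, ["cell_line", "drug", "dose_uM", "replicate_id", "relative_count"], path)
    frame["relative_count"] = _numeric(frame, "relative_count", path)
    if (frame["relative_count"] < 0).any():
        bad = [int(i) + 2 for i in frame.index[frame["relative_count"] < 0]]
        raise PlateFormatError(f"{path}: negative relative_count at line(s) {bad}")
    dup = frame.duplicated(["cell_line", "drug", "dose_uM", "replicate_id"], keep=False)
    if "well" in frame.columns:
        dup = frame.duplicated(["cell_line", "drug", "well"], keep=False)
        if dup.any():
            bad = [int(i) + 2 for i in frame.index[dup]]
            raise PlateFormatError(f"{path}: duplicate wells at line(s) {bad}")
    out = []
    for (cell_line, drug), sub in frame.groupby(["cell_line", "drug"], sort=False):
        tidy = sub[["dose_uM", "replicate_id", "relative_count"]]
        out.append(DoseResponseData.from_replicates(drug, cell_line, tidy))
    return out


def _read_combination(frame: pd.DataFrame, path) -> list[DoseGrid]:
    _require(
        frame,
        ["cell_line", "drug_a", "dose_a_uM", "drug_b", "dose_b_uM", "replicate_id", "relative_count"],
        path,
    )
    frame["relative_count"] = _numeric(frame, "relative_count", path)
    out = []
    for (cell_line, drug_a, drug_b), sub in frame.groupby(
        ["cell_line", "drug_a", "drug_b"], sort=False
    ):
        out.append(grid_from_tidy(sub, cell_line, drug_a, drug_b))
    return out


def grid_from_tidy(tidy: pd.DataFrame, cell_line: str, drug_a: str, drug_b: str) -> DoseGrid:
    """Average replicates of a long-form combination table into a DoseGrid."""
    g = tidy.groupby(["dose_a_uM", "dose_b_uM"])["relative_count"]
    mean = g.mean().unstack()
    n = g.count().unstack()
    sd = g.std(ddof=1).unstack()
    se = (sd / np.sqrt(n)).to_numpy()
    return DoseGrid(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=mean.index.to_numpy(dtype=float),
        doses_b=mean.columns.to_numpy(dtype=float),
        values=mean.to_numpy(),
        cell_line=cell_line,
        se=None if np.all(np.isnan(se)) else se,
    )


def write_dose_response_csv(tidy_or_data, path) -> None:
    """Write single-drug replicate data in the reader schema."""
    if isinstance(tidy_or_data, DoseResponseData):
        d = tidy_or_data
        if d.replicates is not None:
            frame = d.replicates.copy()
            frame.insert(0, "cell_line", d.cell_line)
            frame.insert(1, "drug", d.drug)
        else:
            frame = pd.DataFrame(
                {
                    "cell_line": d.cell_line,
                    "drug": d.drug,
                    "dose_uM": d.doses,
                    "replicate_id": "mean",
                    "relative_count": d.mean_counts,
                }
            )
    else:
        frame = tidy_or_data
    pd.DataFrame(frame).to_csv(path, index=False)


def write_grid_csv(grid_or_tidy, path, matrix: bool = False) -> None:
    """Write combination data; ``matrix=True`` emits the 8x8 layout instead."""
    if isinstance(grid_or_tidy, DoseGrid):
        if matrix:
            frame = pd.DataFrame(
                grid_or_tidy.values,
                index=pd.Index(grid_or_tidy.doses_a, name=f"{grid_or_tidy.drug_a}_uM"),
                columns=pd.Index(grid_or_tidy.doses_b, name=f"{grid_or_tidy.drug_b}_uM"),
            )
            frame.to_csv(path)
            return
        frame = grid_or_tidy.to_frame()
        frame["replicate_id"] = "mean"
    else:
        frame = grid_or_tidy
    pd.DataFrame(frame).to_csv(path, index=False)
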