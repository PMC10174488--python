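"""Robust excess-over-Bliss synergy scoring for 8x8 combination grids.

Raw excess-over-Bliss is sensitive to noise in individual wells, so the
inhibition matrix (y = 1 - relative cell count) is first smoothed by
fitting a four-parameter logistic (4PL) curve

    y(D) = Emin + Emax * (D/EC50)^n / (1 + (D/EC50)^n)

to every row and every column of the grid; each cell's fitted inhibition
y_AB is the average of its row-fit and column-fit values.  The Bliss
independence null for non-interacting drugs is

    y_Bliss = y_A + y_B - y_A * y_B,

with the single-agent inhibitions y_A, y_B read off the fitted surface at
the zero-dose column/row.  The excess over Bliss EOB = y_AB - y_Bliss is
positive for synergy and negative for antagonism; the grid is summarized
by its mean EOB with a standard error across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .combination_prediction import DoseGrid

__all__ = [
    "FourPLFit",
    "EOBResult",
    "inhibition_from_counts",
    "four_pl",
    "fit_4pl",
    "fitted_surface",
    "bliss_independence",
    "eob_surface",
    "eob_from_grid",
]


def four_pl(dose, e_min: float, e_max: float, ec50: float, hill_n: float):
    """4PL logistic; evaluates to exactly ``e_min`` at dose 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill_n, 0.0)
    return e_min + e_max * ratio / (1.0 + ratio)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters for one row or column of an inhibition grid."""

    e_min: float
    e_max: float
    ec50: float
    hill_n: float
    doses: np.ndarray
    fitted: np.ndarray
    sse: float
    converged: bool
    degenerate: bool = False

    def __call__(self, dose):
        return four_pl(dose, self.e_min, self.e_max, self.ec50, self.hill_n)


def inhibition_from_counts(grid: DoseGrid) -> np.ndarray:
    """Inhibition effect y = 1 - relative cell count, cellwise.

    Counts above 1 (stimulation) map to negative inhibition unchanged.
    """
    return 1.0 - grid.values


def fit_4pl(
    doses: Sequence[float],
    inhibitions: Sequence[float],
    seed: int | None = 0,
    n_starts: int = 10,
    e_min_bounds: tuple[float, float] = (-0.5, 1.0),
    e_max_bounds: tuple[float, float] = (0.0, 1.5),
    hill_bounds: tuple[float, float] = (1e-3, 10.0),
) -> FourPLFit:
    """Multi-start least-squares 4PL fit to one dose series.

    EC50 is bounded to [min nonzero dose / 10, max dose * 10].  A constant
    series is returned as a flat fit (e_max = 0) flagged ``degenerate``.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if doses.shape != y.shape or doses.ndim != 1:
        raise ValueError("doses and inhibitions must be matching 1-D arrays")
    nonzero = doses[doses > 0]
    if nonzero.size == 0:
        raise ValueError("need at least one nonzero dose")
    ec50_bounds = (float(nonzero.min()) / 10.0, float(doses.max()) * 10.0)

    if np.ptp(y) < 1e-12:
        c = float(y[0])
        fitted = np.full_like(y, c)
        return FourPLFit(
            e_min=c, e_max=0.0, ec50=float(np.sqrt(ec50_bounds[0] * ec50_bounds[1])),
            hill_n=1.0, doses=doses, fitted=fitted, sse=0.0,
            converged=True, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    log_ec50_bounds = np.log10(ec50_bounds)

    def residuals(theta):
        e_min, e_max, log_ec50, hill_n = theta
        return four_pl(doses, e_min, e_max, 10.0**log_ec50, hill_n) - y

    lower = [e_min_bounds[0], e_max_bounds[0], log_ec50_bounds[0], hill_bounds[0]]
    upper = [e_min_bounds[1], e_max_bounds[1], log_ec50_bounds[1], hill_bounds[1]]
    best = None
    span = float(np.clip(y.max() - y.min(), *e_max_bounds))
    base_start = [float(np.clip(y[np.argmin(doses)], *e_min_bounds)), span]
    for k in range(max(1, int(n_starts))):
        if k == 0:  # data-informed start first, then random exploration
            start = base_start + [float(np.log10(np.median(nonzero))), 1.0]
        else:
            start = [
                rng.uniform(*e_min_bounds),
                rng.uniform(*e_max_bounds),
                rng.uniform(*log_ec50_bounds),
                rng.uniform(0.3, 3.0),
            ]
        try:
            fit = least_squares(
                residuals, start, bounds=(lower, upper),
                xtol=1e-12, ftol=1e-14, gtol=1e-12,
            )
        except Exception:
            continue
        sse = float(np.sum(fit.fun**2))
        if best is None or sse < best[0]:
            best = (sse, fit.x, fit.status > 0)
    if best is None:
        raise RuntimeError("all 4PL starts failed")
    sse, theta, ok = best
    e_min, e_max, log_ec50, hill_n = theta
    ec50 = 10.0**log_ec50
    return FourPLFit(
        e_min=float(e_min), e_max=float(e_max), ec50=float(ec50), hill_n=float(hill_n),
        doses=doses, fitted=four_pl(doses, e_min, e_max, ec50, hill_n),
        sse=sse, converged=bool(ok),
    )


def fitted_surface(
    inhibition: np.ndarray,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    seed: int | None = 0,
    n_starts: int = 10,
) -> tuple[np.ndarray, list[FourPLFit], list[FourPLFit]]:
    """Row/column-averaged 4PL-smoothed inhibition surface.

    Fits a 4PL along every row (dose_b varies) and every column (dose_a
    varies) — 16 fits for an 8x8 grid — and averages the two fitted values
    at each cell.  Returns the surface plus the row and column fits.
    """
    inhibition = np.asarray(inhibition, dtype=float)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    n_a, n_b = inhibition.shape
    if (n_a, n_b) != (doses_a.size, doses_b.size):
        raise ValueError("inhibition matrix shape must match the dose vectors")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_a + n_b)]
    row_fits = [
        fit_4pl(doses_b, inhibition[i, :], seed=seeds[i], n_starts=n_starts)
        for i in range(n_a)
    ]
    col_fits = [
        fit_4pl(doses_a, inhibition[:, j], seed=seeds[n_a + j], n_starts=n_starts)
        for j in range(n_b)
    ]
    row_vals = np.vstack([f.fitted for f in row_fits])  # (n_a, n_b)
    col_vals = np.vstack([f.fitted for f in col_fits]).T  # (n_a, n_b)
    return (row_vals + col_vals) / 2.0, row_fits, col_fits


def bliss_independence(y_a, y_b):
    """Bliss null inhibition for independently acting drugs."""
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    return y_a + y_b - y_a * y_b


@dataclass(frozen=True)
class EOBResult:
    """Excess-over-Bliss surface and its summary score for one grid."""

    drug_a: str
    drug_b: str
    cell_line: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    surface: np.ndarray  # fitted y_AB
    y_a: np.ndarray  # single-agent fitted inhibition of drug A (rows)
    y_b: np.ndarray  # single-agent fitted inhibition of drug B (columns)
    bliss: np.ndarray
    eob: np.ndarray
    mean_eob: float
    se_eob: float
    mean_eob_interior: float  # both doses nonzero (excludes row/column 0)
    se_eob_interior: float
    row_fits: tuple[FourPLFit, ...] = ()
    col_fits: tuple[FourPLFit, ...] = ()

    @property
    def n_degenerate_fits(self) -> int:
        return sum(f.degenerate for f in self.row_fits + self.col_fits)


def eob_surface(
    surface: np.ndarray,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    drug_a: str = "A",
    drug_b: str = "B",
    cell_line: str = "",
    row_fits: Sequence[FourPLFit] = (),
    col_fits: Sequence[FourPLFit] = (),
    y_a: Sequence[float] | None = None,
    y_b: Sequence[float] | None = None,
) -> EOBResult:
    """EOB matrix and mean +/- SE summary from a fitted inhibition surface.

    By default the single-agent inhibitions come from the averaged surface
    itself: y_A from the dose_b = 0 column, y_B from the dose_a = 0 row;
    pass ``y_a``/``y_b`` to use externally fitted single-agent curves
    instead.  The summary mean runs over all cells (zero-dose cells
    contribute ~0); the ``interior`` variants restrict to cells where both
    doses are nonzero.
    """
    surface = np.asarray(surface, dtype=float)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if doses_a[0] != 0 or doses_b[0] != 0:
        raise ValueError("dose vectors must start at the 0 control")
    y_a = surface[:, 0] if y_a is None else np.asarray(y_a, dtype=float)
    y_b = surface[0, :] if y_b is None else np.asarray(y_b, dtype=float)
    bliss = bliss_independence(y_a[:, None], y_b[None, :])
    eob = surface - bliss
    interior = eob[1:, 1:]
    return EOBResult(
        drug_a=drug_a,
        drug_b=drug_b,
        cell_line=cell_line,
        doses_a=doses_a,
        doses_b=doses_b,
        surface=surface,
        y_a=y_a,
        y_b=y_b,
        bliss=bliss,
        eob=eob,
        mean_eob=float(eob.mean()),
        se_eob=float(eob.std(ddof=1) / np.sqrt(eob.size)),
        mean_eob_interior=float(interior.mean()),
        se_eob_interior=float(interior.std(ddof=1) / np.sqrt(interior.size)),
        row_fits=tuple(row_fits),
        col_fits=tuple(col_fits),
    )


def eob_from_grid(grid: DoseGrid, seed: int | None = 0, n_starts: int = 10) -> EOBResult:
    """Full robust EOB pipeline for one relative-count grid."""
    inhibition = inhibition_from_counts(grid)
    surface, row_fits, col_fits = fitted_surface(
        inhibition, grid.doses_a, grid.doses_b, seed=seed, n_starts=n_starts
    )
    return eob_surface(
        surface,
        grid.doses_a,
        grid.doses_b,
        drug_a=grid.drug_a,
        drug_b=grid.drug_b,
        cell_line=grid.cell_line,
        row_fits=row_fits,
        col_fits=col_fits,
    )
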