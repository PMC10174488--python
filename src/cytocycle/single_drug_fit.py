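"""Fit per-drug dose-response parameters to 72-h relative cell counts.

For each drug four parameters are estimated — the transition-inhibition
EC50 and Hill coefficient, and (optionally) the death-term Emax_phi and
EC50_phi — by bounded multi-start least squares against the mean relative
cell count per dose, with the calibrated base transition probabilities held
fixed.  The death and no-death model variants are compared by AIC, with
log-likelihoods built from residuals normalized by the experimental
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, pearsonr

from .pharmacodynamics import CellLineModel, DrugParams, relative_cell_counts
from .state_network import TransitionParams

__all__ = [
    "DoseResponseData",
    "DrugFitResult",
    "fit_drug_params",
    "log_likelihood_normalized",
    "compare_aic",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class DoseResponseData:
    """Single-drug 72-h relative counts, aggregated over replicates."""

    drug: str
    cell_line: str
    doses: np.ndarray  # uM, includes the 0 control
    mean_counts: np.ndarray
    sd: np.ndarray | None = None
    se: np.ndarray | None = None
    replicates: pd.DataFrame | None = None  # tidy: dose_uM, replicate_id, relative_count

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        means = np.asarray(self.mean_counts, dtype=float)
        if doses.ndim != 1 or doses.shape != means.shape:
            raise ValueError("doses and mean_counts must be matching 1-D arrays")
        if len(np.unique(doses)) < 4:
            raise ValueError("need at least 4 distinct doses")
        if 0.0 not in doses:
            raise ValueError("the dose-0 vehicle control must be present")
        if np.any(means <= 0):
            raise ValueError("relative counts must be positive")
        order = np.argsort(doses)
        object.__setattr__(self, "doses", doses[order])
        object.__setattr__(self, "mean_counts", means[order])
        for name in ("sd", "se"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != doses.shape:
                    raise ValueError(f"{name} must match doses in length")
                object.__setattr__(self, name, v[order])

    @classmethod
    def from_replicates(cls, drug: str, cell_line: str, tidy: pd.DataFrame) -> "DoseResponseData":
        """Aggregate a tidy replicate table (dose_uM, replicate_id, relative_count)."""
        g = tidy.groupby("dose_uM")["relative_count"]
        mean = g.mean()
        sd = g.std(ddof=1)
        n = g.count()
        return cls(
            drug=drug,
            cell_line=cell_line,
            doses=mean.index.to_numpy(),
            mean_counts=mean.to_numpy(),
            sd=sd.to_numpy(),
            se=(sd / np.sqrt(n)).to_numpy(),
            replicates=tidy.reset_index(drop=True),
        )


@dataclass(frozen=True)
class DrugFitResult:
    """Best-fit drug parameters with goodness-of-fit bookkeeping."""

    params: DrugParams
    sse: float
    log_likelihood: float | None
    aic: float | None
    n_free_params: int
    residuals: np.ndarray
    predicted: np.ndarray
    include_death: bool
    data: DoseResponseData
    n_starts: int
    all_sse: tuple[float, ...]


def log_likelihood_normalized(
    residuals: np.ndarray, sds: np.ndarray, sd_floor: float = 0.0
) -> float:
    """Sum of standard-normal log densities of sd-normalized residuals."""
    residuals = np.asarray(residuals, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if sd_floor > 0:
        sds = np.maximum(sds, sd_floor)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive (set sd_floor)")
    return float(norm.logpdf(residuals / sds).sum())


def _predict(
    model: CellLineModel, drug: DrugParams, doses: np.ndarray, horizon: int
) -> np.ndarray:
    trial = model.with_drugs([drug])
    return relative_cell_counts(trial, [{drug.name: d} for d in doses], horizon=horizon)


def fit_drug_params(
    data: DoseResponseData,
    base: TransitionParams,
    include_death: bool = True,
    seed: int | None = 0,
    target_state: int | None = None,
    n_starts: int = 20,
    horizon: int = 72,
    sd_floor_frac: float = 0.01,
) -> DrugFitResult:
    """Multi-start least-squares fit of one drug's dose-response parameters.

    Free parameters are (ec50, hill_n) plus (emax_phi, ec50_phi) when
    ``include_death``.  EC50s are bounded to [1e-5, 1e3] uM and optimized in
    log10 space, hill_n to (0, 10], emax_phi to keep every state's retained
    fraction nonnegative.  Starting points: EC50s log-uniform over the
    nonzero dose range, hill_n uniform in [0.3, 3], emax_phi uniform over
    its range.  The fit target is the mean relative count per dose (plain
    SSE); sd-normalized residuals enter only the likelihood/AIC, with the
    sd floored at ``sd_floor_frac`` of the mean count.
    """
    if target_state is None:
        from .datasets import DRUG_TARGET_STATE

        try:
            target_state = DRUG_TARGET_STATE[data.drug]
        except KeyError:
            raise ValueError(
                f"unknown drug {data.drug!r}: pass target_state explicitly"
            ) from None
    rng = np.random.default_rng(seed)
    model = CellLineModel(data.cell_line, base)
    nonzero = data.doses[data.doses > 0]
    lo, hi = float(nonzero.min()), float(nonzero.max())
    emax_cap = float(1.0 - base.as_array().max())

    log_ec50_bounds = (np.log10(1e-5), np.log10(1e3))
    n_bounds = (1e-3, 10.0)

    def make_drug(theta: np.ndarray) -> DrugParams:
        if include_death:
            log_ec50, hill_n, emax_phi, log_ec50_phi = theta
            return DrugParams(
                data.drug, target_state, 10.0**log_ec50, hill_n,
                emax_phi=float(np.clip(emax_phi, 0.0, emax_cap)),
                ec50_phi=10.0**log_ec50_phi,
            )
        log_ec50, hill_n = theta
        return DrugParams(data.drug, target_state, 10.0**log_ec50, hill_n)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _predict(model, make_drug(theta), data.doses, horizon) - data.mean_counts

    if include_death:
        lower = [log_ec50_bounds[0], n_bounds[0], 0.0, log_ec50_bounds[0]]
        upper = [log_ec50_bounds[1], n_bounds[1], emax_cap, log_ec50_bounds[1]]
    else:
        lower = [log_ec50_bounds[0], n_bounds[0]]
        upper = [log_ec50_bounds[1], n_bounds[1]]

    best = None
    statuses: list[str] = []
    sses: list[float] = []
    for _ in range(max(1, int(n_starts))):
        start = [rng.uniform(np.log10(lo), np.log10(hi)), rng.uniform(0.3, 3.0)]
        if include_death:
            start += [rng.uniform(0.0, emax_cap), rng.uniform(np.log10(lo), np.log10(hi))]
        try:
            fit = least_squares(
                residuals, start, bounds=(lower, upper),
                xtol=1e-12, ftol=1e-14, gtol=1e-12,
            )
        except Exception as exc:
            statuses.append(f"failed: {exc}")
            sses.append(np.inf)
            continue
        sse = float(np.sum(fit.fun**2))
        statuses.append(f"ok (status {fit.status})")
        sses.append(sse)
        if best is None or sse < best[0]:
            best = (sse, fit.x)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(f"all {n_starts} starts failed; statuses: {statuses}")

    sse, theta = best
    drug = make_drug(theta)
    predicted = _predict(model, drug, data.doses, horizon)
    res = predicted - data.mean_counts
    log_l = aic = None
    n_free = 4 if include_death else 2
    if data.sd is not None and np.all(np.isfinite(data.sd)):
        floors = sd_floor_frac * data.mean_counts
        log_l = log_likelihood_normalized(res, np.maximum(data.sd, floors))
        aic = 2 * n_free - 2 * log_l
    return DrugFitResult(
        params=drug,
        sse=sse,
        log_likelihood=log_l,
        aic=aic,
        n_free_params=n_free,
        residuals=res,
        predicted=predicted,
        include_death=include_death,
        data=data,
        n_starts=int(n_starts),
        all_sse=tuple(sses),
    )


def _check_same_data(a: DoseResponseData, b: DoseResponseData) -> None:
    if (
        a.drug != b.drug
        or a.cell_line != b.cell_line
        or not np.array_equal(a.doses, b.doses)
        or not np.array_equal(a.mean_counts, b.mean_counts)
    ):
        raise ValueError(
            f"model variants fitted to different data: {a.cell_line}/{a.drug} vs {b.cell_line}/{b.drug}"
        )


def compare_aic(
    fits_death: Sequence[DrugFitResult], fits_nodeath: Sequence[DrugFitResult]
) -> float:
    """Pooled ΔAIC = AIC(death) - AIC(no death) across matched fits.

    Free-parameter counts are pooled (4 vs 2 per fit; 24 vs 12 over the six
    cell line / drug fits).  Negative values favor the death model.
    """
    if len(fits_death) != len(fits_nodeath):
        raise ValueError("need one death fit per no-death fit")
    k_d = k_n = 0
    ll_d = ll_n = 0.0
    for fd, fn in zip(fits_death, fits_nodeath):
        _check_same_data(fd.data, fn.data)
        if fd.log_likelihood is None or fn.log_likelihood is None:
            raise ValueError("AIC comparison requires per-dose standard deviations")
        k_d += fd.n_free_params
        k_n += fn.n_free_params
        ll_d += fd.log_likelihood
        ll_n += fn.log_likelihood
    return (2 * k_d - 2 * ll_d) - (2 * k_n - 2 * ll_n)


def goodness_of_fit(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(pearsonr(predicted, observed).statistic)
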