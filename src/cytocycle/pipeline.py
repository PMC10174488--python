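"""End-to-end orchestration: calibrate, fit singles, predict combos, score EOB.

``run_pipeline`` runs the four analysis stages in order for every cell
line in the configuration and returns (and optionally writes) a
machine-readable report.  Measured data come from CSV files when paths are
configured, otherwise from the synthetic plate generator seeded by the run
seed — so the whole pipeline runs without any external data.  Every seed
and solver setting used is logged into the report.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .bliss_synergy import eob_from_grid
from .combination_prediction import DoseGrid, compare_grids, predict_grid
from .config import RunConfig, default_config
from .datasets import drug_params
from .growth_calibration import fit_transition_params
from .pharmacodynamics import CellLineModel
from .plate_io import grid_from_tidy, read_plate_csv
from .single_drug_fit import DoseResponseData, DrugFitResult, compare_aic, fit_drug_params
from .synthetic_plates import combination_plate, single_drug_plate

logger = logging.getLogger("cytocycle")

__all__ = ["run_pipeline", "PAIRS"]

PAIRS = (
    ("Abemaciclib", "PD0325901"),
    ("Abemaciclib", "TAK-960"),
    ("PD0325901", "TAK-960"),
)


def _derived_seed(base: int, *keys: str) -> int:
    # zlib.crc32 is stable across processes (unlike builtin str hashing)
    entropy = [base] + [zlib.crc32(k.encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def _synthetic_singles(cfg: RunConfig, truth: CellLineModel) -> dict[str, DoseResponseData]:
    out = {}
    for drug in cfg.drug_targets:
        plate = single_drug_plate(
            truth, drug, seed=_derived_seed(cfg.seed, "single", truth.name, drug),
            doses=cfg.single_drug_doses,
        )
        out[drug] = DoseResponseData.from_replicates(
            drug, truth.name, plate[["dose_uM", "replicate_id", "relative_count"]]
        )
    return out


def _synthetic_combos(cfg: RunConfig, truth: CellLineModel) -> dict[tuple[str, str], DoseGrid]:
    out = {}
    for pair in PAIRS:
        plate = combination_plate(
            truth, *pair, seed=_derived_seed(cfg.seed, "combo", truth.name, *pair),
            doses_a=cfg.combo_doses[pair[0]], doses_b=cfg.combo_doses[pair[1]],
        )
        out[pair] = grid_from_tidy(plate, truth.name, *pair)
    return out


def _eob_summary(result) -> dict:
    return {
        "mean_eob": result.mean_eob,
        "se_eob": result.se_eob,
        "mean_eob_interior": result.mean_eob_interior,
        "se_eob_interior": result.se_eob_interior,
        "n_degenerate_fits": result.n_degenerate_fits,
    }


def run_pipeline(cfg: RunConfig | None = None, write: bool = True) -> dict:
    """Execute calibrate -> fit singles -> predict combos -> compare -> EOB.

    Returns the JSON-serializable report; with ``write=True`` also writes
    ``report.json`` plus parameter/comparison CSV tables under
    ``cfg.out_dir``.
    """
    cfg = cfg or default_config()
    report: dict = {
        "schema_version": 1,
        "settings": {
            "seed": cfg.seed,
            "horizon_h": cfg.horizon,
            "calibration_starts": cfg.calibration_starts,
            "fit_starts": cfg.fit_starts,
            "include_death": cfg.include_death,
            "solver_tolerances": {"xtol": 1e-12, "ftol": 1e-14, "gtol": 1e-12},
        },
        "cell_lines": {},
    }

    measured_singles: dict[tuple[str, str], DoseResponseData] = {}
    if cfg.single_drug_csv:
        for data in read_plate_csv(cfg.single_drug_csv):
            measured_singles[(data.cell_line, data.drug)] = data
    measured_combos: dict[tuple[str, str, str], DoseGrid] = {}
    if cfg.combination_csv:
        for grid in read_plate_csv(cfg.combination_csv):
            measured_combos[(grid.cell_line, grid.drug_a, grid.drug_b)] = grid

    all_death_fits: list[DrugFitResult] = []
    all_nodeath_fits: list[DrugFitResult] = []

    for cell_line, constraints in cfg.cell_lines.items():
        stage = f"[{cell_line}] growth calibration"
        logger.info(stage)
        try:
            calib = fit_transition_params(
                constraints, n_starts=cfg.calibration_starts, seed=cfg.seed
            )
        except Exception as exc:
            raise RuntimeError(f"{stage} failed: {exc}") from exc
        base = calib.params
        entry: dict = {
            "growth": {
                "doubling_time_h": constraints.doubling_time,
                "ratios": list(constraints.ratios),
                "fitted_m": [base.m1, base.m2, base.m3],
                "sse": calib.sse,
                "converged_unique": calib.converged_unique,
            },
            "drugs": {},
            "combinations": {},
        }

        # ground-truth model for synthetic data generation
        truth = CellLineModel(
            cell_line, base,
            tuple(drug_params(cell_line, d) for d in cfg.drug_targets),
        )
        singles = {
            drug: measured_singles.get((cell_line, drug)) for drug in cfg.drug_targets
        }
        if any(v is None for v in singles.values()):
            synth = _synthetic_singles(cfg, truth)
            singles = {d: singles[d] or synth[d] for d in singles}
            entry["growth"]["data_source"] = "synthetic"

        stage = f"[{cell_line}] single-drug fitting"
        logger.info(stage)
        fitted_drugs = []
        for drug, data in singles.items():
            try:
                fit = fit_drug_params(
                    data, base, include_death=cfg.include_death,
                    seed=_derived_seed(cfg.seed, "fit", cell_line, drug),
                    target_state=cfg.drug_targets[drug], n_starts=cfg.fit_starts,
                    horizon=cfg.horizon,
                )
                fit_nodeath = fit_drug_params(
                    data, base, include_death=False,
                    seed=_derived_seed(cfg.seed, "fit0", cell_line, drug),
                    target_state=cfg.drug_targets[drug], n_starts=cfg.fit_starts,
                    horizon=cfg.horizon,
                )
            except Exception as exc:
                raise RuntimeError(f"{stage} ({drug}) failed: {exc}") from exc
            all_death_fits.append(fit)
            all_nodeath_fits.append(fit_nodeath)
            fitted_drugs.append(fit.params if cfg.include_death else fit_nodeath.params)
            entry["drugs"][drug] = {
                "ec50_uM": fit.params.ec50,
                "hill_n": fit.params.hill_n,
                "emax_phi_per_h": fit.params.emax_phi,
                "ec50_phi_uM": fit.params.ec50_phi,
                "sse": fit.sse,
                "aic": fit.aic,
                "aic_nodeath": fit_nodeath.aic,
                "doses_uM": data.doses.tolist(),
                "observed": data.mean_counts.tolist(),
                "predicted": fit.predicted.tolist(),
            }

        model = CellLineModel(cell_line, base, tuple(fitted_drugs))

        stage = f"[{cell_line}] combination prediction + EOB"
        logger.info(stage)
        for pair in PAIRS:
            if pair[0] not in cfg.drug_targets or pair[1] not in cfg.drug_targets:
                continue
            predicted = predict_grid(
                model, *pair, cfg.combo_doses[pair[0]], cfg.combo_doses[pair[1]],
                horizon=cfg.horizon,
            )
            measured = measured_combos.get((cell_line, *pair))
            if measured is None:
                measured = _synthetic_combos(cfg, truth)[pair]
            try:
                r, _ = compare_grids(predicted, measured)
            except Exception as exc:
                raise RuntimeError(f"{stage} ({pair}) failed: {exc}") from exc
            eob_seed = _derived_seed(cfg.seed, "eob", cell_line, *pair)
            eob_pred = eob_from_grid(predicted, seed=eob_seed)
            eob_meas = eob_from_grid(measured, seed=eob_seed)
            entry["combinations"]["/".join(pair)] = {
                "doses_a_uM": predicted.doses_a.tolist(),
                "doses_b_uM": predicted.doses_b.tolist(),
                "predicted": predicted.values.tolist(),
                "measured": measured.values.tolist(),
                "pearson_r": r,
                "eob_model": _eob_summary(eob_pred),
                "eob_measured": _eob_summary(eob_meas),
            }
        report["cell_lines"][cell_line] = entry

    try:
        report["delta_aic_death_vs_nodeath"] = compare_aic(all_death_fits, all_nodeath_fits)
        report["pooled_free_params"] = {
            "death": sum(f.n_free_params for f in all_death_fits),
            "no_death": sum(f.n_free_params for f in all_nodeath_fits),
        }
    except ValueError:
        report["delta_aic_death_vs_nodeath"] = None

    if write:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_tables(report, out_dir)
    return report


def _write_tables(report: dict, out_dir: Path) -> None:
    growth_rows, drug_rows, combo_rows = [], [], []
    for cell_line, entry in report["cell_lines"].items():
        g = entry["growth"]
        growth_rows.append(
            {"cell_line": cell_line, "m1": g["fitted_m"][0], "m2": g["fitted_m"][1],
             "m3": g["fitted_m"][2], "sse": g["sse"]}
        )
        for drug, d in entry["drugs"].items():
            drug_rows.append(
                {"cell_line": cell_line, "drug": drug, "ec50_uM": d["ec50_uM"],
                 "hill_n": d["hill_n"], "emax_phi_per_h": d["emax_phi_per_h"],
                 "ec50_phi_uM": d["ec50_phi_uM"], "sse": d["sse"]}
            )
        for pair, c in entry["combinations"].items():
            combo_rows.append(
                {"cell_line": cell_line, "pair": pair, "pearson_r": c["pearson_r"],
                 "mean_eob_model": c["eob_model"]["mean_eob"],
                 "mean_eob_measured": c["eob_measured"]["mean_eob"]}
            )
    pd.DataFrame(growth_rows).to_csv(out_dir / "transition_params.csv", index=False)
    pd.DataFrame(drug_rows).to_csv(out_dir / "drug_params.csv", index=False)
    pd.DataFrame(combo_rows).to_csv(out_dir / "combination_summary.csv", index=False)
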