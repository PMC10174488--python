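"""Figure export: dose-response curves, combination heatmaps, EOB scatter.

Every figure regenerates from the pipeline's JSON report alone, keeping
computation and presentation separate.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_dose_response", "plot_grid_heatmaps", "plot_eob_scatter", "render_report"]


def _dose_axis(doses: np.ndarray, zero_offset: float = 0.3) -> np.ndarray:
    """Positions for a log dose axis; dose 0 sits at a configurable offset
    below the smallest nonzero dose."""
    doses = np.asarray(doses, dtype=float)
    nonzero = doses[doses > 0]
    floor = nonzero.min() * zero_offset if nonzero.size else 1.0
    return np.where(doses > 0, doses, floor)


def plot_dose_response(ax, doses, observed, predicted=None, se=None, label=""):
    x = _dose_axis(doses)
    ax.errorbar(x, observed, yerr=se, fmt="o", ms=4, capsize=2, label="data")
    if predicted is not None:
        ax.plot(x, predicted, "-", label="model")
    ax.set_xscale("log")
    ax.set_xlabel("dose (µM)")
    ax.set_ylabel("relative cell count")
    ax.set_title(label)
    ax.legend(fontsize=7)


def plot_grid_heatmaps(fig, axes, doses_a, doses_b, predicted, measured, pair, r):
    for ax, values, title in zip(
        axes, (np.asarray(predicted), np.asarray(measured)), ("model", "experiment")
    ):
        im = ax.imshow(values, origin="lower", vmin=0, vmax=1.05, cmap="viridis")
        ax.set_title(f"{pair} {title}" + (f" (r={r:.2f})" if title == "experiment" else ""))
        ax.set_xticks(range(len(doses_b)))
        ax.set_xticklabels([f"{d * 1e3:g}" for d in doses_b], rotation=90, fontsize=6)
        ax.set_yticks(range(len(doses_a)))
        ax.set_yticklabels([f"{d * 1e3:g}" for d in doses_a], fontsize=6)
        ax.set_xlabel("dose B (nM)")
        ax.set_ylabel("dose A (nM)")
        fig.colorbar(im, ax=ax, fraction=0.046)


def plot_eob_scatter(ax, model_scores, measured_scores, labels):
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.axvline(0.0, color="gray", lw=0.5)
    for x, y, label in zip(model_scores, measured_scores, labels):
        ax.plot(x, y, "o")
        ax.annotate(label, (x, y), fontsize=6, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("mean EOB (model)")
    ax.set_ylabel("mean EOB (experiment)")
    ax.set_title("excess over Bliss: synergy > 0 > antagonism")


def render_report(report, out_dir) -> list[Path]:
    """Regenerate all figures from a pipeline report (dict or JSON path)."""
    if not isinstance(report, dict):
        report = json.loads(Path(report).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    eob_points: list[tuple[float, float, str]] = []
    for cell_line, entry in report["cell_lines"].items():
        drugs = entry["drugs"]
        if drugs:
            fig, axes = plt.subplots(1, len(drugs), figsize=(4 * len(drugs), 3.2))
            axes = np.atleast_1d(axes)
            for ax, (drug, d) in zip(axes, drugs.items()):
                plot_dose_response(
                    ax, d["doses_uM"], d["observed"], d["predicted"],
                    label=f"{cell_line} {drug}",
                )
            fig.tight_layout()
            path = out_dir / f"dose_response_{cell_line}.png"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            written.append(path)

        for pair, c in entry["combinations"].items():
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.6))
            plot_grid_heatmaps(
                fig, axes, c["doses_a_uM"], c["doses_b_uM"],
                c["predicted"], c["measured"], f"{cell_line} {pair}", c["pearson_r"],
            )
            fig.tight_layout()
            path = out_dir / f"grid_{cell_line}_{pair.replace('/', '_')}.png"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            written.append(path)
            eob_points.append(
                (c["eob_model"]["mean_eob"], c["eob_measured"]["mean_eob"], f"{cell_line} {pair}")
            )

    if eob_points:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        plot_eob_scatter(
            ax,
            [p[0] for p in eob_points],
            [p[1] for p in eob_points],
            [p[2] for p in eob_points],
        )
        fig.tight_layout()
        path = out_dir / "eob_scatter.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
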