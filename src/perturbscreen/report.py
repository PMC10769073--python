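"""Figure rendering and PDF report assembly.

One PDF per input screen, pages in a fixed family order: dose-response,
XY time courses, growth-rate, bar plots, synergy heatmaps.  Synergy heatmaps
use a fixed color scale of [-1, 1], blue for synergism (positive scores) and
red for antagonism.  Endpoint screens get bar plots instead of time courses.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["figure.max_open_warning"] = 0

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages

from .dose_response import DoseResponseFit
from .errors import ValidationError
from .synergy import SynergyResult

log = logging.getLogger(__name__)

SYNERGY_CMAP = "RdBu"  # blue = positive/synergism, red = negative/antagonism
SYNERGY_SCALE = (-1.0, 1.0)

#: plot families produced for each experiment type
FAMILIES_BY_TYPE = {
    "drug": ("dose_response", "xy", "gr", "gr_dose_response"),
    "drug_combination": ("dose_response", "xy", "gr", "bar", "heatmap"),
    "genetic": ("xy", "gr", "bar", "heatmap_conditions"),
    "genetic_chemical": ("dose_response", "xy", "gr", "bar", "heatmap"),
}


@dataclass
class ReportSpec:
    """What to render and where."""

    out_pdf: str
    main_timepoints: tuple[float, ...] = (24.0, 48.0, 72.0)
    families: tuple[str, ...] | None = None  # None = all applicable
    color_scale: tuple[float, float] = SYNERGY_SCALE


def plot_xy(
    times: np.ndarray,
    series: dict[str, np.ndarray],
    predicted: np.ndarray | None = None,
    title: str = "",
    ylabel: str = "effect",
):
    """Time-course XY page: one curve per condition, dashed predicted combination."""
    if not series:
        log.info("plot_xy: no series, page skipped (%s)", title)
        return None
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, y in series.items():
        ax.plot(times, y, marker="o", markersize=3, label=label)
    if predicted is not None:
        ax.plot(times, predicted, "k--", label="predicted combination")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_bar(
    labels: list[str],
    effects: np.ndarray,
    time: float,
    predicted: float | None = None,
    title: str = "",
):
    """Endpoint / main-time-point bar plot of condition effects."""
    fig, ax = plt.subplots(figsize=(7, 5))
    x = np.arange(len(labels))
    ax.bar(x, effects, color="steelblue")
    if predicted is not None:
        ax.axhline(predicted, color="k", linestyle="--", label="predicted combination")
        ax.legend(fontsize=7)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("effect (fraction)")
    ax.set_title(title or f"effects at {time} h")
    fig.tight_layout()
    return fig


def _fmt_metric(value, unit="") -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "not determined"
    return f"{value:.2f}{unit}"


def plot_dose_response(
    fit: DoseResponseFit,
    agent: str,
    time: float,
    unit: str = "",
    overlay: tuple[str, DoseResponseFit] | None = None,
):
    """Dose-response page with fitted curve and annotated potency metrics."""
    fig, ax = plt.subplots(figsize=(7, 5))
    prefix = "GR_" if fit.gr_variant else ""

    def draw(f: DoseResponseFit, lab: str, color):
        if f.doses is None or not len(f.doses):
            return
        ax.semilogx(f.doses, f.responses, "o", color=color, label=f"{lab} observed")
        if f.converged:
            xs = np.geomspace(f.doses[0], f.doses[-1], 200)
            ax.semilogx(xs, f.predict(xs), "-", color=color, label=f"{lab} 4PL fit")

    draw(fit, agent, "tab:blue")
    if overlay is not None:
        draw(overlay[1], overlay[0], "tab:orange")
    lines = [
        f"{prefix}Emax: {_fmt_metric(fit.emax_fitted if fit.gr_variant else fit.emax_observed)}",
        f"{prefix}rel. 50: {_fmt_metric(fit.rel_ic50, ' ' + unit if unit else '')}",
        f"{prefix}abs. 50: {_fmt_metric(fit.abs_ic50, ' ' + unit if unit else '')}",
        f"R²: {_fmt_metric(fit.r_squared)}  χ²: {_fmt_metric(fit.chi_square)}",
    ]
    ax.text(
        0.02,
        0.98,
        "\n".join(lines),
        transform=ax.transAxes,
        va="top",
        fontsize=8,
        bbox=dict(boxstyle="round", fc="white", alpha=0.8),
    )
    ax.set_xlabel(f"dose ({unit})" if unit else "dose")
    ax.set_ylabel("GR value" if fit.gr_variant else "effect (fraction)")
    ax.set_title(f"{agent} dose-response at {time} h")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_gr(times: np.ndarray, gr_by_condition: dict[str, np.ndarray], title: str = ""):
    """Growth-rate page; the grey dashed line at 0 marks growth halt."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, g in gr_by_condition.items():
        ax.plot(times, g, marker="o", markersize=3, label=label)
    ax.axhline(0.0, color="grey", linestyle="--", linewidth=1, label="growth halt")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("growth rate (relative to control)")
    ax.set_title(title or "growth rate over time")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_synergy_heatmaps(
    result: SynergyResult,
    main_timepoints: tuple[float, ...] = (24.0, 48.0, 72.0),
    color_scale: tuple[float, float] = SYNERGY_SCALE,
    dose_units: tuple[str, ...] | None = None,
) -> list:
    """Synergy heatmap pages.

    Always: the score-over-time heatmap (time x combination cell).  At each
    main time point present in the series, for two-chemical-axis grids with
    >=2 doses on each axis, a 2D heatmap and a 3D surface over the dose grid;
    with a single tested concentration on an axis (m = 1) only the 2D map.
    """
    figs = []
    vmin, vmax = color_scale

    fig, ax = plt.subplots(figsize=(8, 5))
    t0, t1 = float(result.times[0]), float(result.times[-1])
    if t1 <= t0:  # endpoint screen: single-column heatmap
        t1 = t0 + 1.0
    im = ax.imshow(
        result.scores.T,
        aspect="auto",
        cmap=SYNERGY_CMAP,
        vmin=vmin,
        vmax=vmax,
        origin="lower",
        extent=(t0, t1, -0.5, result.scores.shape[1] - 0.5),
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("combination cell")
    labels = [
        " / ".join(f"{d:g}" for d in result.cell_doses(c))
        for c in range(len(result.coords))
    ]
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_title(f"{result.method} score over time")
    fig.colorbar(im, ax=ax, label=f"{result.method} score")
    fig.tight_layout()
    figs.append(fig)

    grid = result.grid
    chem_axes = [i for i, g in enumerate(grid.axis_is_genetic) if not g]
    if len(chem_axes) == 2 and len(grid.axis_names) == 2:
        nx, ny = grid.shape
        for tp in main_timepoints:
            hits = np.flatnonzero(np.isclose(result.times, tp))
            if not hits.size:
                continue
            ti = int(hits[0])
            mat = np.full(grid.shape, np.nan)
            for c, xy in enumerate(result.coords):
                mat[xy] = result.scores[ti, c]
            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(
                mat.T, origin="lower", cmap=SYNERGY_CMAP, vmin=vmin, vmax=vmax
            )
            ax.set_xticks(range(nx))
            ax.set_xticklabels([f"{d:g}" for d in grid.axis_doses[0]], rotation=45, fontsize=7)
            ax.set_yticks(range(ny))
            ax.set_yticklabels([f"{d:g}" for d in grid.axis_doses[1]], fontsize=7)
            ax.set_xlabel(grid.axis_names[0])
            ax.set_ylabel(grid.axis_names[1])
            ax.set_title(f"{result.method} score at {tp:g} h")
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            figs.append(fig)
            if not grid.heatmap_2d_only:
                fig3 = plt.figure(figsize=(6, 5))
                ax3 = fig3.add_subplot(111, projection="3d")
                xg, yg = np.meshgrid(range(nx), range(ny), indexing="ij")
                ax3.plot_surface(
                    xg, yg, np.nan_to_num(mat), cmap=SYNERGY_CMAP, vmin=vmin, vmax=vmax
                )
                ax3.set_xlabel(grid.axis_names[0])
                ax3.set_ylabel(grid.axis_names[1])
                ax3.set_zlabel(f"{result.method} score")
                ax3.set_zlim(vmin, vmax)
                ax3.set_title(f"{result.method} score surface at {tp:g} h")
                figs.append(fig3)
    return figs


def assemble_pdf(pages: list, out_pdf: str | os.PathLike) -> str:
    """Write figure pages to a PDF atomically, preserving page order."""
    pages = [p for p in pages if p is not None]
    if not pages:
        raise ValidationError("no figure pages to assemble; refusing to write an empty PDF")
    out_pdf = str(out_pdf)
    os.makedirs(os.path.dirname(out_pdf) or ".", exist_ok=True)
    tmp = out_pdf + ".tmp"
    with PdfPages(tmp) as pdf:
        for fig in pages:
            pdf.savefig(fig)
            plt.close(fig)
    os.replace(tmp, out_pdf)
    return out_pdf
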