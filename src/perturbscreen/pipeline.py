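"""End-to-end orchestration: export file in, PDF + text results out.

``run_screen`` chains the library modules exactly as the interactive tool
would: parse -> pool replicates -> identify controls & categorize ->
normalize to the (pooled) control -> dose-response fits at the main time
points -> growth rates -> synergy over time -> text tables + PDF report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import report as report_mod
from .dose_response import DoseResponseFit, fit_4pl, gr_dose_response
from .errors import ControlError, PerturbScreenError
from .growth_rate import gr_series
from .layout import (
    CombinationGrid,
    Layout,
    build_layout,
    combination_grids,
    write_categorization_error,
)
from .normalize import EffectSeries, normalize_to_control, pool_controls, rescale_sd
from .screen_io import RawScreen, export_results_text, merge_replicates, read_export, write_store
from .synergy import SynergyResult, synergy_over_time


@dataclass
class RunResult:
    """Everything computed for one screen."""

    screen: RawScreen
    layout: Layout
    effects: EffectSeries
    control: np.ndarray  # pooled control read-out per time point
    fits: list[dict] = field(default_factory=list)  # rows: agent/time/fit
    gr: dict[int, object] = field(default_factory=dict)  # condition index -> GRSeries
    synergy: list[SynergyResult] = field(default_factory=list)
    grids: list[CombinationGrid] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    pdf_path: str | None = None
    text_paths: list[str] = field(default_factory=list)
    store_path: str | None = None


def _main_time_indices(times: np.ndarray, main_timepoints) -> list[int]:
    idx = []
    for tp in main_timepoints:
        hits = np.flatnonzero(np.isclose(times, tp))
        if hits.size:
            idx.append(int(hits[0]))
    last = len(times) - 1
    if last not in idx:
        idx.append(last)
    return idx


def _dose_response_rows(
    layout: Layout, effects: np.ndarray, gr_rel: dict[int, np.ndarray],
    times: np.ndarray, t_indices: list[int]
) -> list[dict]:
    rows = []
    for branch in layout.branches:
        for agent in branch.agents:
            members = [
                (i, d.agents[0].concentration, d.agents[0].unit)
                for i, d in zip(branch.members, branch.descriptors)
                if len(d.agents) == 1 and not d.genetic and d.agents[0].name == agent
            ]
            if len(members) < 2:
                continue
            idx = [m[0] for m in members]
            doses = np.asarray([m[1] for m in members])
            unit = members[0][2]
            pos = doses > 0
            if pos.sum() < 2:
                continue
            for ti in t_indices:
                fit = fit_4pl(doses[pos], effects[ti, idx][pos])
                rows.append(
                    {
                        "branch": branch.cell_line,
                        "genetic": "+".join(branch.genetic),
                        "agent": agent,
                        "unit": unit,
                        "time": float(times[ti]),
                        "fit": fit,
                        "gr": False,
                    }
                )
                grv = np.asarray(
                    [gr_rel.get(i, np.full(len(times), np.nan))[ti] for i in idx]
                )
                if np.sum(np.isfinite(grv[pos])) >= 2:
                    gfit = gr_dose_response(grv[pos], doses[pos])
                    rows.append(
                        {
                            "branch": branch.cell_line,
                            "genetic": "+".join(branch.genetic),
                            "agent": agent,
                            "unit": unit,
                            "time": float(times[ti]),
                            "fit": gfit,
                            "gr": True,
                        }
                    )
    return rows


def _fits_table(rows: list[dict]) -> pd.DataFrame:
    recs = []
    for r in rows:
        f: DoseResponseFit = r["fit"]
        recs.append(
            {
                "cell_line": r["branch"],
                "genetic": r["genetic"],
                "agent": r["agent"],
                "time_h": r["time"],
                "metric": "GR" if r["gr"] else "effect",
                "status": f.status,
                "bottom": f.bottom,
                "top": f.top,
                "rel_50": f.rel_ic50 if f.rel_ic50 is not None else np.nan,
                "abs_50": f.abs_ic50 if f.abs_ic50 is not None else np.nan,
                "emax_observed": f.emax_observed,
                "auc_norm": f.auc_norm,
                "chi_square": f.chi_square,
                "r_squared": f.r_squared,
                "unit": r["unit"],
            }
        )
    return pd.DataFrame(recs)


def run_screen(
    source: str | os.PathLike | RawScreen,
    out_dir: str | os.PathLike = ".",
    mode: str = "inhibition",
    method: str = "BI",
    main_timepoints: tuple[float, ...] = (24.0, 48.0, 72.0),
    control_names: tuple[str, ...] = (),
    make_pdf: bool = True,
    save_store: bool = False,
    onset_threshold: float = 0.1,
    delimiter: str = "auto",
    gr_log: str = "natural",
) -> RunResult:
    """Run the full analysis of one export file (or in-memory screen)."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(source, RawScreen):
        screen, name = source, "screen"
    else:
        screen = read_export(source, delimiter=delimiter)
        name = os.path.splitext(os.path.basename(str(source)))[0]
    screen = merge_replicates(screen)  # pools duplicate-condition columns

    try:
        layout = build_layout(
            screen.descriptors, extra_control_names=control_names, confirmed=True
        )
    except (ControlError, PerturbScreenError) as exc:
        write_categorization_error(
            os.path.join(out_dir, f"{name}.categorization_error.txt"),
            screen.descriptors,
            str(exc),
        )
        raise
    screen.descriptors = list(layout.descriptors)

    control_series = [screen.measurements[:, i] for i in layout.control_indices]
    control, control_sd, _ = pool_controls(control_series)
    effects = normalize_to_control(screen.measurements, control, mode)
    if screen.sd is not None and np.any(np.isfinite(control_sd)):
        effects.rescaled_sd = rescale_sd(screen.sd, control_sd)
    if screen.ci95 is not None:
        effects.ci95 = screen.ci95

    times = screen.elapsed
    gr_map: dict[int, object] = {}
    gr_rel: dict[int, np.ndarray] = {}
    if screen.n_times >= 3:
        for i in range(screen.n_conditions):
            if i in layout.control_indices:
                continue
            try:
                g = gr_series(
                    screen.measurements[:, i], times, control_series=control,
                    log_base=gr_log,
                )
            except (ValueError, RuntimeWarning):
                continue
            gr_map[i] = g
            if g.rel_gr is not None:
                gr_rel[i] = g.rel_gr

    t_indices = _main_time_indices(times, main_timepoints)
    fit_rows = _dose_response_rows(layout, effects.effect, gr_rel, times, t_indices)

    synergy_results: list[SynergyResult] = []
    grids: list[CombinationGrid] = []
    if layout.experiment_type in ("drug_combination", "genetic_chemical"):
        for bi, branch in enumerate(layout.branches):
            if not branch.has_combination:
                continue
            companions = [b for j, b in enumerate(layout.branches) if j != bi]
            for grid in combination_grids(branch, companions):
                grids.append(grid)
                res = synergy_over_time(
                    effects.effect,
                    times,
                    grid,
                    method,
                    experiment_type=layout.experiment_type,
                    onset_threshold=onset_threshold,
                )
                synergy_results.append(res)

    tables = _build_tables(screen, layout, effects, fit_rows, synergy_results)
    text_paths = export_results_text(tables, out_dir, prefix=f"{name}_")

    result = RunResult(
        screen=screen,
        layout=layout,
        effects=effects,
        control=control,
        fits=fit_rows,
        gr=gr_map,
        synergy=synergy_results,
        grids=grids,
        tables=tables,
        text_paths=text_paths,
    )
    if save_store:
        store_path = os.path.join(out_dir, f"{name}.h5")
        write_store(store_path, screen, layout)
        result.store_path = store_path
    if make_pdf:
        result.pdf_path = _render_pdf(
            os.path.join(out_dir, f"{name}.pdf"), result, main_timepoints
        )
    return result


def _build_tables(screen, layout, effects, fit_rows, synergy_results):
    labels = screen.labels
    eff_recs = []
    for i in range(screen.n_conditions):
        for ti, t in enumerate(screen.elapsed):
            eff_recs.append(
                {
                    "condition": labels[i],
                    "is_control": i in layout.control_indices,
                    "time_h": float(t),
                    "measurement": screen.measurements[ti, i],
                    "effect": effects.effect[ti, i],
                    "sd": screen.sd[ti, i] if screen.sd is not None else np.nan,
                    "ci95": screen.ci95[ti, i] if screen.ci95 is not None else np.nan,
                }
            )
    tables = {"effects": pd.DataFrame(eff_recs)}
    if fit_rows:
        tables["fits"] = _fits_table(fit_rows)
    syn_recs = []
    for res in synergy_results:
        for c, coords in enumerate(res.coords):
            doses = res.cell_doses(c)
            for ti, t in enumerate(res.times):
                syn_recs.append(
                    {
                        "method": res.method,
                        "time_h": float(t),
                        **{
                            f"dose_{ax}": d
                            for ax, d in zip(res.grid.axis_names, doses)
                        },
                        "observed": res.observed[ti, c],
                        "predicted": res.predicted[ti, c],
                        "score": res.scores[ti, c],
                        "class": res.classification[ti, c],
                    }
                )
    if syn_recs:
        tables["synergy"] = pd.DataFrame(syn_recs)
    return tables


def _render_pdf(out_pdf: str, result: RunResult, main_timepoints) -> str:
    screen, layout = result.screen, result.layout
    times = screen.elapsed
    pages = []
    # dose-response pages (fits at the last main time point, per agent)
    last_t = float(times[-1])
    for r in result.fits:
        if r["time"] == last_t and r["fit"].converged:
            pages.append(
                report_mod.plot_dose_response(
                    r["fit"],
                    r["agent"] + (" GR" if r["gr"] else ""),
                    r["time"],
                    unit=r["unit"],
                )
            )
    # XY pages (or bars for endpoint screens)
    if screen.is_endpoint:
        idx = [i for i in range(screen.n_conditions) if i not in layout.control_indices]
        pages.append(
            report_mod.plot_bar(
                [screen.labels[i] for i in idx],
                result.effects.effect[0, idx],
                float(times[0]),
                title="endpoint effects",
            )
        )
    else:
        for branch in layout.branches:
            series = {
                screen.labels[i]: result.effects.effect[:, i]
                for i in branch.members[:12]
            }
            pages.append(
                report_mod.plot_xy(
                    times,
                    series,
                    title=f"{branch.cell_line} {'+'.join(branch.genetic)}".strip(),
                    ylabel=f"{result.effects.mode} (fraction)",
                )
            )
        # best combination cell: singles + observed + predicted
        for res in result.synergy:
            final = res.scores[-1]
            if not np.any(np.isfinite(final)):
                continue
            c = int(np.nanargmax(final))
            coords = res.coords[c]
            cond_idx = res.grid.cells[coords]
            margin_idx = res.grid.margin_indices(coords)
            series = {screen.labels[cond_idx]: result.effects.effect[:, cond_idx]}
            for m in margin_idx:
                if m is not None:
                    series[screen.labels[m]] = result.effects.effect[:, m]
            pages.append(
                report_mod.plot_xy(
                    times,
                    series,
                    predicted=res.predicted[:, c],
                    title=f"best {res.method} cell",
                    ylabel=f"{result.effects.mode} (fraction)",
                )
            )
    # growth-rate pages
    if result.gr:
        for branch in layout.branches:
            gr_dict = {
                screen.labels[i]: result.gr[i].rel_gr
                for i in branch.members[:12]
                if i in result.gr and result.gr[i].rel_gr is not None
            }
            if gr_dict:
                pages.append(
                    report_mod.plot_gr(
                        times, gr_dict, title=f"growth rate: {branch.cell_line}"
                    )
                )
    # bar page at the final time point for combination screens
    if not screen.is_endpoint and result.synergy:
        res = result.synergy[0]
        final = res.scores[-1]
        if np.any(np.isfinite(final)):
            c = int(np.nanargmax(final))
            coords = res.coords[c]
            cond_idx = res.grid.cells[coords]
            margin_idx = [m for m in res.grid.margin_indices(coords) if m is not None]
            idx = margin_idx + [cond_idx]
            pages.append(
                report_mod.plot_bar(
                    [screen.labels[i] for i in idx],
                    result.effects.effect[-1, idx],
                    last_t,
                    predicted=float(res.predicted[-1, c]),
                    title=f"best {res.method} cell at {last_t:g} h",
                )
            )
    # synergy heatmaps
    for res in result.synergy:
        pages.extend(
            report_mod.plot_synergy_heatmaps(res, main_timepoints=tuple(main_timepoints))
        )
    return report_mod.assemble_pdf(pages, out_pdf)
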