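"""Synergy/antagonism scoring of N-agent combinations per time point.

Three null models over the observed fractional inhibition effects:

* **HSA** — expected combination effect is the highest single-agent effect;
  score = observed - max(D1..DN).
* **BI** (Bliss independence) — expected effect is the probabilistic
  independence value H(F) = 1 - prod(1 - Di) (identical to the
  inclusion-exclusion expansion); score = observed - H(F).
* **ZIP** (zero interaction potency) — for each agent a 4PL is fitted to its
  monotherapy inhibition; for each direction i a *conditional* 4PL is fitted
  along agent i's dose axis with the curve's minimum pinned at the Bliss
  expectation of the fitted partner effects; the delta is the average fitted
  conditional response minus the Bliss expectation of the fitted monotherapy
  curves.  The two-agent case reduces to the classical ZIP delta; higher
  orders average over the N conditional directions.

Scores above zero mean synergism, below zero antagonism.  Before scoring,
effects are capped to [0, 1]: a condition growing faster than its control
(negative inhibition) is reset to the control level to avoid spurious
HSA/BI scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dose_response import _quiet_curve_fit
from .errors import ValidationError
from .layout import CombinationGrid

METHODS = ("HSA", "BI", "ZIP")


def cap_effects(effects: np.ndarray) -> np.ndarray:
    """Cap fractional effects into [0, 1] (NaN preserved).

    Negative inhibition (viability above control) is floored at 0 -- the
    condition is treated as matching the control; numerical overshoots above
    1 are ceiled.
    """
    return np.clip(np.asarray(effects, dtype=float), 0.0, 1.0)


def hsa_score(single_effects, observed: float) -> float:
    """Observed combination effect minus the highest single-agent effect."""
    singles = np.asarray(single_effects, dtype=float)
    if np.any(np.isnan(singles)) or math.isnan(observed):
        return math.nan
    return float(observed - np.max(singles))


def bi_predicted(single_effects) -> float:
    """Bliss-independence expectation H(F) = 1 - prod(1 - Di)."""
    singles = np.asarray(single_effects, dtype=float)
    if np.any(np.isnan(singles)):
        return math.nan
    return float(1.0 - np.prod(1.0 - singles))


def bi_score(single_effects, observed: float) -> float:
    """Observed combination effect minus the Bliss expectation."""
    if math.isnan(observed):
        return math.nan
    return float(observed - bi_predicted(single_effects))


# ---------------------------------------------------------------------------
# ZIP


def _zip_curve(x, emax, m, lam):
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        u = np.power(np.asarray(x, dtype=float) / np.abs(m), lam)
        return emax * u / (1.0 + u)


def _fit_zip_mono(doses: np.ndarray, effects: np.ndarray):
    """Fit the monotherapy inhibition curve f(x) = Emax * u / (1 + u), f(0) = 0."""
    keep = np.isfinite(effects)
    doses, effects = doses[keep], effects[keep]
    if doses.size < 2:
        return None
    p0 = [max(float(np.max(effects)), 1e-3), float(np.median(doses)), 1.0]
    try:
        popt, _ = _quiet_curve_fit(_zip_curve, doses, effects, p0=p0, method="lm", maxfev=20000)
        popt[1] = abs(popt[1])
        if not (0 <= popt[0] <= 2 and popt[1] > 0 and 0.05 <= popt[2] <= 25):
            raise RuntimeError
    except (RuntimeError, ValueError):
        try:
            popt, _ = _quiet_curve_fit(
                _zip_curve,
                doses,
                effects,
                p0=p0,
                bounds=([0.0, doses.min() * 1e-6, 0.1], [2.0, doses.max() * 1e6, 20.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return None
    return tuple(float(v) for v in popt)


def _fit_zip_conditional(doses: np.ndarray, observed: np.ndarray, baseline: float):
    """Fit y = b + (Emax - b) * u / (1 + u) along one dose axis, b fixed."""
    keep = np.isfinite(observed)
    d, y = doses[keep], observed[keep]
    if d.size < 2:
        return None

    def curve(x, emax, m, lam):
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            u = np.power(np.asarray(x, dtype=float) / np.abs(m), lam)
            return baseline + (emax - baseline) * u / (1.0 + u)

    p0 = [max(float(np.max(y)), baseline + 1e-3), float(np.median(d)), 1.0]
    try:
        popt, _ = _quiet_curve_fit(curve, d, y, p0=p0, method="lm", maxfev=20000)
        popt[1] = abs(popt[1])
        if not (popt[1] > 0 and 0.05 <= popt[2] <= 25):
            raise RuntimeError
    except (RuntimeError, ValueError):
        try:
            popt, _ = _quiet_curve_fit(
                curve,
                d,
                y,
                p0=p0,
                bounds=([-2.0, d.min() * 1e-6, 0.1], [2.0, d.max() * 1e6, 20.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return None
    emax, m, lam = (float(v) for v in popt)
    return lambda x: baseline + (emax - baseline) * np.power(x / m, lam) / (
        1.0 + np.power(x / m, lam)
    )


def zip_score(
    axis_doses: list[np.ndarray],
    mono_effects: list[np.ndarray],
    combo_effects: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """ZIP delta per grid cell for an N-agent dose grid (chemical agents only).

    ``axis_doses[i]`` are agent i's combination doses (strictly positive,
    >=2 per agent), ``mono_effects[i]`` the capped monotherapy inhibitions at
    those doses, ``combo_effects`` the capped observed combination inhibition
    with shape ``(n1, ..., nN)``.  Returns ``(delta, predicted)`` arrays of
    that shape; cells whose conditional curve could not be fitted are NaN.
    """
    n_agents = len(axis_doses)
    if n_agents < 2:
        raise ValidationError("ZIP needs >=2 chemical agents")
    axis_doses = [np.asarray(d, dtype=float) for d in axis_doses]
    mono_effects = [np.asarray(e, dtype=float) for e in mono_effects]
    combo = np.asarray(combo_effects, dtype=float)
    if combo.shape != tuple(len(d) for d in axis_doses):
        raise ValidationError("combination grid shape does not match dose axes")
    for d in axis_doses:
        if d.size < 2:
            raise ValidationError("ZIP needs >=2 doses per agent")
        if np.any(d <= 0):
            raise ValidationError("ZIP doses must be strictly positive")

    mono_fits = [_fit_zip_mono(d, e) for d, e in zip(axis_doses, mono_effects)]
    if any(f is None for f in mono_fits):
        warnings.warn("ZIP: a monotherapy curve could not be fitted", RuntimeWarning)
        nan = np.full(combo.shape, np.nan)
        return nan, nan

    # Bliss expectation of the fitted monotherapy curves, per cell
    fitted_mono = [
        _zip_curve(d, *popt) for d, popt in zip(axis_doses, mono_fits)
    ]
    survival = np.ones(combo.shape)
    for i, fm in enumerate(fitted_mono):
        shape = [1] * n_agents
        shape[i] = -1
        survival = survival * (1.0 - fm.reshape(shape))
    predicted = 1.0 - survival

    fitted_sum = np.zeros(combo.shape)
    fitted_cnt = np.zeros(combo.shape)
    for i in range(n_agents):
        moved = np.moveaxis(combo, i, -1)  # partners first, agent i last
        partner_axes = [k for k in range(n_agents) if k != i]
        out_i = np.full(moved.shape, np.nan)
        for partner_idx in np.ndindex(*moved.shape[:-1]):
            baseline = 1.0
            for k, j in zip(partner_axes, partner_idx):
                baseline *= 1.0 - fitted_mono[k][j]
            baseline = 1.0 - baseline
            cond = _fit_zip_conditional(axis_doses[i], moved[partner_idx], baseline)
            if cond is not None:
                out_i[partner_idx] = cond(axis_doses[i])
        out_i = np.moveaxis(out_i, -1, i)
        good = np.isfinite(out_i)
        fitted_sum[good] += out_i[good]
        fitted_cnt[good] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fitted = np.where(fitted_cnt > 0, fitted_sum / fitted_cnt, np.nan)
    delta = mean_fitted - predicted
    return delta, predicted


# ---------------------------------------------------------------------------
# scoring over time


@dataclass
class SynergyResult:
    """Per-time-point synergy scores over the combination grid cells."""

    method: str
    times: np.ndarray
    grid: CombinationGrid
    coords: list[tuple[int, ...]]  # grid coordinates, one per scored cell
    scores: np.ndarray  # [time x cell]
    predicted: np.ndarray  # [time x cell] expected combination effect
    observed: np.ndarray  # [time x cell] capped observed effect
    onset_threshold: float = 0.1
    onset_run: int = 2
    onset_index: list[int | None] = field(default_factory=list)

    @property
    def classification(self) -> np.ndarray:
        """'synergistic' / 'antagonistic' / 'additive' per (time, cell)."""
        out = np.full(self.scores.shape, "additive", dtype=object)
        out[self.scores > 0] = "synergistic"
        out[self.scores < 0] = "antagonistic"
        out[np.isnan(self.scores)] = "NA"
        return out

    def onset_time(self, cell: int) -> float | None:
        idx = self.onset_index[cell]
        return float(self.times[idx]) if idx is not None else None

    def cell_doses(self, cell: int) -> tuple[float, ...]:
        coords = self.coords[cell]
        return tuple(
            float(self.grid.axis_doses[ax][c]) for ax, c in enumerate(coords)
        )


def _detect_onset(scores: np.ndarray, threshold: float, run: int) -> int | None:
    """First index where |score| exceeds threshold for >= run consecutive points."""
    above = np.abs(scores) > threshold
    above = np.where(np.isnan(scores), False, above)
    count = 0
    for i, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count >= run:
            return i - run + 1
    return None


def synergy_over_time(
    effects: np.ndarray,
    times: np.ndarray,
    grid: CombinationGrid,
    method: str,
    experiment_type: str | None = None,
    onset_threshold: float = 0.1,
    onset_run: int = 2,
) -> SynergyResult:
    """Score every combination cell at every time point by one null model.

    ``effects`` is the [time x condition] fractional-inhibition matrix (it is
    capped here).  ZIP is valid for chemical drug combinations only; for
    genetic-chemical screens choose HSA or BI.  Cells missing the observed
    combination or any margin at a time point are NaN there.
    """
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    has_genetic_axis = any(grid.axis_is_genetic)
    if method == "ZIP" and (experiment_type == "genetic_chemical" or has_genetic_axis):
        raise ValidationError(
            "ZIP is defined for chemical drug combinations only; use HSA or BI "
            "for genetic-chemical perturbagen screens"
        )
    effects = np.asarray(effects, dtype=float)
    if effects.ndim == 1:
        effects = effects[None, :]
    times = np.asarray(times, dtype=float)
    capped = cap_effects(effects)

    coords = sorted(grid.cells)
    n_t, n_cells = len(times), len(coords)
    scores = np.full((n_t, n_cells), np.nan)
    predicted = np.full((n_t, n_cells), np.nan)
    observed = np.full((n_t, n_cells), np.nan)

    if method in ("HSA", "BI"):
        for t in range(n_t):
            for c, xy in enumerate(coords):
                cond_idx = grid.cells[xy]
                margin_idx = grid.margin_indices(xy)
                if any(m is None for m in margin_idx):
                    continue
                singles = capped[t, margin_idx]
                obs = capped[t, cond_idx]
                observed[t, c] = obs
                if method == "HSA":
                    pred = float(np.max(singles)) if not np.any(np.isnan(singles)) else math.nan
                    scores[t, c] = hsa_score(singles, obs)
                else:
                    pred = bi_predicted(singles)
                    scores[t, c] = bi_score(singles, obs)
                predicted[t, c] = pred
    else:  # ZIP
        axis_doses = [np.asarray(d, dtype=float) for d in grid.axis_doses]
        shape = grid.shape
        for t in range(n_t):
            mono = []
            usable = True
            for ax in range(len(axis_doses)):
                eff = np.full(len(axis_doses[ax]), np.nan)
                for lvl, idx in grid.margins[ax].items():
                    eff[lvl] = capped[t, idx]
                if np.sum(np.isfinite(eff)) < 2:
                    usable = False
                mono.append(eff)
            combo = np.full(shape, np.nan)
            for xy, idx in grid.cells.items():
                combo[xy] = capped[t, idx]
            if not usable:
                continue
            delta, pred = zip_score(axis_doses, mono, combo)
            for c, xy in enumerate(coords):
                scores[t, c] = delta[xy]
                predicted[t, c] = pred[xy]
                observed[t, c] = combo[xy]

    onset = [
        _detect_onset(scores[:, c], onset_threshold, onset_run) for c in range(n_cells)
    ]
    return SynergyResult(
        method=method,
        times=times,
        grid=grid,
        coords=coords,
        scores=scores,
        predicted=predicted,
        observed=observed,
        onset_threshold=onset_threshold,
        onset_run=onset_run,
        onset_index=onset,
    )
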