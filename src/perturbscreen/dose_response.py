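"""Four-parameter logistic dose-response fitting and potency metrics.

The 4PL form used throughout (also the building block of the ZIP synergy
model) is::

    effect(x) = e0 + (einf - e0) * (x / m)**lam / (1 + (x / m)**lam)

with ``e0`` the response as dose -> 0 (the curve *bottom* for an inhibition
curve), ``einf`` the plateau as dose -> infinity (*top* / Emax asymptote),
``m`` the inflection dose (the relative IC50/EC50) and ``lam`` the Hill
slope.  Fitting is nonlinear least squares, Levenberg-Marquardt first with a
bounded trust-region fallback.  Derived metrics: relative IC50 (= m),
absolute IC50 (dose where the fitted curve crosses the 50% level, in closed
form), observed Emax, trapezoidal AUC on the log10-dose axis, and the GR
analogues (GR_rel50 / GR_abs50 / GR_Emax) when fitted on growth-rate values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit


def _quiet_curve_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        return curve_fit(*args, **kwargs)

LAM_BOUNDS = (0.1, 20.0)


def logistic4(x, e0, einf, m, lam):
    """4PL response at dose ``x`` (vectorized; x and m strictly positive)."""
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        # |m| keeps intermediate LM iterates with m < 0 finite
        u = np.power(np.asarray(x, dtype=float) / np.abs(m), lam)
        return e0 + (einf - e0) * u / (1.0 + u)


@dataclass
class DoseResponseFit:
    """A fitted 4PL curve with fit statistics and derived potency metrics."""

    bottom: float  # e0, response at zero dose
    top: float  # einf, response plateau at infinite dose
    m: float  # inflection dose
    lam: float  # Hill slope
    converged: bool
    status: str  # "ok" | "degenerate" | "failed"
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    chi_square: float = math.nan
    r_squared: float = math.nan
    rel_ic50: float | None = None
    abs_ic50: float | None = None
    emax_observed: float = math.nan
    emax_fitted: float = math.nan
    auc_raw: float = math.nan
    auc_norm: float = math.nan
    gr_variant: bool = False

    def predict(self, x):
        return logistic4(x, self.bottom, self.top, self.m, self.lam)

    # GR-metric aliases used in reports
    @property
    def gr_rel50(self) -> float | None:
        return self.rel_ic50 if self.gr_variant else None

    @property
    def gr_abs50(self) -> float | None:
        return self.abs_ic50 if self.gr_variant else None

    @property
    def gr_emax(self) -> float:
        return self.emax_fitted if self.gr_variant else math.nan


def _failed_fit(doses, responses, status: str) -> DoseResponseFit:
    return DoseResponseFit(
        bottom=math.nan,
        top=math.nan,
        m=math.nan,
        lam=math.nan,
        converged=False,
        status=status,
        doses=doses,
        responses=responses,
    )


def fit_4pl(doses, responses, gr_variant: bool = False) -> DoseResponseFit:
    """Fit a 4PL curve to (dose, response) pairs.

    Requires >=2 distinct strictly positive doses.  A flat response vector is
    a degenerate fit (no IC50; the pipeline continues).  Non-convergence is
    recorded in ``status`` rather than raised.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    keep = ~(np.isnan(doses) | np.isnan(responses))
    doses, responses = doses[keep], responses[keep]
    if doses.size < 2 or np.unique(doses).size < 2:
        return _failed_fit(doses, responses, "failed")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive for 4PL fitting")

    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    if np.ptp(responses) == 0:
        return _failed_fit(doses, responses, "degenerate")

    e0_guess = float(responses[0])
    einf_guess = float(responses[-1])
    half = 0.5 * (e0_guess + einf_guess)
    m_guess = float(doses[np.argmin(np.abs(responses - half))])
    m_guess = m_guess if m_guess > 0 else float(np.median(doses))
    p0 = [e0_guess, einf_guess, m_guess, 1.0]

    popt = None
    try:
        popt, _ = _quiet_curve_fit(logistic4, doses, responses, p0=p0, method="lm", maxfev=20000)
        popt[2] = abs(popt[2])  # logistic4 is even in m
        if not (popt[2] > 0 and LAM_BOUNDS[0] <= popt[3] <= LAM_BOUNDS[1]):
            popt = None
    except (RuntimeError, ValueError):
        popt = None
    if popt is None:
        try:
            lo = [-np.inf, -np.inf, doses[0] * 1e-6, LAM_BOUNDS[0]]
            hi = [np.inf, np.inf, doses[-1] * 1e6, LAM_BOUNDS[1]]
            popt, _ = _quiet_curve_fit(
                logistic4, doses, responses, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            return _failed_fit(doses, responses, "failed")

    e0, einf, m, lam = (float(v) for v in popt)
    fitted = logistic4(doses, e0, einf, m, lam)
    residuals = responses - fitted
    chi2 = float(np.sum(residuals**2))
    sstot = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 - chi2 / sstot if sstot > 0 else (1.0 if chi2 == 0 else math.nan)

    fit = DoseResponseFit(
        bottom=e0,
        top=einf,
        m=m,
        lam=lam,
        converged=True,
        status="ok",
        doses=doses,
        responses=responses,
        residuals=residuals,
        chi_square=chi2,
        r_squared=r2,
        gr_variant=gr_variant,
    )
    level = 0.5
    metrics = derive_ic_metrics(fit, doses, responses, level=level)
    fit.rel_ic50 = metrics["rel_ic50"]
    fit.abs_ic50 = metrics["abs_ic50"]
    fit.emax_observed = metrics["emax_observed"]
    fit.emax_fitted = float(logistic4(doses[-1], e0, einf, m, lam))
    fit.auc_raw, fit.auc_norm = auc(doses, responses)
    return fit


def derive_ic_metrics(
    fit: DoseResponseFit, doses=None, responses=None, level: float = 0.5
) -> dict:
    """Relative/absolute IC50 (or EC50 / GR50) and observed Emax from a fit.

    The relative IC50 is the inflection dose ``m``.  The absolute IC50 is the
    closed-form dose where the fitted curve equals ``level``:
    ``m * u**(1/lam)`` with ``u = (level - e0) / (einf - level)``; it is
    undetermined (None) when ``level`` is not strictly between the fitted
    asymptotes.
    """
    if not fit.converged:
        return {"rel_ic50": None, "abs_ic50": None, "emax_observed": math.nan}
    doses = fit.doses if doses is None else np.asarray(doses, dtype=float)
    responses = fit.responses if responses is None else np.asarray(responses, dtype=float)
    rel = float(fit.m)
    abs_ic: float | None = None
    denom = fit.top - level
    numer = level - fit.bottom
    if denom != 0 and numer / denom > 0:
        abs_ic = float(fit.m * (numer / denom) ** (1.0 / fit.lam))
    emax_obs = float(responses[np.argmax(doses)]) if doses is not None and doses.size else math.nan
    return {"rel_ic50": rel, "abs_ic50": abs_ic, "emax_observed": emax_obs}


def auc(doses, responses) -> tuple[float, float]:
    """Trapezoidal area under the response curve on the log10-dose axis.

    Returns ``(raw, normalized)`` where the normalized area divides by the
    tested log10-dose range (a constant response of 1 has normalized AUC 1).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 2:
        raise ValueError("AUC needs >=2 doses")
    order = np.argsort(doses)
    x = np.log10(doses[order])
    y = responses[order]
    raw = float(np.trapezoid(y, x))
    span = x[-1] - x[0]
    return raw, raw / span if span > 0 else math.nan


def gr_dose_response(gr_values, doses) -> DoseResponseFit:
    """4PL fit of growth-rate values against dose (the GR metric family).

    GR_rel50 is the inflection dose, GR_abs50 the dose where the fitted GR
    curve crosses 0.5 (undetermined when the fitted plateau stays above 0.5),
    GR_Emax the fitted GR at the highest tested dose.
    """
    return fit_4pl(doses, gr_values, gr_variant=True)
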