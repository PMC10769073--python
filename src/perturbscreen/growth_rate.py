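"""Time-resolved growth rates from confluency-style read-outs.

Each condition is first rescaled to its value at the first time point.  The
*interval-mean* growth rate over [0, t] is

    <GR>(c, t) = ln(x(t) / x(0)) / t        [per hour]

which is exactly the time average of the instantaneous rate
GR(c, t) = d ln x / dt.  The instantaneous rate is reconstructed from the
identity GR(t) = <GR>(t) + t * d<GR>/dt, discretized symmetrically over the
bracketing sample points t1 < t < t2:

    GR(t) = (<GR>(t2) + <GR>(t1)) / 2 + t * (d<GR>/dt|t2 + d<GR>/dt|t1) / 2

with derivatives taken by central finite differences on a least-squares
smoothing spline of <GR> (one-sided at the ends).  Control-relative GR is
the pointwise ratio GR_condition / GR_control: 1 means control-like growth,
0 cryostasis, negative values net cell death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

LOG_BASES = {"natural": np.e, "base2": 2.0}


@dataclass
class GRSeries:
    """Growth-rate trajectories for one condition."""

    times: np.ndarray
    mean_gr: np.ndarray  # <GR>(c, t); NaN at t = 0
    inst_gr: np.ndarray | None  # GR(c, t); None when < 3 time points
    rel_gr: np.ndarray | None = None  # vs. control, dimensionless
    smoothing: float | None = None
    log_base: str = "natural"


def rescale_to_t0(series: np.ndarray) -> np.ndarray:
    """Normalize a read-out series to its first time point (result[0] = 1)."""
    series = np.asarray(series, dtype=float)
    if not series.size:
        raise ValueError("empty series")
    if not (series[0] > 0):
        warnings.warn(
            "first time-point value is not positive; condition excluded from "
            "growth-rate analysis",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(series, np.nan)
    return series / series[0]


def mean_gr(series: np.ndarray, times: np.ndarray, log_base: str = "natural") -> np.ndarray:
    """Interval-mean growth rate <GR>(c, t) = log(x(t)/x(0)) / t for t > 0.

    ``series`` is the t0-rescaled trajectory.  NaN at t = 0 and wherever the
    trajectory is non-positive.  ``log_base`` ``"base2"`` expresses rates in
    doublings per hour instead of e-foldings.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    base = LOG_BASES[log_base]
    out = np.full_like(series, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = (times > 0) & (series > 0)
        out[valid] = np.log(series[valid]) / np.log(base) / times[valid]
    return out


def _smooth_mean_gr(g: np.ndarray, t: np.ndarray, smoothing: float | None):
    """Least-squares cubic smoothing spline of <GR> over time.

    The smoothing target defaults to ``n * sigma^2`` with ``sigma^2``
    estimated from second differences, so noiseless input is interpolated
    exactly (shape preserving).
    """
    if smoothing is None:
        if g.size >= 3:
            d2 = np.diff(g, 2)
            sigma2 = float(np.mean(d2**2)) / 6.0  # var of 2nd diff = 6 sigma^2
        else:
            sigma2 = 0.0
        smoothing = g.size * sigma2
        scale = float(np.mean(g**2)) or 1.0
        if smoothing < 1e-12 * scale:  # effectively noiseless: interpolate
            smoothing = 0.0
    k = min(3, g.size - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        spl = UnivariateSpline(t, g, k=k, s=smoothing)
    return spl(t), smoothing


def inst_gr(
    mean_gr_values: np.ndarray,
    times: np.ndarray,
    smoothing: float | None = None,
) -> tuple[np.ndarray, float]:
    """Instantaneous growth rate GR(c, t) reconstructed from <GR>(c, t).

    Needs >=3 time points with t > 0 and finite <GR>.  Returns the GR series
    (NaN where undefined) and the smoothing factor used.
    """
    g = np.asarray(mean_gr_values, dtype=float)
    t = np.asarray(times, dtype=float)
    valid = np.isfinite(g) & (t > 0)
    if valid.sum() < 3:
        raise ValueError("instantaneous GR needs >=3 time points with t > 0")
    tv, gv = t[valid], g[valid]
    smooth_g, s_used = _smooth_mean_gr(gv, tv, smoothing)
    # central finite differences of the smoothed <GR>; one-sided at the ends
    dg = np.gradient(smooth_g, tv)
    gr = np.full_like(g, np.nan)
    out = np.empty_like(gv)
    for i in range(gv.size):
        i1 = max(i - 1, 0)
        i2 = min(i + 1, gv.size - 1)
        out[i] = 0.5 * (smooth_g[i2] + smooth_g[i1]) + tv[i] * 0.5 * (dg[i2] + dg[i1])
    gr[valid] = out
    return gr, s_used


def rel_gr(condition_gr: np.ndarray, control_gr: np.ndarray) -> np.ndarray:
    """Control-relative GR: GR_condition / GR_control per time point.

    NaN (with a warning) wherever the control rate is not strictly positive.
    """
    condition_gr = np.asarray(condition_gr, dtype=float)
    control_gr = np.asarray(control_gr, dtype=float)
    bad = np.isfinite(control_gr) & (control_gr <= 0)
    if np.any(bad):
        warnings.warn(
            "control growth rate <= 0 at some time points; relative GR "
            "unavailable there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = condition_gr / control_gr
    out = np.where(control_gr > 0, out, np.nan)
    return out


def gr_series(
    series: np.ndarray,
    times: np.ndarray,
    control_series: np.ndarray | None = None,
    smoothing: float | None = None,
    log_base: str = "natural",
) -> GRSeries:
    """Full growth-rate analysis of one condition (optionally vs. a control)."""
    times = np.asarray(times, dtype=float)
    rescaled = rescale_to_t0(series)
    mgr = mean_gr(rescaled, times, log_base)
    igr = None
    s_used = smoothing
    if np.sum(np.isfinite(mgr) & (times > 0)) >= 3:
        igr, s_used = inst_gr(mgr, times, smoothing)
    rgr = None
    if control_series is not None and igr is not None:
        ctrl_mgr = mean_gr(rescale_to_t0(control_series), times, log_base)
        ctrl_igr, _ = inst_gr(ctrl_mgr, times, smoothing)
        rgr = rel_gr(igr, ctrl_igr)
    return GRSeries(
        times=times,
        mean_gr=mgr,
        inst_gr=igr,
        rel_gr=rgr,
        smoothing=s_used,
        log_base=log_base,
    )
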