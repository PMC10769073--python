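"""Control-relative normalization of raw read-outs, per time point.

Fractional effects are inhibition ``1 - value/control`` or enhancement
``value/control - 1``, computed against the time-matched (pooled) control.
Effects are kept as fractions internally and may leave [0, 1] here; capping
happens in the synergy module, immediately before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NormalizationError, ReplicateError

MODES = ("inhibition", "enhancement")


@dataclass
class EffectSeries:
    """Control-relative fractional effect per (time, condition)."""

    effect: np.ndarray  # [time x condition]
    mode: str
    rescaled_sd: np.ndarray | None = None
    ci95: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def normalize_to_control(
    values: np.ndarray,
    control_values: np.ndarray,
    mode: str = "inhibition",
) -> EffectSeries:
    """Normalize a [time x condition] matrix to a per-time-point control series.

    inhibition(t, c) = 1 - value(t, c) / control(t);
    enhancement(t, c) = value(t, c) / control(t) - 1.

    The control must be strictly positive wherever any condition is measured.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if control.shape[0] != values.shape[0]:
        raise NormalizationError("control series length does not match time axis")
    used = np.any(~np.isnan(values), axis=1)
    bad = used & ~(control > 0)
    if np.any(bad):
        t = int(np.flatnonzero(bad)[0])
        raise NormalizationError(
            f"control read-out is zero/negative at time index {t} "
            f"(value {control[t]!r}); cannot normalize"
        )
    ratio = values / control[:, None]
    effect = 1.0 - ratio if mode == "inhibition" else ratio - 1.0
    return EffectSeries(effect=effect, mode=mode)


def rescale_sd(sd_condition: np.ndarray, sd_control: np.ndarray) -> np.ndarray:
    """Rescale condition SDs by the control SD (elementwise quotient).

    Cells with zero control SD become NaN with a warning.
    """
    sd_condition = np.asarray(sd_condition, dtype=float)
    sd_control = np.asarray(sd_control, dtype=float)
    if sd_condition.ndim == 1:
        sd_condition = sd_condition[:, None]
    denom = sd_control[:, None] if sd_control.ndim == 1 else sd_control
    zero = denom == 0
    if np.any(zero & ~np.isnan(sd_condition)):
        warnings.warn(
            "control SD is zero at some time points; rescaled SD unavailable there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sd_condition / denom
    out = np.where(zero, np.nan, out)
    return out


def pool_controls(control_series: list[np.ndarray]):
    """Pool >=2 control series into one mean control with SD and 95% CI.

    All series must share the time grid (same length, no interpolation).
    Returns ``(mean, sd, ci95_halfwidth)`` per time point.
    """
    if len(control_series) < 1:
        raise ReplicateError("no control series to pool")
    arrs = [np.asarray(c, dtype=float) for c in control_series]
    n0 = arrs[0].shape[0]
    if any(a.shape[0] != n0 for a in arrs):
        raise ReplicateError("control series have mismatched time grids")
    stack = np.column_stack(arrs)
    k = stack.shape[1]
    mean = np.nanmean(stack, axis=1)
    if k >= 2:
        sd = np.nanstd(stack, axis=1, ddof=1)
        ci = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
    else:
        sd = np.full(n0, np.nan)
        ci = np.full(n0, np.nan)
    return mean, sd, ci
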