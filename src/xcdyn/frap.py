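"""FRAP trace correction, double normalization and recovery summaries.

The bleached-ROI signal is first background-subtracted and scaled to
its prebleach mean (Ic), then divided by the identically normalized
unbleached control region (Icb) to remove acquisition photobleaching.
Background and control traces are replaced by exponential-decay fits
before normalization, which suppresses their shot noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_io import FrapTraceSet, ValidationError


@dataclass
class ExponentialDecayFit:
    """A·e^(−k·t) + C least-squares fit of one trace."""

    amplitude: float
    rate: float  # s⁻¹, >= 0
    offset: float
    residual_rms: float
    converged: bool

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(t)) + self.offset


def fit_exponential_decay(trace: np.ndarray, time: np.ndarray) -> ExponentialDecayFit:
    """Fit A·e^(−k·t) + C to a trace (k constrained non-negative).

    Falls back to a flat fit (A = 0, C = mean) flagged as
    non-converged when the optimizer fails.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if trace.size < 5:
        raise ValidationError("need at least 5 points to fit a decay")
    span = float(trace[0] - trace[-1])
    t_span = float(time[-1] - time[0])
    p0 = [span, max(1.0 / t_span, 1e-6) if span != 0 else 1e-6, float(trace[-1])]

    def model(p):
        return p[0] * np.exp(-p[1] * time) + p[2]

    def residual(p):
        return model(p) - trace

    try:
        res = optimize.least_squares(
            residual, p0, bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf])
        )
        ok = bool(res.success)
        p = res.x
    except Exception:
        ok = False
        p = None
    if not ok or p is None:
        mean = float(trace.mean())
        rms = float(np.sqrt(np.mean((trace - mean) ** 2)))
        return ExponentialDecayFit(0.0, 0.0, mean, rms, False)
    rms = float(np.sqrt(np.mean((model(p) - trace) ** 2)))
    return ExponentialDecayFit(float(p[0]), float(p[1]), float(p[2]), rms, True)


@dataclass
class FrapCurve:
    """Normalized FRAP recovery for one cell.

    ``ic`` is background-subtracted and prebleach-scaled; ``icb``
    additionally divides out acquisition bleaching measured in the
    control region. The mean of ``icb`` over prebleach frames is 1 up
    to fit error.
    """

    time: np.ndarray
    ic: np.ndarray
    icb: np.ndarray
    bleach_frame: int
    prebleach_roi_mean: float
    region: str = ""


def normalize_frap(
    traces: FrapTraceSet, use_fits: bool = True, region: str = ""
) -> FrapCurve:
    """Double-normalize a FRAP trace set.

    Background and control traces are replaced by their exponential
    fits (``use_fits=False`` keeps the raw traces, for diagnostics).
    Prebleach means are taken over all frames before ``bleach_frame``.
    """
    t = traces.time
    pre = np.arange(traces.n_frames) < traces.bleach_frame
    if use_fits:
        bkg = fit_exponential_decay(traces.background, t)(t)
        ctrl = fit_exponential_decay(traces.control, t)(t)
    else:
        bkg = traces.background
        ctrl = traces.control
    denom_roi = float(traces.roi[pre].mean() - bkg[pre].mean())
    denom_ctrl = float(ctrl[pre].mean() - bkg[pre].mean())
    if denom_roi <= 0 or denom_ctrl <= 0:
        raise ValidationError("prebleach signal does not exceed background")
    ic = (traces.roi - bkg) / denom_roi
    ctrl_norm = (ctrl - bkg) / denom_ctrl
    icb = ic / ctrl_norm
    return FrapCurve(
        time=t,
        ic=ic,
        icb=icb,
        bleach_frame=traces.bleach_frame,
        prebleach_roi_mean=float(traces.roi[pre].mean()),
        region=region,
    )


@dataclass
class AggregateFrap:
    """Pointwise mean recovery across cells with a 95% CI band."""

    time: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: int


def aggregate_frap(curves: list[FrapCurve]) -> AggregateFrap:
    """Mean Icb curve over cells with normal-approximation 95% CI.

    Curves are truncated to the shortest common length; with a single
    curve the CI is undefined (NaN band).
    """
    if not curves:
        raise ValidationError("no curves to aggregate")
    n_frames = min(c.icb.size for c in curves)
    arr = np.vstack([c.icb[:n_frames] for c in curves])
    t = curves[0].time[:n_frames]
    mean = arr.mean(axis=0)
    if len(curves) < 2:
        warnings.warn("fewer than 2 curves; CI undefined", stacklevel=2)
        band = np.full(n_frames, np.nan)
    else:
        band = 1.96 * arr.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return AggregateFrap(
        time=t, mean=mean, ci_lo=mean - band, ci_hi=mean + band, n=len(curves)
    )


def plateau_fraction(curve: FrapCurve | AggregateFrap, t_eval: float) -> float:
    """Recovered fraction at time ``t_eval``.

    (Icb(t_eval) − Icb(first post-bleach frame)) divided by the bleach
    depth (1 − Icb(first post-bleach frame)). Undefined (NaN) when no
    bleaching occurred.
    """
    time = curve.time
    values = curve.icb if isinstance(curve, FrapCurve) else curve.mean
    bleach_frame = (
        curve.bleach_frame if isinstance(curve, FrapCurve) else int(np.argmin(values))
    )
    if not time[0] <= t_eval <= time[-1]:
        raise ValidationError("t_eval outside the trace")
    i0 = bleach_frame
    v0 = float(values[i0])
    depth = 1.0 - v0
    if depth <= 0:
        return np.nan
    v_t = float(np.interp(t_eval, time, values))
    return (v_t - v0) / depth
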