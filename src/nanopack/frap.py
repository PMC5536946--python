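"""FRAP recovery analysis.

Workflow: extract background-corrected bleach/control traces from an image
time series, screen recordings for out-of-focus drift on the control region
(first 10 vs last 3 frames, >15% excludes), average the surviving traces, fit
the post-bleach segment with a hyperbola-plus-offset

    F(t) = offset + amplitude * t / (t_half + t)

and read off the half-time of recovery.  Fits with R^2 below 0.7 are flagged
as not accepted.  The half-time is invariant to any positive rescaling of the
trace, so fitting raw or pre-bleach-normalized traces gives identical t_half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FrapTrace",
    "FrapQC",
    "HyperbolaFit",
    "extract_trace",
    "drift_qc",
    "fit_hyperbola",
    "fit_trace",
    "average_traces",
    "halftime_vs_expression",
]

DRIFT_LIMIT = 0.15
R2_ACCEPT = 0.7


@dataclass
class FrapTrace:
    """Background-corrected intensity traces of one FRAP recording."""

    times_s: np.ndarray
    roi_intensity: np.ndarray       # bleach ROI, background corrected
    control_intensity: np.ndarray   # non-bleached control region, background corrected
    background: np.ndarray
    n_prebleach: int = 10
    bleach_index: int = 10          # index of first post-bleach frame

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.roi_intensity = np.asarray(self.roi_intensity, float)
        self.control_intensity = np.asarray(self.control_intensity, float)
        self.background = np.asarray(self.background, float)
        n = len(self.times_s)
        if not (len(self.roi_intensity) == len(self.control_intensity) == len(self.background) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def prebleach_mean(self) -> float:
        return float(self.roi_intensity[: self.n_prebleach].mean())

    def postbleach(self) -> tuple[np.ndarray, np.ndarray]:
        """(times re-zeroed at the first post-bleach frame, intensities)."""
        t = self.times_s[self.bleach_index :]
        return t - t[0], self.roi_intensity[self.bleach_index :]


@dataclass
class FrapQC:
    drift_fraction: float | None
    passed: bool
    reason: str | None = None


@dataclass
class HyperbolaFit:
    t_half_s: float | None
    amplitude: float | None
    offset: float | None
    r2: float | None
    accepted: bool
    reason: str | None = None


def _roi_slices(roi, shape) -> tuple[slice, slice]:
    x, y, w, h = roi
    if w <= 0 or h <= 0:
        raise ValueError("ROI width and height must be > 0")
    if x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0]:
        raise ValueError(f"ROI {roi} outside frame of shape {shape}")
    return slice(y, y + h), slice(x, x + w)


def _rects_overlap(a, b) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def extract_trace(
    stack: np.ndarray,
    bleach_roi: tuple[int, int, int, int],
    control_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    times_s: np.ndarray | None = None,
    n_prebleach: int = 10,
    bleach_index: int | None = None,
) -> FrapTrace:
    """Per-frame ROI means with background subtraction.

    ROIs are (x, y, w, h) rectangles; they must be pairwise disjoint and lie
    inside the frame.  The background ROI mean is subtracted frame-wise from
    both the bleach and the control trace.
    """
    stack = np.asarray(stack, float)
    shape = stack.shape[1:]
    rois = dict(bleach=bleach_roi, control=control_roi, background=background_roi)
    slc = {k: _roi_slices(v, shape) for k, v in rois.items()}
    names = list(rois)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _rects_overlap(rois[a], rois[b]):
                raise ValueError(f"{a} and {b} ROIs overlap")
    bg = stack[:, slc["background"][0], slc["background"][1]].mean(axis=(1, 2))
    roi = stack[:, slc["bleach"][0], slc["bleach"][1]].mean(axis=(1, 2)) - bg
    ctl = stack[:, slc["control"][0], slc["control"][1]].mean(axis=(1, 2)) - bg
    if times_s is None:
        times_s = np.arange(len(stack), dtype=float)
    return FrapTrace(
        times_s=times_s,
        roi_intensity=roi,
        control_intensity=ctl,
        background=bg,
        n_prebleach=n_prebleach,
        bleach_index=n_prebleach if bleach_index is None else bleach_index,
    )


def drift_qc(trace: FrapTrace) -> FrapQC:
    """Out-of-focus drift screen on the control region.

    Compares the mean of the last 3 control frames with the mean of the first
    10; a relative difference strictly greater than 15% excludes the
    recording (exactly 15% is retained).
    """
    ctl = trace.control_intensity
    if len(ctl) < 13:
        return FrapQC(None, False, reason="fewer than 13 control frames")
    first = float(ctl[:10].mean())
    if first == 0:
        return FrapQC(None, False, reason="zero reference control intensity")
    drift = abs(float(ctl[-3:].mean()) / first - 1.0)
    return FrapQC(drift_fraction=drift, passed=drift <= DRIFT_LIMIT)


def _hyperbola(t, offset, amplitude, t_half):
    return offset + amplitude * t / (t_half + t)


def fit_hyperbola(
    times_s: np.ndarray,
    values: np.ndarray,
    r2_min: float = R2_ACCEPT,
) -> HyperbolaFit:
    """Least-squares hyperbola-with-offset fit of a post-bleach segment.

    ``times_s`` must start at (or be re-zeroed to) the first post-bleach
    frame.  Initialisation: offset = first point, amplitude = span, t_half =
    time at which the trace first crosses half the span; t_half is bounded in
    (0, 10x duration].  Degenerate flat traces yield an unaccepted fit, not an
    exception.
    """
    t = np.asarray(times_s, float)
    v = np.asarray(values, float)
    t = t - t[0]
    duration = float(t[-1]) if len(t) > 1 else 1.0
    span = float(v[-1] - v[0])
    if np.ptp(v) == 0:
        return HyperbolaFit(None, None, float(v[0]) if len(v) else None, None,
                            accepted=False, reason="flat trace")
    half_level = v[0] + span / 2.0
    crossed = np.nonzero(v >= half_level)[0] if span > 0 else np.array([], int)
    t_half0 = float(t[crossed[0]]) if len(crossed) and t[crossed[0]] > 0 else duration / 4.0
    p0 = [float(v[0]), span, t_half0]
    try:
        popt, _ = optimize.curve_fit(
            _hyperbola,
            t,
            v,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 10.0 * duration]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return HyperbolaFit(None, None, None, None, accepted=False,
                            reason="fit did not converge")
    offset, amplitude, t_half = (float(p) for p in popt)
    resid = v - _hyperbola(t, *popt)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    accepted = r2 >= r2_min and t_half > 0
    return HyperbolaFit(t_half, amplitude, offset, r2,
                        accepted=accepted,
                        reason=None if accepted else f"R2 {r2:.3f} below {r2_min}")


def fit_trace(trace: FrapTrace, r2_min: float = R2_ACCEPT,
              normalize_prebleach: bool = False) -> HyperbolaFit:
    """Fit one trace's post-bleach segment; optional pre-bleach normalization
    (t_half and R^2 are invariant to it)."""
    t, v = trace.postbleach()
    if normalize_prebleach:
        pre = trace.prebleach_mean
        if pre <= 0:
            return HyperbolaFit(None, None, None, None, accepted=False,
                                reason="non-positive pre-bleach mean")
        v = v / pre
    return fit_hyperbola(t, v, r2_min=r2_min)


def average_traces(
    traces: list[FrapTrace], qc: list[FrapQC] | None = None
) -> pd.DataFrame | None:
    """Pointwise mean +- SD over QC-passed traces of one experiment.

    Returns a DataFrame (time_s, mean, sd, n) or None with a warning when no
    trace passes.
    """
    if qc is not None:
        traces = [tr for tr, q in zip(traces, qc) if q.passed]
    if not traces:
        warnings.warn("no traces passed QC; nothing to average")
        return None
    lengths = {len(tr.times_s) for tr in traces}
    if len(lengths) != 1:
        raise ValueError("traces must share length and timing")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if not np.allclose(tr.times_s, t0):
            raise ValueError("traces must share length and timing")
    vals = np.stack([tr.roi_intensity for tr in traces])
    return pd.DataFrame(
        dict(
            time_s=t0,
            mean=vals.mean(axis=0),
            sd=vals.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros(len(t0)),
            n=len(traces),
        )
    )


def halftime_vs_expression(
    fits: list[HyperbolaFit], prebleach_intensities: list[float]
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Per-cell (pre-bleach intensity, t_half) pairs with Spearman correlation.

    Pre-bleach intensity is a relative expression-level proxy.  Only accepted
    fits enter; with fewer than 3 cells, or a degenerate (constant) variable,
    the correlation is reported as None.
    """
    if len(fits) != len(prebleach_intensities):
        raise ValueError("fits and intensities must pair up")
    rows = [
        dict(prebleach=p, t_half_s=f.t_half_s)
        for f, p in zip(fits, prebleach_intensities)
        if f.accepted
    ]
    table = pd.DataFrame(rows, columns=["prebleach", "t_half_s"])
    if len(table) < 3:
        return table, None, None
    if table["t_half_s"].nunique() == 1 or table["prebleach"].nunique() == 1:
        return table, None, None
    rho, p = stats.spearmanr(table["prebleach"], table["t_half_s"])
    return table, float(rho), float(p)
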