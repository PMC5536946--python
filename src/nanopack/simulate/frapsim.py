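"""Diffusion-based FRAP simulator.

A mobile membrane pool diffuses on a 2D grid (explicit finite differences,
zero-flux boundaries) while an immobile pool stays put.  At the bleach event
both pools inside a square region of interest lose a fraction of their
fluorescence; frames are then sampled at the acquisition rate.  Because linear
diffusion is self-similar in D·t, the recovery half-time is inversely
proportional to the diffusion coefficient — the relation the analysis stage is
expected to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrapGroundTruth", "FrapSimResult", "simulate_frap_stack"]


@dataclass(frozen=True)
class FrapGroundTruth:
    """Parameters of one simulated FRAP recording.

    Defaults follow a typical confocal membrane-protein protocol: 1 Hz
    acquisition with a 10-frame pre-bleach sequence, a 500 ms bleach of a
    12 x 12 px region at 414 nm/px, and 200 s of recovery.
    """

    diffusion_coeff_um2_s: float = 0.1
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.9
    frame_rate_hz: float = 1.0
    n_prebleach: int = 10
    bleach_duration_s: float = 0.5
    post_duration_s: float = 200.0
    roi_px: int = 12
    pixel_size_nm: float = 414.0
    grid_px: int = 96
    drift_injection: float = 0.0  # fractional multiplicative trend over the recording
    intensity_scale: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        for name in ("frame_rate_hz", "bleach_duration_s", "post_duration_s", "pixel_size_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.diffusion_coeff_um2_s < 0:
            raise ValueError("diffusion_coeff_um2_s must be >= 0")
        if self.grid_px < 4 * self.roi_px:
            raise ValueError("grid must span at least 4x the bleach ROI")


@dataclass
class FrapSimResult:
    stack: np.ndarray            # (n_frames, grid, grid)
    times_s: np.ndarray          # (n_frames,)
    bleach_index: int            # index of the first post-bleach frame
    roi_slice: tuple[slice, slice]
    roi_trace_truth: np.ndarray  # noise- and drift-free mean ROI concentration
    truth: FrapGroundTruth = field(repr=False, default=None)


def _laplacian(c: np.ndarray) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) boundaries; conserves mass."""
    p = np.pad(c, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * c


def simulate_frap_stack(
    truth: FrapGroundTruth,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt_s: float | None = None,
) -> FrapSimResult:
    """Run the diffusion simulation and sample the image time series.

    ``dt_s`` optionally fixes the integration step; a step above the explicit
    stability bound dx^2/(4D) is refused with the required step in the message.
    By default the step is 0.9x the bound.  ``noise_sd`` adds Gaussian noise
    (in the same a.u. as ``intensity_scale``) to the sampled frames.
    """
    n = truth.grid_px
    dx_um = truth.pixel_size_nm / 1000.0
    d_px = truth.diffusion_coeff_um2_s / (dx_um * dx_um)  # px^2 / s
    frame_dt = 1.0 / truth.frame_rate_hz

    if d_px > 0:
        dt_max = (dx_um * 0 + 1.0) / (4.0 * d_px)  # dx = 1 px
        if dt_s is not None:
            if dt_s > dt_max:
                raise ValueError(
                    f"time step {dt_s:g} s violates the explicit stability bound; "
                    f"required step <= {dt_max:g} s"
                )
            dt = dt_s
        else:
            dt = 0.9 * dt_max
    else:
        dt = dt_s if dt_s is not None else frame_dt

    mobile = np.full((n, n), 1.0 - truth.immobile_fraction)
    immobile = np.full((n, n), truth.immobile_fraction)

    lo = (n - truth.roi_px) // 2
    roi = (slice(lo, lo + truth.roi_px), slice(lo, lo + truth.roi_px))

    rng = np.random.default_rng(seed)
    n_post = int(round(truth.post_duration_s * truth.frame_rate_hz))
    times = np.empty(truth.n_prebleach + n_post)
    frames = np.empty((len(times), n, n))
    roi_truth = np.empty(len(times))

    def evolve(duration: float):
        nonlocal mobile
        steps = int(np.ceil(duration / dt)) if duration > 0 else 0
        if steps == 0 or d_px == 0:
            return
        h = duration / steps
        alpha = d_px * h
        for _ in range(steps):
            mobile = mobile + alpha * _laplacian(mobile)

    t_end = (truth.n_prebleach - 1) * frame_dt + truth.bleach_duration_s + n_post * frame_dt

    def record(i: int, t: float):
        conc = mobile + immobile
        roi_truth[i] = conc[roi].mean()
        frame = truth.intensity_scale * conc
        if truth.drift_injection:
            frame = frame * (1.0 + truth.drift_injection * t / t_end)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        frames[i] = frame
        times[i] = t

    # pre-bleach frames (static: nothing evolves before the bleach perturbs it)
    for i in range(truth.n_prebleach):
        record(i, i * frame_dt)

    # The bleach laser destroys fluorophores throughout its 500 ms window, so
    # the depleted state is reached at the window's end; the first post-bleach
    # frame is the scan acquired immediately afterwards.  This keeps recovery
    # time zero aligned with the first sampled frame, preserving the exact
    # t_half ~ 1/D scaling of self-similar diffusion.
    mobile[roi] *= 1.0 - truth.bleach_depth
    immobile[roi] *= 1.0 - truth.bleach_depth
    t0 = (truth.n_prebleach - 1) * frame_dt + truth.bleach_duration_s
    record(truth.n_prebleach, t0)

    for k in range(1, n_post):
        evolve(frame_dt)
        record(truth.n_prebleach + k, t0 + k * frame_dt)

    return FrapSimResult(
        stack=frames,
        times_s=times,
        bleach_index=truth.n_prebleach,
        roi_slice=roi,
        roi_trace_truth=roi_truth,
        truth=truth,
    )
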