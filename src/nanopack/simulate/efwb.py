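"""Generators for paired epifluorescence / western-blot (EF/WB) experiments.

The EF/WB scheme compares two epitope-tagged constructs: microscopy signal
scales with epitope accessibility in situ (packing-sensitive) while the blot
signal, measured after lysis, does not.  Each simulated transfection pair
carries large multiplicative batch nuisances (imaging settings, blotting
efficiency) that cancel exactly in the ratio-of-ratios, leaving the
accessibility ratio of the two constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import _apply_noise, ImagingConfig, render_emitters

__all__ = [
    "EfwbGroundTruth",
    "simulate_efwb_experiment",
    "simulate_ef_image_set",
    "simulate_bont_cohort",
]

REFERENCE = "reference"
VARIANT = "variant"


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


@dataclass
class EfwbGroundTruth:
    """Ground truth of a paired EF/WB experiment.

    accessibility maps construct name -> fraction of epitopes reachable by the
    antibody in situ; the quantity the analysis recovers is the variant /
    reference accessibility ratio.  Batch scales are per-pair nuisance
    multipliers (drawn lognormal with ``batch_scale_sigma`` if not given).
    """

    n_pairs: int = 14
    accessibility: dict = None
    expression_level: float = 1.0
    expression_cv: float = 0.5
    batch_scale_sigma: float = 1.0
    microscopy_batch_scale: np.ndarray | None = None
    blot_batch_scale: np.ndarray | None = None
    noise_cv: float = 0.3

    def __post_init__(self):
        if self.accessibility is None:
            self.accessibility = {REFERENCE: 0.2, VARIANT: 0.6}
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for c, a in self.accessibility.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"accessibility[{c!r}] must be in (0, 1]")
        for arr in (self.microscopy_batch_scale, self.blot_batch_scale):
            if arr is not None and np.any(np.asarray(arr) <= 0):
                raise ValueError("batch scales must be > 0")

    @property
    def true_ratio(self) -> float:
        return self.accessibility[VARIANT] / self.accessibility[REFERENCE]


def simulate_efwb_experiment(
    truth: EfwbGroundTruth, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit tidy (ef_table, wb_table) for all pairs and constructs.

    For pair i and construct c:
        EF_raw = m_i * expression_ic * accessibility_c * noise
        WB_raw = b_i * expression_ic * noise
    with m_i, b_i the microscopy/blot batch scales.  WB rows carry raw band
    and loading-control intensities whose quotient is the blot value.
    """
    rng = np.random.default_rng(seed)
    m = truth.microscopy_batch_scale
    b = truth.blot_batch_scale
    if m is None:
        m = rng.lognormal(0.0, truth.batch_scale_sigma, truth.n_pairs)
    if b is None:
        b = rng.lognormal(0.0, truth.batch_scale_sigma, truth.n_pairs)
    m = np.broadcast_to(np.asarray(m, float), (truth.n_pairs,))
    b = np.broadcast_to(np.asarray(b, float), (truth.n_pairs,))

    ef_rows, wb_rows = [], []
    for i in range(truth.n_pairs):
        for construct, access in truth.accessibility.items():
            expr = truth.expression_level * _lognormal_factor(rng, truth.expression_cv)
            tid = f"P{i:02d}-{construct}"
            ef = m[i] * expr * access * _lognormal_factor(rng, truth.noise_cv)
            loading = _lognormal_factor(rng, 0.1) if truth.noise_cv > 0 else 1.0
            band = b[i] * expr * _lognormal_factor(rng, truth.noise_cv) * loading
            ef_rows.append(
                dict(pair_id=i, transfection_id=tid, construct=construct, ef_value=ef)
            )
            wb_rows.append(
                dict(
                    pair_id=i,
                    transfection_id=tid,
                    construct=construct,
                    band_intensity=band,
                    loading_control=loading,
                )
            )
    return pd.DataFrame(ef_rows), pd.DataFrame(wb_rows)


def simulate_ef_image_set(
    n_images: int = 4,
    cells_per_image: int = 8,
    per_cell_signal: float = 2.0e5,
    per_cell_cv: float = 0.25,
    signal_sigma_px: float = 2.0,
    nucleus_amplitude: float = 800.0,
    shape: tuple[int, int] = (128, 128),
    cfg: ImagingConfig | None = None,
    seed: int | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Render (myc_images, dapi_images, mock_images) for the EF quantification.

    Each cell contributes a Gaussian patch of integrated tag signal
    ``per_cell_signal`` in the green channel and a compact nucleus blob in the
    DAPI channel; mock images carry background only, from the same noise
    model, and define the background threshold downstream.
    """
    if cfg is None:
        cfg = ImagingConfig(photon_scale=0.0, camera_offset=100.0, read_noise_sd=5.0)
    rng = np.random.default_rng(seed)
    myc_images, dapi_images, mock_images = [], [], []
    h, w = shape
    margin = 12
    for _ in range(n_images):
        pos = rng.uniform(margin, [h - margin, w - margin], size=(cells_per_image, 2))
        pos_nm = pos[:, ::-1] * cfg.pixel_size_nm + 0.5 * cfg.pixel_size_nm  # (x, y) nm
        signals = per_cell_signal * _lognormal_factor(rng, per_cell_cv, cells_per_image)
        myc = np.zeros(shape)
        for p_nm, s in zip(pos_nm, signals):
            peak = s / (2.0 * np.pi * signal_sigma_px**2)
            myc += render_emitters(p_nm[None], shape, cfg.pixel_size_nm,
                                   2.3548 * signal_sigma_px * cfg.pixel_size_nm, peak)
        dapi = render_emitters(pos_nm, shape, cfg.pixel_size_nm,
                               2.3548 * 1.5 * cfg.pixel_size_nm, nucleus_amplitude)
        myc_images.append(_apply_noise(myc, cfg, rng))
        dapi_images.append(_apply_noise(dapi, cfg, rng))
        mock_images.append(_apply_noise(np.zeros(shape), cfg, rng))
    return myc_images, dapi_images, mock_images


def simulate_bont_cohort(
    n_cells_per_condition: int = 40,
    accessibility_factor: float = 1.5,
    area_factor: float = 0.7,
    base_signal: float = 1000.0,
    base_area: float = 2000.0,
    autofluorescence_mean: float = 50.0,
    toxin_gfp_mean: float = 300.0,
    noise_cv: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell table for the toxin co-expression comparison.

    Two conditions: tag-only cells (``cotransfected=False``, defining the GFP
    autofluorescence level) and toxin co-expressing cells whose per-cell total
    tag signal is scaled by ``accessibility_factor`` while the cell footprint
    shrinks by ``area_factor``.  Mean intensity is total signal / area, so the
    raw means overstate the accessibility change — the bias the size
    correction removes.  A few co-transfected cells receive autofluorescence-
    level GFP to exercise the gating rule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cotrans, acc, af in ((False, 1.0, 1.0), (True, accessibility_factor, area_factor)):
        for k in range(n_cells_per_condition):
            area = base_area * af * _lognormal_factor(rng, noise_cv)
            total = base_signal * acc * _lognormal_factor(rng, noise_cv)
            if cotrans:
                # ~10% of co-transfected cells failed to take up the toxin plasmid
                has_toxin = rng.random() > 0.1
                gfp = (toxin_gfp_mean if has_toxin else 0.5 * autofluorescence_mean)
                gfp *= _lognormal_factor(rng, noise_cv)
            else:
                gfp = autofluorescence_mean * _lognormal_factor(rng, noise_cv)
            rows.append(
                dict(
                    cell_id=f"{'tox' if cotrans else 'ctl'}{k:03d}",
                    condition="with_toxin" if cotrans else "without_toxin",
                    cotransfected=cotrans,
                    gfp_mean=gfp,
                    myc_mean=total / area,
                    cell_area=area,
                )
            )
    return pd.DataFrame(rows)
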