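"""Surface/internal localization assays.

Two complementary measurements of how much of a membrane protein pool resides
at the cell surface:

* the pH-quench assay — surface-exposed GFP is quenched by acidic external
  buffer, so the per-cell intensity ratio pH 4.3 / pH 7.4 reports the
  protected internal fraction;
* the x-z slice-stack analysis — the membrane contour traced on a membrane-
  marker channel is contracted/expanded by 5 px to delineate cytosol and whole
  cell, and the antibody-channel signal integrals give the cytosolic fraction,
  after correcting the antibody channel for marker-channel bleed-through
  (6% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk, erosion

__all__ = [
    "QuenchRecord",
    "SliceStack",
    "FractionResult",
    "quench_fraction",
    "bleedthrough_correct",
    "cytosolic_fraction",
]

DEFAULT_BLEEDTHROUGH = 0.06


@dataclass
class QuenchRecord:
    cell_id: int
    intensity_ph74: float
    intensity_ph43: float
    remaining_fraction: float


@dataclass
class SliceStack:
    """Ordered x-z sections of one cell: (marker, antibody) channel pairs plus
    a traced membrane ROI (boolean mask) per slice."""

    marker_slices: list[np.ndarray]
    antibody_slices: list[np.ndarray]
    membrane_rois: list[np.ndarray]
    bleedthrough_coeff: float = DEFAULT_BLEEDTHROUGH
    cell_id: str = ""

    def __post_init__(self):
        if not (len(self.marker_slices) == len(self.antibody_slices) == len(self.membrane_rois)):
            raise ValueError("slice lists must have equal length")
        for m, a in zip(self.marker_slices, self.antibody_slices):
            if m.shape != a.shape:
                raise ValueError("marker and antibody slices must share shape")
        if not 0.0 <= self.bleedthrough_coeff < 1.0:
            raise ValueError("bleedthrough_coeff must be in [0, 1)")


@dataclass
class FractionResult:
    cell_id: str
    cytosolic_signal: float
    total_signal: float
    cytosolic_fraction: float


def _region_mean(image: np.ndarray, region) -> float:
    img = np.asarray(image, float)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if not region.any():
            raise ValueError("empty background region")
        return float(img[region].mean())
    (y0, y1), (x0, x1) = region
    return float(img[y0:y1, x0:x1].mean())


def quench_fraction(
    image_ph74: np.ndarray,
    image_ph43: np.ndarray,
    cell_masks: np.ndarray,
    background_region,
) -> list[QuenchRecord]:
    """Per-cell remaining fraction after the pH 7.4 -> 4.3 switch.

    ``cell_masks`` is a label image shared by both acquisitions (the same
    cells are imaged twice).  Intensities are cell-mean minus the background
    region's mean, per image; cells whose corrected pH 7.4 intensity is not
    positive are skipped with a warning.
    """
    img74 = np.asarray(image_ph74, float)
    img43 = np.asarray(image_ph43, float)
    if img74.shape != img43.shape or img74.shape != cell_masks.shape:
        raise ValueError("images and mask must share shape")
    bg74 = _region_mean(img74, background_region)
    bg43 = _region_mean(img43, background_region)
    records = []
    for lab in np.unique(cell_masks):
        if lab == 0:
            continue
        m = cell_masks == lab
        i74 = float(img74[m].mean()) - bg74
        i43 = float(img43[m].mean()) - bg43
        if i74 <= 0:
            warnings.warn(f"cell {lab}: non-positive corrected pH 7.4 intensity; skipped")
            continue
        records.append(QuenchRecord(int(lab), i74, i43, i43 / i74))
    return records


def bleedthrough_correct(
    antibody_image: np.ndarray,
    marker_image: np.ndarray,
    coeff: float = DEFAULT_BLEEDTHROUGH,
) -> np.ndarray:
    """Subtract marker-channel bleed-through from the antibody channel.

    corrected = antibody - coeff * marker, clamped at zero.
    """
    if not 0.0 <= coeff < 1.0:
        raise ValueError("coeff must be in [0, 1)")
    a = np.asarray(antibody_image, float)
    m = np.asarray(marker_image, float)
    if a.shape != m.shape:
        raise ValueError("images must share shape")
    return np.clip(a - coeff * m, 0.0, None)


def cytosolic_fraction(
    stack: SliceStack,
    background_cells_value: float = 0.0,
    expand_px: int = 5,
    apply_bleedthrough: bool = True,
) -> FractionResult:
    """Cytosolic / total signal of one cell from its x-z slice stack.

    Per slice the traced membrane region is eroded by ``expand_px`` (inner
    ROI, cytosol) and dilated by the same amount (outer ROI, whole cell) with
    a disk structuring element; the bleed-through-corrected antibody signal is
    integrated over both, background (the per-pixel mean measured on
    non-transfected control cells) subtracted, and summed over slices.  The
    fraction is clamped to [0, 1].
    """
    selem = disk(expand_px)
    cyto = 0.0
    total = 0.0
    for k, (marker, antibody, roi) in enumerate(
        zip(stack.marker_slices, stack.antibody_slices, stack.membrane_rois)
    ):
        roi = np.asarray(roi, bool)
        signal = (
            bleedthrough_correct(antibody, marker, stack.bleedthrough_coeff)
            if apply_bleedthrough
            else np.asarray(antibody, float)
        )
        inner = erosion(roi, selem)
        outer = dilation(roi, selem)
        if not inner.any():
            warnings.warn(f"slice {k}: inner ROI empty after erosion; contributes 0 cytosolic")
        else:
            cyto += float(signal[inner].sum()) - background_cells_value * int(inner.sum())
        total += float(signal[outer].sum()) - background_cells_value * int(outer.sum())
    cyto = max(cyto, 0.0)
    total = max(total, 0.0)
    frac = min(cyto / total, 1.0) if total > 0 else 0.0
    return FractionResult(stack.cell_id, cyto, total, frac)
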