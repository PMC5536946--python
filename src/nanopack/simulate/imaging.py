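"""Rendering of synthetic confocal/STED images and pH-quench image pairs.

Every bound antibody is rendered as an isotropic 2D Gaussian whose FWHM is the
channel's point-spread function; expected photon counts then receive Poisson
shot noise, additive Gaussian read noise and a constant camera offset.  The
confocal and STED channels share the same underlying geometry, differing only
in PSF width — mirroring simultaneous two-channel acquisition on a STED
microscope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clusters import ClusterField

__all__ = [
    "ImagingConfig",
    "QuenchGroundTruth",
    "render_image_pair",
    "render_emitters",
    "simulate_quench_pair",
    "simulate_slice_stack",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition parameters shared by the synthetic microscopes.

    pixel_size_nm
        Length per pixel; 20 nm is the STED-mode acquisition setting.
    psf_fwhm_confocal_nm / psf_fwhm_sted_nm
        Gaussian PSF widths of the two channels.
    photon_scale
        Expected photon count at the peak of a single bound label.
    camera_offset, read_noise_sd
        Additive detector baseline and Gaussian read noise, in a.u.
    """

    pixel_size_nm: float = 20.0
    psf_fwhm_confocal_nm: float = 250.0
    psf_fwhm_sted_nm: float = 60.0
    photon_scale: float = 200.0
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    rng_seed: int | None = None

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not self.psf_fwhm_sted_nm < self.psf_fwhm_confocal_nm:
            raise ValueError("STED PSF must be narrower than confocal PSF")
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")


def render_emitters(
    positions_nm: np.ndarray,
    shape: tuple[int, int],
    pixel_size_nm: float,
    psf_fwhm_nm: float,
    amplitude: float,
) -> np.ndarray:
    """Noise-free expected-photon image of point emitters.

    Each emitter contributes ``amplitude * exp(-r^2 / 2 sigma^2)`` evaluated at
    pixel centres (pixel i spans [i*p, (i+1)*p) nm).  Kernels are truncated at
    5 sigma; the neglected mass is < 4e-6 of a kernel.
    """
    img = np.zeros(shape, float)
    positions_nm = np.asarray(positions_nm, float).reshape(-1, 2)
    if len(positions_nm) == 0:
        return img
    sigma_px = psf_fwhm_nm * _FWHM_TO_SIGMA / pixel_size_nm
    rad = int(np.ceil(5.0 * sigma_px))
    h, w = shape
    for x_nm, y_nm in positions_nm:
        # pixel-centre coordinates of the emitter
        cx = x_nm / pixel_size_nm - 0.5
        cy = y_nm / pixel_size_nm - 0.5
        x0 = max(int(np.floor(cx)) - rad, 0)
        x1 = min(int(np.ceil(cx)) + rad + 1, w)
        y0 = max(int(np.floor(cy)) - rad, 0)
        y1 = min(int(np.ceil(cy)) + rad + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma_px**2))
        img[y0:y1, x0:x1] += amplitude * g
    return img


def _apply_noise(
    expected: np.ndarray, cfg: ImagingConfig, rng: np.random.Generator
) -> np.ndarray:
    out = rng.poisson(np.clip(expected, 0, None)).astype(float)
    if cfg.read_noise_sd > 0:
        out += rng.normal(0.0, cfg.read_noise_sd, size=out.shape)
    return out + cfg.camera_offset


def render_image_pair(
    field: ClusterField,
    cfg: ImagingConfig,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (confocal, STED) images of a field with filled antibody occupancy.

    With ``noise=False`` the returned images are the expected photon counts
    plus the camera offset, so rendering is exactly linear in the emitter set.
    """
    if field.occupancy is None:
        raise ValueError("field has no antibody occupancy; run simulate_antibody_binding first")
    n_px = int(round(field.side_nm / cfg.pixel_size_nm))
    if n_px < 1:
        raise ValueError("field smaller than one pixel at this pixel size")
    shape = (n_px, n_px)
    if field.side_nm > n_px * cfg.pixel_size_nm + 1e-6:
        raise ValueError("field extent exceeds the rendered image")
    pos = field.bound_positions()
    images = []
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    for fwhm in (cfg.psf_fwhm_confocal_nm, cfg.psf_fwhm_sted_nm):
        expected = render_emitters(pos, shape, cfg.pixel_size_nm, fwhm, cfg.photon_scale)
        if noise:
            images.append(_apply_noise(expected, cfg, rng))
        else:
            images.append(expected + cfg.camera_offset)
    return images[0], images[1]


@dataclass
class QuenchGroundTruth:
    """Ground truth for a pH-quench experiment on GFP-tagged membrane protein.

    A fraction ``surface_fraction`` of each cell's fluorophores faces the
    extracellular buffer and is quenched (with efficiency ``quench_efficiency``)
    when the bath is switched from pH 7.4 to pH 4.3; the internal pool is
    protected.  The per-cell remaining fraction at pH 4.3 is therefore
    ``1 - surface_fraction * quench_efficiency``.
    """

    surface_fraction: float
    quench_efficiency: float = 1.0
    n_cells: int = 25
    cell_radius_px: int = 12
    cell_amplitude: float = 500.0
    amplitude_cv: float = 0.3
    cell_mask: np.ndarray | None = None  # optional label image; generated if None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.surface_fraction <= 1.0:
            raise ValueError("surface_fraction must be in [0, 1]")
        if not 0.0 <= self.quench_efficiency <= 1.0:
            raise ValueError("quench_efficiency must be in [0, 1]")

    @property
    def remaining_fraction(self) -> float:
        return 1.0 - self.surface_fraction * self.quench_efficiency


def _disk_cell_mask(n_cells: int, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Label image of non-overlapping disk 'cells' on a jittered grid."""
    per_row = int(np.ceil(np.sqrt(n_cells)))
    pitch = 2 * radius + 8
    size = per_row * pitch + 2 * radius
    mask = np.zeros((size, size), np.int32)
    yy, xx = np.mgrid[0:size, 0:size]
    label = 0
    for i in range(per_row):
        for j in range(per_row):
            if label >= n_cells:
                break
            label += 1
            cy = radius + 4 + i * pitch + rng.integers(-2, 3)
            cx = radius + 4 + j * pitch + rng.integers(-2, 3)
            mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = label
    return mask


def simulate_quench_pair(
    truth: QuenchGroundTruth,
    cfg: ImagingConfig,
    noise: bool = True,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the (pH 7.4, pH 4.3) image pair of one field of cells.

    Returns ``(image_ph74, image_ph43, cell_mask, per_cell_amplitudes)``.
    Cells are uniform disks; the pH 7.4 image carries the total per-cell
    signal, the pH 4.3 image the protected remainder.  Both share the noise
    model of ``cfg``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mask = truth.cell_mask
    if mask is None:
        mask = _disk_cell_mask(truth.n_cells, truth.cell_radius_px, rng)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if truth.amplitude_cv > 0:
        sigma = np.sqrt(np.log(1.0 + truth.amplitude_cv**2))
        amps = truth.cell_amplitude * rng.lognormal(-0.5 * sigma**2, sigma, len(labels))
    else:
        amps = np.full(len(labels), truth.cell_amplitude)
    img74 = np.zeros(mask.shape, float)
    for lab, a in zip(labels, amps):
        img74[mask == lab] = a
    img43 = img74 * truth.remaining_fraction
    if noise:
        img74 = _apply_noise(img74, cfg, rng)
        img43 = _apply_noise(img43, cfg, rng)
    else:
        img74 = img74 + cfg.camera_offset
        img43 = img43 + cfg.camera_offset
    return img74, img43, mask, amps


def simulate_slice_stack(
    internal_fraction: float,
    n_slices: int = 5,
    shape: tuple[int, int] = (72, 96),
    cell_radius_px: int = 24,
    total_signal_per_slice: float = 2.0e4,
    marker_amplitude: float = 300.0,
    bleedthrough_coeff: float = 0.06,
    cfg: ImagingConfig | None = None,
    noise: bool = True,
    seed: int | None = None,
):
    """Simulate the x-z slice stack of one cell for the cytosolic-fraction assay.

    Each slice holds an elliptical cell whose membrane is a ~4 px band around
    the contour (carrying the marker stain and the membrane-localized antibody
    pool) and whose interior carries the internal antibody pool; a fraction
    ``internal_fraction`` of the antibody signal is internal.  The marker
    bleeds into the antibody channel with ``bleedthrough_coeff``.  Returns a
    :class:`nanopack.localization.SliceStack` whose ``membrane_rois`` are the
    filled cell regions traced on the marker channel.
    """
    from skimage.morphology import dilation, disk, erosion

    from ..localization import SliceStack

    if not 0.0 <= internal_fraction <= 1.0:
        raise ValueError("internal_fraction must be in [0, 1]")
    if cfg is None:
        cfg = ImagingConfig(photon_scale=0.0, camera_offset=0.0, read_noise_sd=1.0)
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    markers, antibodies, rois = [], [], []
    for k in range(n_slices):
        # slice-dependent cell extent, as in an x-z scan through a cell
        r = cell_radius_px * (0.7 + 0.3 * np.sin(np.pi * (k + 1) / (n_slices + 1)))
        cy, cx = h // 2, w // 2
        cell = ((yy - cy) / r) ** 2 + ((xx - cx) / (1.4 * r)) ** 2 <= 1.0
        band = dilation(cell, disk(2)) & ~erosion(cell, disk(2))
        interior = erosion(cell, disk(8))
        marker = np.where(band, marker_amplitude, 0.0)
        antibody = np.zeros(shape, float)
        if interior.any():
            antibody[interior] = internal_fraction * total_signal_per_slice / interior.sum()
        antibody[band] += (1.0 - internal_fraction) * total_signal_per_slice / band.sum()
        antibody = antibody + bleedthrough_coeff * marker
        if noise:
            marker = _apply_noise(marker, cfg, rng)
            antibody = _apply_noise(antibody, cfg, rng)
        markers.append(marker)
        antibodies.append(antibody)
        rois.append(cell)
    return SliceStack(
        marker_slices=markers,
        antibody_slices=antibodies,
        membrane_rois=rois,
        bleedthrough_coeff=bleedthrough_coeff,
    )
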