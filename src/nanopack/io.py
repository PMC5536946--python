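"""Thin I/O layer: 16-bit TIFF with pixel-size metadata, label masks, polygon
ROIs, YAML parameter files and JSON ground-truth sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "write_tiff",
    "read_tiff",
    "read_mask",
    "polygons_to_mask",
    "write_ground_truth",
    "load_params_yaml",
]


def write_tiff(path, image: np.ndarray, pixel_size_nm: float | None = None) -> None:
    """Write an image (or stack) as 16-bit TIFF, carrying the pixel size as
    TIFF resolution metadata (pixels per centimetre)."""
    arr = np.asarray(image)
    arr = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    kwargs = {}
    if pixel_size_nm is not None:
        px_per_cm = 1e7 / pixel_size_nm
        kwargs = dict(resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER")
    tifffile.imwrite(str(path), arr, **kwargs)


def read_tiff(path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF; returns (float array, pixel_size_nm or None)."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(float)
        page = tif.pages[0]
        pixel_size_nm = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0:
                per_unit = num / den
                scale = {2: 2.54e7, 3: 1e7}.get(int(unit.value))  # inch / cm in nm
                if scale:
                    pixel_size_nm = scale / per_unit
    return arr, pixel_size_nm


def polygons_to_mask(polygons: list[list[tuple[float, float]]], shape) -> np.ndarray:
    """Rasterize (x, y) vertex polygons into a label image (1-based labels)."""
    mask = np.zeros(shape, np.int32)
    for i, poly in enumerate(polygons, start=1):
        xy = np.asarray(poly, float)
        rr, cc = _sk_polygon(xy[:, 1], xy[:, 0], shape=shape)
        mask[rr, cc] = i
    return mask


def read_mask(path, shape=None) -> np.ndarray:
    """Read per-cell regions from a label TIFF or a polygon JSON file.

    The JSON format is ``{"polygons": [[[x, y], ...], ...]}`` and requires
    ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr, _ = read_tiff(path)
        return arr.astype(np.int32)
    with open(path) as fh:
        data = json.load(fh)
    if shape is None:
        raise ValueError("shape required to rasterize polygon ROIs")
    return polygons_to_mask(data["polygons"], shape)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating, np.bool_)):
            return obj.item()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_ground_truth(path, record) -> None:
    """JSON sidecar for a simulation's ground-truth record (dataclass or dict)."""
    if dataclasses.is_dataclass(record):
        record = dataclasses.asdict(record)
    with open(path, "w") as fh:
        json.dump(record, fh, cls=_NumpyEncoder, indent=2)


def load_params_yaml(path, cls):
    """Instantiate a parameter dataclass from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return cls(**data)
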