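"""Epitope-accessibility quantification from paired microscopy and blot data.

The core scheme: per transfection, the thresholded epifluorescence signal per
cell (EF) is divided by the loading-control-normalized western-blot band (WB).
Because microscopy sees only antibody-reachable epitopes while the blot sees
total protein, EF/WB reports in-situ epitope accessibility; relating the
variant construct's ratio to the reference construct's ratio within each
transfection pair cancels every per-experiment nuisance scale, yielding the
"normalized EF/WB ratio".

Also here: the toxin co-expression comparison, with GFP autofluorescence
gating and cell-size-corrected tag intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spots import dog_filter, find_maxima

__all__ = [
    "EFMeasurement",
    "WBMeasurement",
    "EfwbPair",
    "EfwbSummary",
    "NucleusCountParams",
    "ef_from_images",
    "count_nuclei",
    "wb_from_table",
    "efwb_ratio_and_pairing",
    "bont_compare",
]


@dataclass
class EFMeasurement:
    transfection_id: str
    construct: str
    ef_value: float           # average integrated thresholded signal per cell
    n_cells: int              # total nuclei counted over the included images
    threshold_used: float
    n_images: int = 0


@dataclass
class WBMeasurement:
    transfection_id: str
    construct: str
    band_intensity: float
    loading_control: float

    @property
    def wb_value(self) -> float:
        if self.loading_control <= 0:
            raise ValueError("loading_control must be > 0")
        return self.band_intensity / self.loading_control


@dataclass
class EfwbPair:
    pair_id: int | str
    ratio_reference: float
    ratio_variant: float

    @property
    def normalized_ratio(self) -> float:
        return self.ratio_variant / self.ratio_reference


@dataclass
class EfwbSummary:
    pairs: list[EfwbPair]
    mean_normalized_ratio: float
    sem_normalized_ratio: float
    geometric_mean_ratio: float
    t_statistic: float | None
    p_value: float | None


@dataclass(frozen=True)
class NucleusCountParams:
    """Nucleus detector settings (shared maxima semantics, DAPI scale)."""

    dog_sigma_small_px: float = 1.5
    dog_sigma_large_px: float = 4.5
    prominence: float = 20.0
    aggregate_threshold: float | None = None  # raw-peak gate; None disables


def count_nuclei(
    dapi_image: np.ndarray, params: NucleusCountParams = NucleusCountParams()
) -> int:
    """Count DAPI nuclei as DOG maxima, rejecting bright aggregates.

    Maxima whose *raw* peak value exceeds ``aggregate_threshold`` are
    discarded as staining aggregates rather than nuclei.
    """
    img = np.asarray(dapi_image, float)
    dog = dog_filter(img, params.dog_sigma_small_px, params.dog_sigma_large_px)
    peaks = find_maxima(dog, params.prominence)
    if params.aggregate_threshold is not None:
        peaks = [(y, x) for y, x in peaks if img[y, x] <= params.aggregate_threshold]
    return len(peaks)


def ef_from_images(
    myc_images: list[np.ndarray],
    dapi_images: list[np.ndarray],
    mock_images: list[np.ndarray],
    transfection_id: str = "",
    construct: str = "",
    threshold_quantile: float = 0.999,
    nucleus_params: NucleusCountParams = NucleusCountParams(),
) -> EFMeasurement:
    """Average per-cell integrated tag signal of one transfection.

    The background threshold is a high quantile (default 99.9th percentile) of
    the pooled mock-transfected images from the same staining batch; it is
    subtracted from every tag image (negatives clamped), the remaining
    integral divided by the image's nucleus count, and the per-image values
    averaged.  Images with zero detected nuclei are skipped with a warning.
    """
    if len(myc_images) != len(dapi_images):
        raise ValueError("need one DAPI image per tag image")
    if not mock_images:
        raise ValueError("mock images required to set the background threshold")
    mock_pixels = np.concatenate([np.asarray(m, float).ravel() for m in mock_images])
    threshold = float(np.quantile(mock_pixels, threshold_quantile))
    per_image = []
    n_cells_total = 0
    for i, (myc, dapi) in enumerate(zip(myc_images, dapi_images)):
        n = count_nuclei(dapi, nucleus_params)
        if n == 0:
            warnings.warn(f"image {i}: zero nuclei detected; skipped")
            continue
        integral = float(np.clip(np.asarray(myc, float) - threshold, 0.0, None).sum())
        per_image.append(integral / n)
        n_cells_total += n
    if not per_image:
        raise ValueError("no image with detected nuclei")
    return EFMeasurement(
        transfection_id=transfection_id,
        construct=construct,
        ef_value=float(np.mean(per_image)),
        n_cells=n_cells_total,
        threshold_used=threshold,
        n_images=len(per_image),
    )


def wb_from_table(wb_table: pd.DataFrame) -> pd.DataFrame:
    """Attach wb_value = band_intensity / loading_control to a tidy blot table."""
    out = wb_table.copy()
    if (out["loading_control"] <= 0).any():
        raise ValueError("loading_control must be > 0")
    out["wb_value"] = out["band_intensity"] / out["loading_control"]
    return out


def efwb_ratio_and_pairing(
    ef_table: pd.DataFrame,
    wb_table: pd.DataFrame,
    reference: str = "reference",
    variant: str = "variant",
) -> EfwbSummary:
    """EF/WB ratios per transfection, paired into normalized ratios.

    Tables are tidy with columns (pair_id, construct, ef_value) and (pair_id,
    construct, band_intensity, loading_control).  Pairs missing either
    construct in either table are dropped with a warning.  The summary holds
    the arithmetic mean +- SEM of the normalized ratios (for display), their
    geometric mean (the consistent estimator of the accessibility ratio under
    multiplicative noise), and a two-sided paired t-test computed on the
    NON-normalized EF/WB ratios of the two constructs across pairs.
    """
    wb = wb_from_table(wb_table)
    ef = ef_table.set_index(["pair_id", "construct"])["ef_value"]
    wbv = wb.set_index(["pair_id", "construct"])["wb_value"]
    pairs = []
    ref_ratios, var_ratios = [], []
    for pid in sorted(ef.index.get_level_values("pair_id").unique()):
        try:
            r_ref = float(ef[pid, reference]) / float(wbv[pid, reference])
            r_var = float(ef[pid, variant]) / float(wbv[pid, variant])
        except KeyError:
            warnings.warn(f"pair {pid}: missing construct; dropped")
            continue
        pairs.append(EfwbPair(pid, r_ref, r_var))
        ref_ratios.append(r_ref)
        var_ratios.append(r_var)
    if not pairs:
        raise ValueError("no complete pairs")
    norm = np.array([p.normalized_ratio for p in pairs])
    mean = float(norm.mean())
    sem = float(norm.std(ddof=1) / np.sqrt(len(norm))) if len(norm) > 1 else 0.0
    gmean = float(np.exp(np.log(norm).mean()))
    if len(pairs) > 1:
        diffs = np.asarray(var_ratios) - np.asarray(ref_ratios)
        if np.allclose(diffs, 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_rel(var_ratios, ref_ratios)
            t_stat, p_val = float(t_stat), float(p_val)
    else:
        t_stat = p_val = None
    return EfwbSummary(pairs, mean, sem, gmean, t_stat, p_val)


def bont_compare(
    cell_table: pd.DataFrame,
    size_correction: str = "multiply",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toxin co-expression comparison with gating and size correction.

    ``cell_table`` columns: condition, cotransfected (bool), gfp_mean,
    myc_mean, cell_area.  The single-transfected cohort defines the GFP
    autofluorescence mean; co-transfected cells below it are excluded (they
    are taken not to express the toxin).  Per condition, the reported
    intensity relates the mean tag intensity to the average cell size:
    multiplied by (condition mean area / grand mean area) by default, so that
    conditions concentrating signal onto smaller footprints are not
    over-credited; ``size_correction='divide'`` gives the inverse reading,
    ``'none'`` disables it.

    Returns (per-condition summary, pairwise two-sided t-tests on the
    size-corrected per-cell intensities).
    """
    if size_correction not in ("multiply", "divide", "none"):
        raise ValueError("size_correction must be 'multiply', 'divide' or 'none'")
    df = cell_table.copy()
    single = df[~df["cotransfected"]]
    if single.empty:
        raise ValueError("single-transfected cohort required to define autofluorescence")
    autofluo = float(single["gfp_mean"].mean())
    included = (~df["cotransfected"]) | (df["gfp_mean"] >= autofluo)
    df["included"] = included
    kept = df[included]
    grand_mean_area = float(kept["cell_area"].mean())

    def corrected(sub: pd.DataFrame) -> np.ndarray:
        factor = float(sub["cell_area"].mean()) / grand_mean_area
        if size_correction == "multiply":
            return sub["myc_mean"].to_numpy() * factor
        if size_correction == "divide":
            return sub["myc_mean"].to_numpy() / factor
        return sub["myc_mean"].to_numpy()

    rows = []
    per_cond_values = {}
    for cond, sub in kept.groupby("condition"):
        vals = corrected(sub)
        per_cond_values[cond] = vals
        rows.append(
            dict(
                condition=cond,
                n_cells=len(sub),
                n_excluded=int((df["condition"] == cond).sum() - len(sub)),
                mean_intensity=float(vals.mean()),
                sem_intensity=float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                mean_area=float(sub["cell_area"].mean()),
                autofluorescence_gate=autofluo,
            )
        )
    for cond in df["condition"].unique():
        if cond not in per_cond_values:
            warnings.warn(f"condition {cond}: empty after gating; reported as missing")
    summary = pd.DataFrame(rows)
    conds = sorted(per_cond_values)
    test_rows = []
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            t, p = stats.ttest_ind(per_cond_values[a], per_cond_values[b])
            test_rows.append(dict(condition_a=a, condition_b=b,
                                  t_statistic=float(t), p_value=float(p)))
    return summary, pd.DataFrame(test_rows, columns=["condition_a", "condition_b",
                                                     "t_statistic", "p_value"])
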