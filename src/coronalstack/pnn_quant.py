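"""WFA+ perineuronal-net quantification in Iba1-defined perilesional ROIs.

The perilesional band (PL) is the tissue within a configurable distance
of the lesion boundary.  Intersecting it with the segmented Iba1 area
splits it into an inflamed (Iba1+) and a non-inflamed (Iba1-) PL.  WFA+
cells are counted in rectangular ROIs of each class and normalized to
mirrored contralateral ROIs on the same slice -- the intrinsic control
for the regional variability of WFA staining -- giving per-slice fold
changes whose Iba1+ vs Iba1- difference is assessed with a paired
t-test over slices (slices are the statistical N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import filters

from .masking import ContourProfile, SectionMask
from .stacks_io import Calibration

__all__ = [
    "RoiSpec",
    "PnnSliceRecord",
    "PnnQuant",
    "PnnSummary",
    "classify_pl_regions",
    "detect_wfa_cells",
    "pair_threshold",
    "fold_change_analysis",
    "DEFAULT_PL_BAND_MM",
]

DEFAULT_PL_BAND_MM = 0.5


@dataclass(frozen=True)
class RoiSpec:
    """Ipsi/contra ROI rectangle pair for one slice and region class.

    Rectangles are (r0, c0, r1, c1) pixel bounds, half-open on the
    upper edge; ``rect_contra`` is the mirror of ``rect_ipsi`` across
    the slice midline.
    """

    slice_id: str
    region_class: str  # "iba1_pos" | "iba1_neg"
    rect_ipsi: tuple[int, int, int, int]
    rect_contra: tuple[int, int, int, int]


@dataclass
class PnnSliceRecord:
    slice_id: str
    region_class: str
    n_cells_ipsi: int
    n_cells_contra: int
    mean_intensity_ipsi: float
    mean_intensity_contra: float

    @property
    def fold_change_count(self) -> float | None:
        if self.n_cells_contra <= 0:
            return None
        return self.n_cells_ipsi / self.n_cells_contra

    @property
    def fold_change_intensity(self) -> float | None:
        if not np.isfinite(self.mean_intensity_contra) or self.mean_intensity_contra <= 0:
            return None
        return self.mean_intensity_ipsi / self.mean_intensity_contra


@dataclass
class PnnQuant:
    records: list[PnnSliceRecord] = field(default_factory=list)


@dataclass
class PnnSummary:
    mean_fold: dict[str, float]
    sem_fold: dict[str, float]
    n_slices: dict[str, int]
    t_statistic: float
    p_value: float
    n_pairs: int
    warnings: list[str]


def classify_pl_regions(
    iba1_mask: np.ndarray,
    tissue_mask: SectionMask,
    contour: ContourProfile,
    calibration: Calibration,
    band_width_mm: float = DEFAULT_PL_BAND_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the perilesional band into Iba1+ and Iba1- regions.

    The lesion cavity is the filled contour minus the tissue
    foreground; the PL band is tissue within ``band_width_mm`` of the
    cavity.  Returns the boolean (Iba1+ PL, Iba1- PL) pair.  A slice
    without a lesion yields two empty regions with a warning.
    """
    tissue = np.asarray(tissue_mask.binary, dtype=bool)
    if contour.filled is None:
        raise ValueError("contour must carry its filled mask (outer_contour output)")
    cavity = contour.filled & ~tissue
    # ignore sub-speckle residue along the contour boundary
    cavity = ndimage.binary_opening(cavity, np.ones((3, 3), dtype=bool))
    if not cavity.any():
        warnings.warn(
            f"no lesion cavity on slice {tissue_mask.slice_id!r}; PL regions empty",
            stacklevel=2,
        )
        empty = np.zeros_like(tissue)
        return empty, empty.copy()
    band_px = band_width_mm * 1000.0 / calibration.microns_per_pixel
    dist = ndimage.distance_transform_edt(~cavity)
    band = tissue & (dist <= band_px) & ~cavity
    iba1 = np.asarray(iba1_mask, dtype=bool)
    return band & iba1, band & ~iba1


def pair_threshold(
    image: np.ndarray, rect_contra: tuple[int, int, int, int]
) -> float:
    """One shared WFA threshold per ROI pair, set on the contralateral ROI.

    Otsu's method on the contralateral rectangle separates the stained
    somata from the tissue background; applying the same cut to both
    rectangles keeps the ipsi/contra comparison intensity-calibrated
    (and invariant to a global intensity rescale).
    """
    r0, c0, r1, c1 = rect_contra
    crop = np.asarray(image[r0:r1, c0:c1], dtype=np.float64)
    if crop.size == 0:
        raise ValueError("empty contralateral ROI")
    return float(filters.threshold_otsu(crop))


def _declump(binary: np.ndarray, min_size_px: int) -> np.ndarray:
    """Watershed separation of touching somata on the binary mask.

    Distance-transform maxima seed a watershed, splitting clumps whose
    constituent cells are resolvable -- the binary-watershed step that
    routinely precedes particle counting.  Returns a label image.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndimage.distance_transform_edt(binary)
    min_dist = max(2, int(round(0.8 * math.sqrt(min_size_px / math.pi))))
    coords = peak_local_max(dist, min_distance=min_dist, labels=binary)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-dist, markers, mask=binary)


def detect_wfa_cells(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    threshold: float,
    min_size_px: int = 200,
    declump: bool = True,
) -> tuple[list[np.ndarray], int, list[float]]:
    """Detect WFA+ cells inside one rectangle of the raw image.

    Thresholds the ROI crop, separates touching somata with a binary
    watershed (``declump``), labels 8-connected components, drops those
    below ``min_size_px``, and measures each retained cell's mean
    intensity on the raw (unblurred) pixels.  Returns (per-cell boolean
    masks in ROI coordinates, count, per-cell mean raw intensities).
    """
    r0, c0, r1, c1 = roi
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(f"roi {roi} outside image of shape {image.shape}")
    crop = np.asarray(image[r0:r1, c0:c1], dtype=np.float64)
    if crop.size == 0:
        return [], 0, []
    binary = crop >= threshold
    if not binary.any():
        return [], 0, []
    if declump:
        labels = _declump(binary, min_size_px)
        n = int(labels.max())
    else:
        labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return [], 0, []
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = [i for i in range(1, n + 1) if sizes[i] >= min_size_px]
    masks = [labels == i for i in keep]
    intensities = [float(crop[m].mean()) for m in masks]
    return masks, len(masks), intensities


def quantify_slice(
    wfa_image: np.ndarray,
    rois: list[RoiSpec],
    min_size_px: int = 200,
    threshold: float | None = None,
) -> list[PnnSliceRecord]:
    """Count and measure WFA+ cells for every ROI pair of one slice."""
    records = []
    for spec in rois:
        thr = pair_threshold(wfa_image, spec.rect_contra) if threshold is None else threshold
        _, n_ipsi, int_ipsi = detect_wfa_cells(wfa_image, spec.rect_ipsi, thr, min_size_px)
        _, n_contra, int_contra = detect_wfa_cells(wfa_image, spec.rect_contra, thr, min_size_px)
        records.append(
            PnnSliceRecord(
                slice_id=spec.slice_id,
                region_class=spec.region_class,
                n_cells_ipsi=n_ipsi,
                n_cells_contra=n_contra,
                mean_intensity_ipsi=float(np.mean(int_ipsi)) if int_ipsi else float("nan"),
                mean_intensity_contra=float(np.mean(int_contra)) if int_contra else float("nan"),
            )
        )
    return records


def fold_change_analysis(quant: PnnQuant) -> PnnSummary:
    """Per-class mean +/- sem fold change and the paired slice-wise test.

    Slices missing a defined fold change in either class are excluded
    from the paired t-test with a warning.  A degenerate (zero-variance)
    set of paired differences is flagged rather than assigned a
    statistic.
    """
    notes: list[str] = []
    by_class: dict[str, dict[str, float]] = {}
    for rec in quant.records:
        fc = rec.fold_change_count
        if fc is None:
            notes.append(
                f"slice {rec.slice_id!r} class {rec.region_class!r}: zero contralateral "
                "count, fold change undefined"
            )
            continue
        by_class.setdefault(rec.region_class, {})[rec.slice_id] = fc
    mean_fold, sem_fold, n_slices = {}, {}, {}
    for cls, folds in by_class.items():
        vals = np.array(list(folds.values()))
        mean_fold[cls] = float(vals.mean())
        sem_fold[cls] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        n_slices[cls] = len(vals)
    classes = sorted(by_class)
    if len(classes) != 2:
        raise ValueError(
            f"paired comparison needs exactly 2 region classes, got {classes}"
        )
    # paired difference is (last class - first class) in sorted label
    # order, i.e. iba1_pos - iba1_neg for the standard labels
    a, b = by_class[classes[1]], by_class[classes[0]]
    shared = sorted(set(a) & set(b))
    skipped = sorted((set(a) | set(b)) - set(shared))
    if skipped:
        notes.append(f"slices excluded from the paired test: {skipped}")
    if len(shared) < 2:
        raise ValueError("paired test needs >= 2 slices with both classes defined")
    x = np.array([a[s] for s in shared])
    y = np.array([b[s] for s in shared])
    diffs = x - y
    if np.allclose(diffs.std(ddof=1), 0.0):
        notes.append("paired differences have zero variance; t statistic undefined")
        t_stat, p_val = float("nan"), float("nan") if diffs.mean() != 0 else 1.0
    else:
        t_stat, p_val = stats.ttest_rel(x, y)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return PnnSummary(
        mean_fold=mean_fold,
        sem_fold=sem_fold,
        n_slices=n_slices,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_pairs=len(shared),
        warnings=notes,
    )
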