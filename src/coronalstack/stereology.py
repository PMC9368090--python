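"""Per-slice marker areas and Cavalieri-style volume integration.

Each sorted, aligned slice contributes one point (bregma position,
marker area) to an area profile A(x).  The marker volume is the
integral V = int_a^b A(x) dx of a least-squares polynomial fitted to
the profile; where the fitted polynomial dips below zero it contributes
nothing, since a cross-sectional area cannot be negative.

Three per-slice measurements feed the profiles:

* ``segment_marker_area`` -- blur / threshold / particle-size filter
  segmentation of a diffuse marker (Iba1, IgG),
* ``injury_area`` -- the lesion cavity, taken as the filled outer
  contour minus the actual tissue foreground,
* ``assign_bregma`` -- AP positions from the sorted ranks and the
  series calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import ndimage
from skimage import filters, measure

from .masking import ContourProfile, SectionMask
from .sorting import SortResult
from .stacks_io import Calibration

__all__ = [
    "AreaProfile",
    "VolumeEstimate",
    "segment_marker_area",
    "injury_area",
    "assign_bregma",
    "fit_and_integrate",
    "contralateral_threshold",
]


@dataclass
class AreaProfile:
    """(bregma mm, area mm^2) samples for one marker, anterior first."""

    marker: str
    points: list[tuple[float, float]]
    slice_ids: list[str]

    def __post_init__(self) -> None:
        x = np.array([p[0] for p in self.points])
        if len(x) > 1 and not np.all(np.diff(x) < 0):
            raise ValueError("bregma positions must be strictly decreasing (anterior first)")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("areas must be non-negative")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class VolumeEstimate:
    """Fitted polynomial profile and its clipped integral."""

    marker: str
    poly_coeffs: np.ndarray  # ascending degree, standard basis
    degree: int
    a_mm: float
    b_mm: float
    volume_mm3: float
    fit_r2: float
    warnings: list[str]


def contralateral_threshold(
    image: np.ndarray, lesion_side: str = "right", quantile: float = 0.999
) -> float:
    """Marker threshold anchored to the contralateral (healthy) hemisphere.

    The contralateral half-image gives the reference level healthy tissue
    essentially never exceeds (its ``quantile``); the threshold is set
    halfway between that level and the brightest ipsilateral signal, so
    only staining clearly above the healthy ceiling is marker-positive.
    On a slice without pathological signal the two levels coincide and
    nothing is segmented.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    img = np.asarray(image, dtype=np.float64)
    cols = img.shape[1]
    # exclude a central band so midline-adjacent signal (or its blur) does
    # not contaminate the healthy reference
    band = cols // 20
    if lesion_side == "left":
        contra, ipsi = img[:, cols // 2 + band :], img[:, : cols // 2 - band]
    else:
        contra, ipsi = img[:, : cols // 2 - band], img[:, cols // 2 + band :]
    ceiling = float(np.quantile(contra, quantile))
    signal = float(np.quantile(ipsi, quantile))
    return 0.5 * (ceiling + max(signal, ceiling))


def segment_marker_area(
    image: np.ndarray,
    calibration: Calibration,
    sigma: float = 5.0,
    threshold: float | str = "auto",
    min_size_px: int = 1000,
    lesion_side: str = "right",
) -> tuple[float, list[np.ndarray]]:
    """Segment a diffuse marker (Iba1, IgG) on one slice.

    Gaussian blur (sigma = 5 px) homogenizes the staining, a single
    intensity threshold binarizes it, and connected components
    (8-connectivity) smaller than ``min_size_px`` are discarded as
    speckle.  Returns the retained area in mm^2 and the component
    boundary polygons.  ``threshold="auto"`` anchors the cut to the
    contralateral hemisphere via :func:`contralateral_threshold`.
    """
    image = np.asarray(image, dtype=np.float64)
    blurred = filters.gaussian(image, sigma=sigma, preserve_range=True)
    thr = (
        contralateral_threshold(blurred, lesion_side=lesion_side)
        if threshold == "auto"
        else float(threshold)
    )
    binary = blurred >= thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0.0, []
    sizes = np.bincount(labels.ravel())
    keep_ids = np.flatnonzero(sizes >= min_size_px)
    keep_ids = keep_ids[keep_ids != 0]
    kept = np.isin(labels, keep_ids)
    area_mm2 = float(np.count_nonzero(kept) * calibration.mm2_per_px)
    polygons = [
        max(measure.find_contours((labels == i).astype(float), 0.5), key=len)
        for i in keep_ids
    ]
    return area_mm2, polygons


def injury_area(
    dapi_mask: SectionMask, contour: ContourProfile, calibration: Calibration
) -> float:
    """Lesion cavity area on one slice, mm^2.

    The filled outer contour bridges the hole; subtracting the actual
    tissue foreground leaves exactly the cavity.  Intact slices give ~0
    (clamped at 0 against the slight boundary rounding the closing adds).
    """
    if contour.slice_id != dapi_mask.slice_id:
        raise ValueError(
            f"contour {contour.slice_id!r} does not match mask {dapi_mask.slice_id!r}"
        )
    if contour.filled is not None:
        cavity = contour.filled & ~np.asarray(dapi_mask.binary, dtype=bool)
        # a 1-px ring of closing residue along the outer boundary is not a
        # cavity; a single opening removes it without touching real holes
        cavity = ndimage.binary_opening(cavity, np.ones((3, 3), dtype=bool))
        hole_px = int(np.count_nonzero(cavity))
    else:
        hole_px = max(contour.contour_area_px - dapi_mask.area_px, 0)
    return hole_px * calibration.mm2_per_px


def assign_bregma(result: SortResult, calibration: Calibration) -> dict[str, float]:
    """AP position per slice id from sorted rank and series spacing."""
    return {
        sid: float(calibration.bregma_of_rank(rank))
        for rank, sid in enumerate(result.order)
    }


def _clipped_poly_integral(poly: Polynomial, a: float, b: float) -> float:
    """Integral of max(poly, 0) over [a, b] via sign-change subdivision."""
    if a > b:
        a, b = b, a
    roots = poly.roots()
    cuts = sorted(
        {a, b}
        | {float(r.real) for r in roots if abs(r.imag) < 1e-9 and a < r.real < b}
    )
    antideriv = poly.integ()
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if poly((lo + hi) / 2.0) > 0:
            total += float(antideriv(hi) - antideriv(lo))
    return max(total, 0.0)


def fit_and_integrate(
    profile: AreaProfile,
    degree: int = 3,
    bounds: tuple[float, float] | str = "auto",
) -> VolumeEstimate:
    """Fit A(x) with a polynomial and integrate it into a volume.

    ``bounds="auto"`` integrates over the marker's support: from the
    first to the last slice with positive area, padded by half the
    median slice spacing on each side.  Only the profile points inside
    the bounds inform the fit -- distant all-zero slices carry no shape
    information a low-order polynomial could honor.  If fewer than
    ``degree + 1`` points remain the degree is reduced with a warning.
    An all-zero profile yields volume 0.
    """
    notes: list[str] = []
    x = profile.x
    areas = profile.areas
    if not (1 <= degree <= 6):
        raise ValueError("degree must be between 1 and 6")

    nz = np.flatnonzero(areas > 0)
    spacing = float(np.median(np.abs(np.diff(x)))) if len(x) > 1 else 0.0
    if bounds == "auto":
        if len(nz) == 0:
            return VolumeEstimate(
                marker=profile.marker,
                poly_coeffs=np.zeros(1),
                degree=0,
                a_mm=float(x.min(initial=0.0)),
                b_mm=float(x.max(initial=0.0)),
                volume_mm3=0.0,
                fit_r2=1.0,
                warnings=["all-zero profile; volume 0"],
            )
        lo = float(x[nz].min()) - spacing / 2.0
        hi = float(x[nz].max()) + spacing / 2.0
    else:
        lo, hi = float(min(bounds)), float(max(bounds))
    sel = (x >= lo) & (x <= hi)
    xs, ys = x[sel], areas[sel]
    if len(xs) == 0:
        raise ValueError("no profile points inside the integration bounds")
    deg = degree
    if len(xs) < deg + 1:
        deg = max(len(xs) - 1, 0)
        notes.append(
            f"only {len(xs)} points inside bounds; degree reduced from {degree} to {deg}"
        )
        warnings.warn(notes[-1], stacklevel=2)
    poly = Polynomial.fit(xs, ys, deg)
    fitted = poly(xs)
    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    std_poly = poly.convert()
    volume = _clipped_poly_integral(std_poly, lo, hi)
    return VolumeEstimate(
        marker=profile.marker,
        poly_coeffs=std_poly.coef,
        degree=deg,
        a_mm=lo,
        b_mm=hi,
        volume_mm3=volume,
        fit_r2=r2,
        warnings=notes,
    )
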