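"""Synthetic serial-section image stacks with analytic ground truth.

The generator emulates the raw material of a focal cortical-injury
histology experiment: shuffled serial coronal sections imaged in four
fluorescence channels (DAPI, Iba1, IgG, WFA), with

* elliptical section silhouettes (fixed width:height aspect 1.6) whose
  area grows logarithmically along the AP axis,
* a drill-type lesion: a circular hole of 2.1 mm diameter carved through
  a contiguous AP extent of sections, lateralized to one hemisphere,
* an Iba1+ microglial halo drawn as a ventral half-annulus around the
  hole, and an IgG extravasation cloud overlapping but not identical to
  the halo,
* punctate WFA+ cells (perineuronal nets) placed as a Poisson point
  process at a baseline density everywhere in tissue, reduced to a
  configurable retention fraction inside the Iba1+ region,
* a per-slice rigid placement jitter (small rotation + translation),
  recorded through a ground-truth midline reference segment.

Every geometric primitive is analytic, so per-slice areas and the
volumes of the lesion, halo and cloud solids are exact closed forms
against which the measurement pipeline can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stacks_io import Calibration, ChannelStack, save_stack

__all__ = [
    "SynthParams",
    "GroundTruth",
    "RoiRect",
    "generate_brain",
    "analytic_lesion_profile",
    "analytic_iba1_profile",
    "analytic_igg_profile",
    "simulate_roi_patches",
    "write_brain",
    "CHANNELS",
]

CHANNELS = ("DAPI", "Iba1", "IgG", "WFA")

# Ellipse silhouette: width:height aspect (semi-axis a = ASPECT * b).
ASPECT = 1.6

# Lateral offset of the drill hole centre from the midline, mm.  2.1 mm
# diameter at 1.5 mm lateral keeps the hole clear of the midline by
# 0.45 mm, mimicking a motor-cortex lesion.
HOLE_CX_MM = 1.5

# IgG cloud: a disc slightly larger than and laterally shifted from the
# hole, minus the hole itself -- overlapping but not identical to the halo.
IGG_SHIFT_MM = 0.1
IGG_EXTRA_MM = 0.3

# Ground-truth midline reference segment: fixed dorsoventral half-length
# so that line-based registration is rigid (scale 1) across slices.
MIDLINE_HALF_MM = 1.2

# Intensity model (8-bit): background + flat tissue baseline + marker
# signal + Gaussian read noise.  No optics PSF is simulated.
_BG, _NOISE_SD = 25.0, 5.0
_LEVELS = {"DAPI": (170.0, 0.0), "Iba1": (55.0, 200.0), "IgG": (50.0, 170.0), "WFA": (40.0, 0.0)}
_WFA_PEAK = 185.0


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle in canonical section coordinates (mm)."""

    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area_mm2(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def mirrored(self) -> "RoiRect":
        """Reflection across the midline (x = 0)."""
        return RoiRect(-self.x1, -self.x0, self.y0, self.y1)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


# Quantification rectangles, canonical frame: the Iba1+ ROI sits inside
# the ventral half-annulus halo; the Iba1- ROI is its dorsal mirror,
# perilesional but outside the halo.  y > 0 is ventral.
ROI_IBA1_POS = RoiRect(HOLE_CX_MM - 0.35, HOLE_CX_MM + 0.35, 1.10, 1.50)
ROI_IBA1_NEG = RoiRect(HOLE_CX_MM - 0.35, HOLE_CX_MM + 0.35, -1.50, -1.10)


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; defaults define the study conditions.

    Lengths in mm, densities in cells/mm^2, image calibration in um/px.
    ``area_start_mm2 < area_end_mm2``: section areas grow from the
    anterior end toward posterior.  ``wfa_retention_iba1pos`` is the
    fraction of the baseline WFA+ density retained inside the Iba1+
    halo (1.0 = no effect).
    """

    n_slices: int = 11
    image_shape: tuple[int, int] | None = None  # (rows, cols); None = auto-size
    microns_per_pixel: float = 4.0
    slice_thickness_um: float = 40.0
    series_count: int = 8
    anchor_bregma_mm: float = 2.5
    area_start_mm2: float = 14.0
    area_end_mm2: float = 26.0
    area_noise_sd_mm2: float = 0.1
    lesion_center_bregma_mm: float = 0.94
    lesion_diameter_mm: float = 2.1
    lesion_depth_mm: float = 1.6
    iba1_halo_width_mm: float = 0.5
    wfa_density_per_mm2: float = 120.0
    wfa_retention_iba1pos: float = 0.2
    wfa_cell_radius_um: float = 18.0
    rotation_jitter_deg: float = 2.0
    translation_jitter_um: float = 100.0
    intensity_noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.area_start_mm2 < self.area_end_mm2:
            raise ValueError("area_start_mm2 must be < area_end_mm2 (areas grow AP)")
        if not 0.0 <= self.wfa_retention_iba1pos <= 1.0:
            raise ValueError("wfa_retention_iba1pos must lie in [0, 1]")
        for name in (
            "microns_per_pixel",
            "slice_thickness_um",
            "area_start_mm2",
            "wfa_cell_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "lesion_diameter_mm",
            "lesion_depth_mm",
            "iba1_halo_width_mm",
            "area_noise_sd_mm2",
            "wfa_density_per_mm2",
            "rotation_jitter_deg",
            "translation_jitter_um",
            "intensity_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_slices < 1 or self.series_count < 1:
            raise ValueError("n_slices and series_count must be >= 1")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            microns_per_pixel=self.microns_per_pixel,
            slice_thickness_um=self.slice_thickness_um,
            series_count=self.series_count,
            anchor_bregma_mm=self.anchor_bregma_mm,
        )

    @property
    def lesion_radius_mm(self) -> float:
        return self.lesion_diameter_mm / 2.0

    @property
    def lesion_extent_mm(self) -> tuple[float, float]:
        """Closed AP interval [posterior, anterior] carrying the lesion."""
        h = self.lesion_depth_mm / 2.0
        return (self.lesion_center_bregma_mm - h, self.lesion_center_bregma_mm + h)

    def in_lesion_extent(self, bregma_mm: float) -> bool:
        lo, hi = self.lesion_extent_mm
        return lo <= bregma_mm <= hi

    def section_area_curve(self, t: np.ndarray | float) -> np.ndarray | float:
        """Noiseless section area at normalized AP position t in [0, 1].

        Logarithmic interpolation between the anterior and posterior end
        areas: strictly increasing, concave, with the steep growth at the
        anterior end characteristic of the frontal-to-parietal transition.
        """
        span = self.area_end_mm2 - self.area_start_mm2
        return self.area_start_mm2 + span * np.log1p((math.e - 1.0) * np.asarray(t))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_order: list[str]  # slice ids in true AP order (anterior first)
    true_bregma_mm: dict[str, float]
    true_section_area_mm2: dict[str, float]
    true_lesion_area_mm2: dict[str, float]
    true_iba1_area_mm2: dict[str, float]
    true_igg_area_mm2: dict[str, float]
    true_lesion_volume_mm3: float
    true_iba1_volume_mm3: float
    true_igg_volume_mm3: float
    # per slice id: counts of generated WFA+ cell centres in each ROI
    true_wfa_counts: dict[str, dict[str, int]]
    # per slice id: midline endpoints ((x0,y0),(x1,y1)) px, p0 = dorsal
    true_reference_lines: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    rois: dict[str, RoiRect] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# analytic area profiles (closed-form oracles for the volume stage)
# ---------------------------------------------------------------------------

def analytic_lesion_profile(params: SynthParams, bregma_mm: float) -> float:
    """Exact lesion cross-sectional area (mm^2) at an AP position.

    The lesion solid is a cylinder of the drill diameter running through
    the stack: every section within the lesion's AP extent carries a
    circular hole of area pi*r^2; sections outside carry none.
    """
    if params.in_lesion_extent(bregma_mm):
        return math.pi * params.lesion_radius_mm**2
    return 0.0


def _halo_area_mm2(params: SynthParams) -> float:
    r, w = params.lesion_radius_mm, params.iba1_halo_width_mm
    return 0.5 * math.pi * ((r + w) ** 2 - r**2)


def _igg_area_mm2(params: SynthParams) -> float:
    r = params.lesion_radius_mm
    r2 = r + IGG_EXTRA_MM
    return math.pi * (r2**2 - r**2)


def analytic_iba1_profile(params: SynthParams, bregma_mm: float) -> float:
    """Exact Iba1+ halo cross-sectional area (mm^2) at an AP position."""
    return _halo_area_mm2(params) if params.in_lesion_extent(bregma_mm) else 0.0


def analytic_igg_profile(params: SynthParams, bregma_mm: float) -> float:
    """Exact IgG+ cloud cross-sectional area (mm^2) at an AP position."""
    return _igg_area_mm2(params) if params.in_lesion_extent(bregma_mm) else 0.0


# ---------------------------------------------------------------------------
# geometry helpers (canonical frame: x lateral, + = ipsilateral;
#                   y dorsoventral, + = ventral; origin = section centre)
# ---------------------------------------------------------------------------

def _semi_axes(area_mm2: float) -> tuple[float, float]:
    b = math.sqrt(area_mm2 / (ASPECT * math.pi))
    return ASPECT * b, b


def _check_marker_geometry(
    params: SynthParams, area_mm2: float, bregma: float, channels: tuple[str, ...]
) -> None:
    """The generated structures must lie strictly inside the section
    ellipse on every lesioned slice, otherwise the recorded analytic
    areas would be wrong.  Only structures of the requested channels are
    constrained (a DAPI-only stack needs just the hole to fit)."""
    a, b = _semi_axes(area_mm2)

    def inside(x: float, y: float) -> bool:
        return (x / a) ** 2 + (y / b) ** 2 < 1.0

    def ring_probes(radius: float, cx: float = HOLE_CX_MM) -> list[tuple[float, float]]:
        return [(cx + radius, 0.0), (cx - radius, 0.0), (cx, radius), (cx, -radius)]

    probes = ring_probes(params.lesion_radius_mm)
    if "Iba1" in channels:
        probes += ring_probes(params.lesion_radius_mm + params.iba1_halo_width_mm)
    if "IgG" in channels:
        probes += ring_probes(params.lesion_radius_mm + IGG_EXTRA_MM, HOLE_CX_MM + IGG_SHIFT_MM)
    if "WFA" in channels:
        for rect in (ROI_IBA1_POS, ROI_IBA1_NEG, ROI_IBA1_POS.mirrored(), ROI_IBA1_NEG.mirrored()):
            probes += [(rect.x0, rect.y0), (rect.x1, rect.y0), (rect.x0, rect.y1), (rect.x1, rect.y1)]
    for x, y in probes:
        if not inside(x, y):
            raise ValueError(
                f"section area {area_mm2:.2f} mm^2 at bregma {bregma:+.2f} is too "
                f"small to contain the lesion geometry (probe ({x:.2f},{y:.2f}) mm "
                f"outside the ellipse); increase section areas or shrink the lesion"
            )


def _auto_shape(params: SynthParams) -> tuple[int, int]:
    max_area = params.area_end_mm2 + 4.0 * params.area_noise_sd_mm2
    a, b = _semi_axes(max_area)
    rot = math.radians(4.0 * params.rotation_jitter_deg)
    margin = 4.0 * params.translation_jitter_um / 1000.0 + a * math.sin(rot) + 0.2
    mpp_mm = params.microns_per_pixel / 1000.0
    rows = int(math.ceil(2.0 * (b + margin) / mpp_mm))
    cols = int(math.ceil(2.0 * (a + margin) / mpp_mm))
    return rows, cols


def _check_shape(params: SynthParams, shape: tuple[int, int]) -> None:
    rows, cols = shape
    need_rows, need_cols = _auto_shape(params)
    if rows < need_rows:
        raise ValueError(
            f"image too small for the section ellipse: rows={rows} < {need_rows} "
            f"required at {params.microns_per_pixel} um/px"
        )
    if cols < need_cols:
        raise ValueError(
            f"image too small for the section ellipse: cols={cols} < {need_cols} "
            f"required at {params.microns_per_pixel} um/px"
        )


class _Frame:
    """Rigid map between canonical section coordinates (mm) and pixels."""

    def __init__(self, shape: tuple[int, int], mpp_um: float, theta: float, shift_px: tuple[float, float]):
        self.shape = shape
        self.mpp_mm = mpp_um / 1000.0
        self.theta = theta
        self.cy = (shape[0] - 1) / 2.0 + shift_px[0]
        self.cx = (shape[1] - 1) / 2.0 + shift_px[1]

    def canonical_grids(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        x = (xx - self.cx) * self.mpp_mm
        y = (yy - self.cy) * self.mpp_mm
        ct, st = math.cos(self.theta), math.sin(self.theta)
        # undo the rotation: canonical = R(-theta) @ image-offset
        return ct * x + st * y, -st * x + ct * y

    def to_px(self, x_mm: np.ndarray, y_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        xi = ct * x_mm - st * y_mm
        yi = st * x_mm + ct * y_mm
        return self.cy + yi / self.mpp_mm, self.cx + xi / self.mpp_mm


def _sample_points_in(
    rng: np.random.Generator,
    n: int,
    member: "callable",
    bbox: tuple[float, float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points in an analytic region via rejection sampling."""
    x0, x1, y0, y1 = bbox
    xs, ys = [], []
    remaining = n
    while remaining > 0:
        m = max(16, int(remaining * 2.5))
        cx = rng.uniform(x0, x1, m)
        cy = rng.uniform(y0, y1, m)
        keep = member(cx, cy)
        cx, cy = cx[keep][:remaining], cy[keep][:remaining]
        xs.append(cx)
        ys.append(cy)
        remaining -= len(cx)
    return np.concatenate(xs), np.concatenate(ys)


def _stamp_cells(image: np.ndarray, rr: np.ndarray, cc: np.ndarray, radius_px: float, peak: float) -> None:
    """Add soma-scale WFA+ cell spots in place.

    Each cell is a flat-core disc of the nominal radius with a Gaussian
    edge roll-off, so the half-intensity (and hence any mid-range
    threshold) isophote encloses approximately pi*r^2 pixels.
    """
    rad = int(math.ceil(radius_px)) + 2
    sigma = max(0.15 * radius_px, 0.6)
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    d = np.sqrt(dy**2 + dx**2)
    from scipy.special import erf  # smooth step: disc convolved with a Gaussian edge

    spot = peak * 0.5 * (1.0 + erf((radius_px - d) / (math.sqrt(2.0) * sigma)))
    rows, cols = image.shape
    for r, c in zip(np.rint(rr).astype(int), np.rint(cc).astype(int)):
        r0, r1 = max(r - rad, 0), min(r + rad + 1, rows)
        c0, c1 = max(c - rad, 0), min(c + rad + 1, cols)
        if r0 >= r1 or c0 >= c1:
            continue
        image[r0:r1, c0:c1] += spot[r0 - (r - rad) : r1 - (r - rad), c0 - (c - rad) : c1 - (c - rad)]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_brain(
    params: SynthParams,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[dict[str, ChannelStack], GroundTruth]:
    """Generate shuffled, mutually registered channel stacks plus truth.

    Returns one :class:`ChannelStack` per requested channel (all channels
    of a slice share the same placement jitter, emulating co-registered
    series of the same brain) and the :class:`GroundTruth` manifest.
    Slices are returned in a shuffled storage order; ``true_order`` lists
    slice ids in the true anteroposterior order.
    """
    unknown = [c for c in channels if c not in CHANNELS]
    if unknown:
        raise ValueError(f"unknown channels {unknown}; available: {CHANNELS}")
    shape = params.image_shape or _auto_shape(params)
    _check_shape(params, shape)

    n = params.n_slices
    cal = params.calibration
    layout_rng = np.random.default_rng(
        np.random.SeedSequence([int(params.rng_seed) & 0x7FFFFFFF, 0])
    )

    t = np.zeros(n) if n == 1 else np.arange(n) / (n - 1)
    areas = np.asarray(params.section_area_curve(t), dtype=float)
    if params.area_noise_sd_mm2 > 0:
        areas = areas + layout_rng.normal(0.0, params.area_noise_sd_mm2, n)
    areas = np.maximum(areas, 1.0)
    bregma = params.anchor_bregma_mm - np.arange(n) * cal.inter_slice_spacing_mm

    lesioned = np.array([params.in_lesion_extent(b) for b in bregma]) & (
        params.lesion_diameter_mm > 0
    )
    for i in range(n):
        if lesioned[i]:
            _check_marker_geometry(params, areas[i], bregma[i], channels)

    thetas = np.radians(layout_rng.normal(0.0, params.rotation_jitter_deg, n))
    shifts = layout_rng.normal(0.0, params.translation_jitter_um / params.microns_per_pixel, (n, 2))
    shuffle = layout_rng.permutation(n)  # shuffle[k] = AP rank stored at position k

    slice_ids = [f"s{k:03d}" for k in range(n)]
    id_of_rank = {int(shuffle[k]): slice_ids[k] for k in range(n)}

    r_hole = params.lesion_radius_mm
    r_halo = r_hole + params.iba1_halo_width_mm
    r_igg = r_hole + IGG_EXTRA_MM
    cell_r_px = params.wfa_cell_radius_um / params.microns_per_pixel

    rois = {
        "iba1_pos_ipsi": ROI_IBA1_POS,
        "iba1_pos_contra": ROI_IBA1_POS.mirrored(),
        "iba1_neg_ipsi": ROI_IBA1_NEG,
        "iba1_neg_contra": ROI_IBA1_NEG.mirrored(),
    }

    stacks: dict[str, list[np.ndarray]] = {c: [] for c in channels}
    gt = GroundTruth(
        true_order=[id_of_rank[r] for r in range(n)],
        true_bregma_mm={},
        true_section_area_mm2={},
        true_lesion_area_mm2={},
        true_iba1_area_mm2={},
        true_igg_area_mm2={},
        true_lesion_volume_mm3=analytic_lesion_profile(params, params.lesion_center_bregma_mm)
        * params.lesion_depth_mm,
        true_iba1_volume_mm3=_halo_area_mm2(params) * params.lesion_depth_mm
        if params.lesion_diameter_mm > 0
        else 0.0,
        true_igg_volume_mm3=_igg_area_mm2(params) * params.lesion_depth_mm
        if params.lesion_diameter_mm > 0
        else 0.0,
        true_wfa_counts={},
        true_reference_lines={},
        rois=dict(rois),
    )

    for k in range(n):
        rank = int(shuffle[k])
        sid = slice_ids[k]
        area = float(areas[rank])
        a, b = _semi_axes(area)
        les = bool(lesioned[rank])
        frame = _Frame(shape, params.microns_per_pixel, float(thetas[rank]), tuple(shifts[rank]))
        X, Y = frame.canonical_grids()

        tissue = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        d2 = (X - HOLE_CX_MM) ** 2 + Y**2
        hole = (d2 <= r_hole**2) & les
        halo = les & (d2 > r_hole**2) & (d2 <= r_halo**2) & (Y > 0) & tissue
        d2g = (X - HOLE_CX_MM - IGG_SHIFT_MM) ** 2 + Y**2
        cloud = les & (d2g <= r_igg**2) & ~(d2 <= r_hole**2) & tissue

        gt.true_bregma_mm[sid] = float(bregma[rank])
        gt.true_section_area_mm2[sid] = area
        gt.true_lesion_area_mm2[sid] = math.pi * r_hole**2 if les else 0.0
        gt.true_iba1_area_mm2[sid] = _halo_area_mm2(params) if les else 0.0
        gt.true_igg_area_mm2[sid] = _igg_area_mm2(params) if les else 0.0

        p0 = frame.to_px(np.array([0.0]), np.array([-MIDLINE_HALF_MM]))
        p1 = frame.to_px(np.array([0.0]), np.array([MIDLINE_HALF_MM]))
        gt.true_reference_lines[sid] = (
            (float(p0[1][0]), float(p0[0][0])),  # (x, y) px, dorsal end
            (float(p1[1][0]), float(p1[0][0])),
        )

        # WFA+ cell centres, Poisson in each density stratum
        cell_rng = np.random.default_rng(
            np.random.SeedSequence([int(params.rng_seed) & 0x7FFFFFFF, 1, rank])
        )
        tissue_area = area - (math.pi * r_hole**2 if les else 0.0)
        halo_area = _halo_area_mm2(params) if les else 0.0
        base_area = max(tissue_area - halo_area, 0.0)
        d0 = params.wfa_density_per_mm2

        def in_tissue(cx, cy):
            ok = (cx / a) ** 2 + (cy / b) ** 2 <= 1.0
            if les:
                ok &= (cx - HOLE_CX_MM) ** 2 + cy**2 > r_hole**2
            return ok

        def in_halo(cx, cy):
            dd = (cx - HOLE_CX_MM) ** 2 + cy**2
            return (dd > r_hole**2) & (dd <= r_halo**2) & (cy > 0) & in_tissue(cx, cy)

        def in_base(cx, cy):
            ok = in_tissue(cx, cy)
            if les:
                ok &= ~in_halo(cx, cy)
            return ok

        n_base = cell_rng.poisson(d0 * base_area)
        cx_b, cy_b = _sample_points_in(cell_rng, int(n_base), in_base, (-a, a, -b, b))
        if les and halo_area > 0:
            n_halo = cell_rng.poisson(d0 * params.wfa_retention_iba1pos * halo_area)
            cx_h, cy_h = _sample_points_in(
                cell_rng, int(n_halo), in_halo, (HOLE_CX_MM - r_halo, HOLE_CX_MM + r_halo, 0.0, r_halo)
            )
            cx_all = np.concatenate([cx_b, cx_h])
            cy_all = np.concatenate([cy_b, cy_h])
        else:
            cx_all, cy_all = cx_b, cy_b

        gt.true_wfa_counts[sid] = {
            name: int(np.count_nonzero(rect.contains(cx_all, cy_all)))
            for name, rect in rois.items()
        }

        for ci, chan in enumerate(channels):
            base, sig = _LEVELS[chan]
            img = np.full(shape, _BG, dtype=np.float64)
            if chan == "DAPI":
                img[tissue & ~hole] = base
            elif chan == "Iba1":
                img[tissue & ~hole] = base
                img[halo] = sig
            elif chan == "IgG":
                img[tissue & ~hole] = base
                img[cloud] = sig
            elif chan == "WFA":
                img[tissue & ~hole] = base
                rr, cc = frame.to_px(cx_all, cy_all)
                _stamp_cells(img, rr, cc, cell_r_px, _WFA_PEAK)
            if params.intensity_noise_sd > 0:
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [int(params.rng_seed) & 0x7FFFFFFF, 2, rank, CHANNELS.index(chan)]
                    )
                )
                img += noise_rng.normal(0.0, params.intensity_noise_sd, shape)
            stacks[chan].append(np.clip(img, 0, 255).astype(np.uint8))

    out = {
        chan: ChannelStack(
            channel=chan,
            slices=stacks[chan],
            slice_ids=list(slice_ids),
            calibration=cal,
        )
        for chan in channels
    }
    return out, gt


# ---------------------------------------------------------------------------
# lightweight ROI-patch simulator for statistical calibration at scale
# ---------------------------------------------------------------------------

def simulate_roi_patches(
    params: SynthParams,
    rng: np.random.Generator,
    region_class: str,
) -> dict[str, np.ndarray]:
    """Render one ipsi/contra WFA ROI image pair for one slice.

    The patch is the ROI rectangle rendered in isolation with the same
    cell model and intensity statistics as :func:`generate_brain`:
    ipsilateral density is the baseline times the retention fraction for
    the ``"iba1_pos"`` class and the plain baseline for ``"iba1_neg"``;
    contralateral patches always carry the baseline density.  Used to
    exercise detection and fold-change statistics over hundreds of
    simulated brains without rendering full sections.
    """
    if region_class not in ("iba1_pos", "iba1_neg"):
        raise ValueError("region_class must be 'iba1_pos' or 'iba1_neg'")
    rect = ROI_IBA1_POS if region_class == "iba1_pos" else ROI_IBA1_NEG
    mpp = params.microns_per_pixel
    pad_px = int(math.ceil(2.0 * params.wfa_cell_radius_um / mpp)) + 2
    w_px = int(round((rect.x1 - rect.x0) * 1000.0 / mpp))
    h_px = int(round((rect.y1 - rect.y0) * 1000.0 / mpp))
    shape = (h_px + 2 * pad_px, w_px + 2 * pad_px)
    pad_mm = pad_px * mpp / 1000.0
    full_area = ((rect.x1 - rect.x0) + 2 * pad_mm) * ((rect.y1 - rect.y0) + 2 * pad_mm)
    cell_r_px = params.wfa_cell_radius_um / mpp
    out: dict[str, np.ndarray] = {}
    for side in ("ipsi", "contra"):
        dens = params.wfa_density_per_mm2
        if side == "ipsi" and region_class == "iba1_pos":
            dens *= params.wfa_retention_iba1pos
        n_cells = rng.poisson(dens * full_area)
        img = np.full(shape, _LEVELS["WFA"][0], dtype=np.float64)
        rr = rng.uniform(0, shape[0], n_cells)
        cc = rng.uniform(0, shape[1], n_cells)
        _stamp_cells(img, rr, cc, cell_r_px, _WFA_PEAK)
        if params.intensity_noise_sd > 0:
            img += rng.normal(0.0, params.intensity_noise_sd, shape)
        out[side] = np.clip(img, 0, 255).astype(np.uint8)
    out["roi_px"] = np.array([pad_px, pad_px, pad_px + h_px, pad_px + w_px])  # r0,c0,r1,c1
    return out


# ---------------------------------------------------------------------------
# on-disk manifest
# ---------------------------------------------------------------------------

def write_brain(
    stacks: dict[str, ChannelStack],
    gt: GroundTruth,
    params: SynthParams,
    directory: str | Path,
) -> None:
    """Write TIFF stacks, TSV ground-truth manifest and JSON params."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for chan in sorted(stacks):
        save_stack(stacks[chan], directory)
    any_stack = next(iter(stacks.values()))
    rows = []
    for sid in any_stack.slice_ids:
        (x0, y0), (x1, y1) = gt.true_reference_lines[sid]
        rows.append(
            {
                "slice_id": sid,
                "true_rank": gt.true_order.index(sid),
                "true_bregma_mm": gt.true_bregma_mm[sid],
                "true_section_area_mm2": gt.true_section_area_mm2[sid],
                "true_lesion_area_mm2": gt.true_lesion_area_mm2[sid],
                "true_iba1_area_mm2": gt.true_iba1_area_mm2[sid],
                "true_igg_area_mm2": gt.true_igg_area_mm2[sid],
                "line_x0": x0,
                "line_y0": y0,
                "line_x1": x1,
                "line_y1": y1,
                **{f"wfa_{k}": v for k, v in gt.true_wfa_counts[sid].items()},
            }
        )
    pd.DataFrame(rows).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    meta = dataclasses.asdict(params)
    meta["true_lesion_volume_mm3"] = gt.true_lesion_volume_mm3
    meta["true_iba1_volume_mm3"] = gt.true_iba1_volume_mm3
    meta["true_igg_volume_mm3"] = gt.true_igg_volume_mm3
    meta["rois_mm"] = {k: dataclasses.asdict(v) for k, v in gt.rois.items()}
    (directory / "params.json").write_text(json.dumps(meta, indent=2, default=list))
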