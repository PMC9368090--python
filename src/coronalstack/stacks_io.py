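"""Reading and writing per-section channel images.

Serial coronal sections are stored one TIFF per section per channel, named

    <experiment>_<brain>_<channel>[_mask]_<sliceid>.tif

Slices within one interleaved series are equidistant along the
anteroposterior (AP) axis: with 40 um sections distributed over 8 series the
in-series spacing is 0.32 mm.  AP positions are bregma coordinates in mm,
positive anterior; moving posterior through the series the position
decreases by one inter-slice spacing per rank.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Calibration", "ChannelStack", "load_stack", "save_stack"]


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of a sectioned brain.

    Parameters
    ----------
    microns_per_pixel:
        In-plane pixel size, um/px.
    slice_thickness_um:
        Physical section thickness, um (cryostat setting).
    series_count:
        Number of interleaved AP-ordered series the sections were
        distributed into; consecutive slices of one series are
        ``slice_thickness_um * series_count`` um apart.
    anchor_bregma_mm:
        AP position (bregma, mm) of the most anterior slice of the
        analyzed series.  May be negative.
    """

    microns_per_pixel: float
    slice_thickness_um: float = 40.0
    series_count: int = 8
    anchor_bregma_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.slice_thickness_um <= 0:
            raise ValueError("slice_thickness_um must be > 0")
        if self.series_count <= 0:
            raise ValueError("series_count must be > 0")

    @property
    def inter_slice_spacing_mm(self) -> float:
        """AP distance between consecutive slices of one series, mm."""
        return self.slice_thickness_um * self.series_count / 1000.0

    @property
    def mm2_per_px(self) -> float:
        """Area of one pixel in mm^2."""
        return (self.microns_per_pixel / 1000.0) ** 2

    def bregma_of_rank(self, rank: int | np.ndarray) -> float | np.ndarray:
        """AP position of the slice at a given sorted rank (0 = anterior)."""
        return self.anchor_bregma_mm - np.asarray(rank) * self.inter_slice_spacing_mm


@dataclass
class ChannelStack:
    """Ordered 2D section images for one fluorescence channel of one brain."""

    channel: str
    slices: list[np.ndarray]
    slice_ids: list[str]
    calibration: Calibration
    brain: str = "B1"
    experiment: str = "EXP"
    is_mask: bool = False

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.slice_ids):
            raise ValueError("slices and slice_ids must have equal length")
        if len(set(self.slice_ids)) != len(self.slice_ids):
            raise ValueError("slice_ids must be unique")
        shapes = {im.shape for im in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"all slices must share one shape, got {shapes}")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.slices[0].shape if self.slices else None

    def reordered(self, slice_ids: list[str]) -> "ChannelStack":
        """Return a copy with slices permuted into the given id order."""
        index = {sid: i for i, sid in enumerate(self.slice_ids)}
        missing = [sid for sid in slice_ids if sid not in index]
        if missing:
            raise KeyError(f"slice ids not in stack: {missing}")
        return replace(
            self,
            slices=[self.slices[index[s]] for s in slice_ids],
            slice_ids=list(slice_ids),
        )


def _filename(stack: ChannelStack, slice_id: str) -> str:
    mask = "_mask" if stack.is_mask else ""
    return f"{stack.experiment}_{stack.brain}_{stack.channel}{mask}_{slice_id}.tif"


def save_stack(stack: ChannelStack, directory: str | Path) -> list[Path]:
    """Write one TIFF per slice under the naming convention.

    Returns the written paths in slice order.  An empty stack writes
    nothing and returns an empty list.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for image, slice_id in zip(stack.slices, stack.slice_ids):
        path = directory / _filename(stack, slice_id)
        tifffile.imwrite(path, np.asarray(image))
        paths.append(path)
    return paths


def load_stack(
    directory: str | Path,
    brain: str,
    channel: str,
    calibration: Calibration,
    experiment: str | None = None,
    mask: bool = False,
) -> ChannelStack:
    """Assemble the channel stack for one brain from per-section TIFFs.

    Files are matched by the ``*_<brain>_<channel>[_mask]_<sliceid>.tif``
    convention and loaded in filename-lexicographic order; the order
    before sorting is arbitrary by design (AP order is recovered later
    from the contour areas).  Slice ids are taken from the trailing
    filename token.
    """
    directory = Path(directory)
    mask_part = "_mask" if mask else ""
    pattern = f"*_{brain}_{channel}{mask_part}_*.tif"
    rx = re.compile(
        rf"^(?P<exp>.+)_{re.escape(brain)}_{re.escape(channel)}{mask_part}_(?P<sid>[^_]+)\.tiff?$"
    )
    hits = sorted(p for p in directory.glob(pattern) if rx.match(p.name))
    if not hits:
        raise FileNotFoundError(
            f"no files matching {pattern!r} for brain={brain!r} "
            f"channel={channel!r} in {directory}"
        )
    slices, slice_ids, exp_name = [], [], None
    for path in hits:
        m = rx.match(path.name)
        assert m is not None
        image = tifffile.imread(path)
        if slices and image.shape != slices[0].shape:
            raise ValueError(
                f"mixed image dimensions: {path.name} has shape {image.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(image)
        slice_ids.append(m.group("sid"))
        exp_name = m.group("exp")
    return ChannelStack(
        channel=channel,
        slices=slices,
        slice_ids=slice_ids,
        calibration=calibration,
        brain=brain,
        experiment=exp_name or "EXP",
        is_mask=mask,
    )
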