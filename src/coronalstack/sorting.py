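"""Anteroposterior sorting of shuffled sections by outer-contour area.

Across the anterior frontal-to-parietal window the cross-sectional area
of the mouse brain grows monotonically, so ranking sections by their
(hole-bridged) contour area recovers the anteroposterior order without
any atlas.  The assumption holds up to bregma -2.0 mm: for stacks whose
calibration implies slices caudal to that bound a warning is attached,
since area growth is no longer monotone there and the ordering is not
trustworthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .masking import ContourProfile
from .stacks_io import Calibration

__all__ = ["SortResult", "sort_by_contour_area", "CAUDAL_VALIDITY_BREGMA_MM"]

CAUDAL_VALIDITY_BREGMA_MM = -2.0


@dataclass
class SortResult:
    """Recovered AP order: ``order[rank] = slice_id`` (anterior first)."""

    order: list[str]
    key_areas_mm2: list[float]
    warnings: list[str] = field(default_factory=list)

    def rank_of(self, slice_id: str) -> int:
        return self.order.index(slice_id)


def sort_by_contour_area(
    profiles: list[ContourProfile],
    calibration: Calibration | None = None,
) -> SortResult:
    """Order slices by ascending contour area (anterior = smallest).

    Ties are broken by lexicographic slice id and reported in
    ``warnings``.  Callers wanting posterior-first order reverse the
    result explicitly.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 contour profiles to sort")
    ids = [p.slice_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate slice_ids: {dupes}")

    def key_area(p: ContourProfile) -> float:
        a = p.contour_area_mm2
        return float(a) if np.isfinite(a) else float(p.contour_area_px)

    notes: list[str] = []
    ordered = sorted(profiles, key=lambda p: (key_area(p), p.slice_id))
    areas = [key_area(p) for p in ordered]
    seen: dict[float, str] = {}
    for p, a in zip(ordered, areas):
        if a in seen:
            notes.append(
                f"tied contour area {a!r} between slices {seen[a]!r} and "
                f"{p.slice_id!r}; order broken by slice id"
            )
        else:
            seen[a] = p.slice_id
    if calibration is not None:
        last = calibration.bregma_of_rank(len(profiles) - 1)
        if last < CAUDAL_VALIDITY_BREGMA_MM:
            notes.append(
                f"stack extends to bregma {last:+.2f} mm, caudal to the "
                f"{CAUDAL_VALIDITY_BREGMA_MM:+.1f} mm validity bound of "
                "area-based sorting; ordering of caudal slices is unreliable"
            )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return SortResult(order=[p.slice_id for p in ordered], key_areas_mm2=areas, warnings=notes)
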