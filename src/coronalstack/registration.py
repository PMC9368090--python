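"""Line-based rigid/similarity registration of a sorted stack.

Each slice carries one user-drawn (or ground-truth) reference segment,
conventionally the anatomical midline with the first endpoint at the
dorsal end.  Two point correspondences determine exactly the four
degrees of freedom of a 2D similarity (rotation, isotropic scale,
translation), which is fitted in closed form and applied to every
channel of the brain: because the series are mutually registered, the
transforms estimated on the DAPI series transfer unchanged to the
Iba1/IgG/WFA series (the multiplexing contract).

Elastic or polynomial warps are deliberately not offered: on injured
tissue they hallucinate structure around the cavity, while a similarity
can at worst be rigidly wrong.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stacks_io import ChannelStack

__all__ = [
    "ReferenceLine",
    "SliceTransform",
    "fit_line_transform",
    "apply_transforms",
    "transform_points",
]


@dataclass(frozen=True)
class ReferenceLine:
    """One reference segment; endpoints in (x, y) pixel coordinates.

    By convention ``p0`` is the dorsal (top) end of the midline.
    """

    slice_id: str
    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError(f"degenerate reference line on slice {self.slice_id!r}")

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)


@dataclass(frozen=True)
class SliceTransform:
    """Similarity q = s * R(theta) @ p + t mapping slice to reference frame."""

    slice_id: str
    rotation: float  # radians, positive from +x toward +y (image y points down)
    scale: float
    translation: tuple[float, float]  # (dx, dy) px
    model: str = "similarity"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def complex_coeffs(self) -> tuple[complex, complex]:
        a = self.scale * cmath.exp(1j * self.rotation)
        return a, complex(*self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points into the reference frame."""
        a, b = self.complex_coeffs
        z = points[:, 0] + 1j * points[:, 1]
        w = a * z + b
        return np.column_stack([w.real, w.imag])

    def inverse(self) -> "SliceTransform":
        a, b = self.complex_coeffs
        ai = 1.0 / a
        bi = -b / a
        return SliceTransform(
            slice_id=self.slice_id,
            rotation=cmath.phase(ai),
            scale=abs(ai),
            translation=(bi.real, bi.imag),
            model=self.model,
        )


def transform_points(transform: SliceTransform, points: np.ndarray) -> np.ndarray:
    return transform.apply(np.asarray(points, dtype=float))


def fit_line_transform(line: ReferenceLine, reference: ReferenceLine) -> SliceTransform:
    """Closed-form similarity mapping ``line`` onto ``reference``.

    In complex coordinates z = x + iy the map is w = a z + b with
    a = (q1 - q0) / (p1 - p0) and b = q0 - a p0, so the slice's endpoint
    pair lands exactly on the reference pair; identical lines give the
    identity.
    """
    p0, p1 = complex(*line.p0), complex(*line.p1)
    q0, q1 = complex(*reference.p0), complex(*reference.p1)
    a = (q1 - q0) / (p1 - p0)
    b = q0 - a * p0
    return SliceTransform(
        slice_id=line.slice_id,
        rotation=cmath.phase(a),
        scale=abs(a),
        translation=(b.real, b.imag),
    )


def apply_transforms(
    stack: ChannelStack,
    transforms: dict[str, SliceTransform] | list[SliceTransform],
) -> ChannelStack:
    """Resample every slice of a stack into the reference frame.

    Bilinear interpolation, out-of-frame pixels set to 0; output
    dimensions equal input dimensions.  Transforms are keyed by
    slice_id, so the same set is reusable across the channels of one
    brain.
    """
    if not isinstance(transforms, dict):
        transforms = {t.slice_id: t for t in transforms}
    missing = [sid for sid in stack.slice_ids if sid not in transforms]
    if missing:
        raise KeyError(f"missing transform for slices: {missing}")
    out_slices = []
    for image, sid in zip(stack.slices, stack.slice_ids):
        t = transforms[sid]
        inv = t.inverse()
        c, s = math.cos(inv.rotation), math.sin(inv.rotation)
        # (x, y) action: p = s*R @ q + t; ndimage works on (row, col) = (y, x)
        m_xy = inv.scale * np.array([[c, -s], [s, c]])
        m_rc = np.array([[m_xy[1, 1], m_xy[1, 0]], [m_xy[0, 1], m_xy[0, 0]]])
        offset = np.array([inv.translation[1], inv.translation[0]])
        warped = ndimage.affine_transform(
            image.astype(np.float64),
            m_rc,
            offset=offset,
            order=1,
            mode="constant",
            cval=0.0,
            output_shape=image.shape,
        )
        if np.issubdtype(image.dtype, np.integer):
            info = np.iinfo(image.dtype)
            warped = np.clip(np.rint(warped), info.min, info.max)
        out_slices.append(warped.astype(image.dtype))
    result = ChannelStack(
        channel=stack.channel,
        slices=out_slices,
        slice_ids=list(stack.slice_ids),
        calibration=stack.calibration,
        brain=stack.brain,
        experiment=stack.experiment,
        is_mask=stack.is_mask,
    )
    return result
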