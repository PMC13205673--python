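"""Stem coordinate system and resampling between the CT and stem-aligned grids.

The stem frame is the measurement coordinate system of hip CT-RSA: y along
the prosthetic stem centerline (positive superior/proximal), x along the
neckline (positive medial, reported as if all hips were right-sided), z
completing a right-handed frame (anterior-positive for a right hip).  The
"rotation" of the CT described by the simulator is implemented as resampling
the image onto a grid whose axes are parallel to the stem frame; the inverse
rotation resamples back onto the original grid.  Both directions are grid
changes in a fixed world space, so the forward and inverse rigid transforms
compose to the identity exactly, independent of interpolation error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .io import _from_sitk, _to_sitk
from .phantom import StemLandmarks
from .volume import CTVolume, LabelVolume, check_congruent

__all__ = [
    "StemFrame",
    "ResampleSpec",
    "FrameResample",
    "DegenerateFrameError",
    "build_stem_frame",
    "default_frame_spacing",
    "resample_to_frame",
    "resample_from_frame",
]


class DegenerateFrameError(ValueError):
    """Landmarks too close to collinear to define a stem frame."""


@dataclass(frozen=True)
class StemFrame:
    """Orthonormal stem coordinate system.

    ``rotation`` columns are the unit x (neckline), y (centerline) and z axes
    expressed in world coordinates; ``origin_mm`` is the stem center.
    """

    origin_mm: tuple[float, float, float]
    rotation: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise DegenerateFrameError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("rotation is not orthonormal")
        if not math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-9):
            raise DegenerateFrameError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def x_axis(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.rotation[:, 2]


@dataclass(frozen=True)
class ResampleSpec:
    """How volumes are resampled onto the stem-aligned grid."""

    interpolation: str = "linear"
    output_spacing_mm: tuple[float, float, float] | None = None  # None: inherit (permuted) CT spacing
    padding_value: float = -1024.0

    def __post_init__(self) -> None:
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")
        if self.output_spacing_mm is not None:
            s = tuple(float(v) for v in self.output_spacing_mm)
            if any(v <= 0 for v in s):
                raise ValueError("output_spacing must be strictly positive")
            object.__setattr__(self, "output_spacing_mm", s)


def build_stem_frame(landmarks: StemLandmarks, side: str) -> StemFrame:
    """Stem frame from the stem center, tip and neck point.

    y = unit(center - tip) (distal to proximal); x = the component of
    (neck_point - center) orthogonal to y, negated for left hips so reported
    x follows the as-if-right-sided convention; z = x cross y (right-handed,
    det +1).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    center = np.asarray(landmarks.center_mm, float)
    tip = np.asarray(landmarks.tip_mm, float)
    neck = np.asarray(landmarks.neck_point_mm, float)

    y = center - tip
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateFrameError("stem center and tip coincide")
    yhat = y / ny

    v = neck - center
    x_perp = v - (v @ yhat) * yhat
    nv = np.linalg.norm(v)
    if nv < 1e-9 or np.linalg.norm(x_perp) < math.sin(math.radians(1.0)) * nv:
        raise DegenerateFrameError("neck point is collinear with the stem axis")
    xhat = x_perp / np.linalg.norm(x_perp)
    if side == "left":
        xhat = -xhat
    zhat = np.cross(xhat, yhat)

    R = np.column_stack([xhat, yhat, zhat])
    # re-orthonormalise against accumulated rounding before the strict ctor
    u_svd, _, vt = np.linalg.svd(R)
    R = u_svd @ vt
    return StemFrame(tuple(center), R, side)


def default_frame_spacing(vol: CTVolume, frame: StemFrame) -> tuple[float, float, float]:
    """CT spacing permuted to the closest-aligned frame axis, so a one-voxel
    step in the stem grid stays comparable to the baseline spacing."""
    out = []
    for j in range(3):
        dots = np.abs(vol.direction.T @ frame.rotation[:, j])
        out.append(float(vol.spacing[int(np.argmax(dots))]))
    return tuple(out)


@dataclass(frozen=True)
class FrameResample:
    """Record of a forward resampling, sufficient to invert it exactly."""

    frame: StemFrame
    reference_shape: tuple[int, int, int]
    reference_spacing: tuple[float, float, float]
    reference_origin: tuple[float, float, float]
    reference_direction: np.ndarray
    frame_shape: tuple[int, int, int]
    frame_spacing: tuple[float, float, float]
    frame_origin: tuple[float, float, float]

    @property
    def world_to_frame(self) -> np.ndarray:
        """4x4 homogeneous map from world mm to stem-frame mm coordinates."""
        R = self.frame.rotation
        o = np.asarray(self.frame.origin_mm)
        M = np.eye(4)
        M[:3, :3] = R.T
        M[:3, 3] = -R.T @ o
        return M

    @property
    def frame_to_world(self) -> np.ndarray:
        R = self.frame.rotation
        o = np.asarray(self.frame.origin_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = o
        return M

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "world_to_frame": self.world_to_frame.tolist(),
                    "frame_to_world": self.frame_to_world.tolist(),
                    "side": self.frame.side,
                    "frame_spacing_mm": list(self.frame_spacing),
                },
                fh,
                indent=2,
            )


_INTERPOLATORS = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def _frame_grid(vol, frame: StemFrame, spacing) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Stem-aligned grid (shape, world origin) covering the volume's voxel-centre
    bounding box.  Sized so that an axis-aligned identity frame reproduces the
    input grid exactly."""
    n = np.asarray(vol.shape)
    corners_ijk = np.array([[i, j, k] for i in (0, n[0] - 1) for j in (0, n[1] - 1) for k in (0, n[2] - 1)], float)
    corners = (
        np.asarray(vol.origin)
        + (corners_ijk * np.asarray(vol.spacing)) @ np.asarray(vol.direction).T
    )
    R = frame.rotation
    o = np.asarray(frame.origin_mm)
    proj = (corners - o) @ R
    pmin = proj.min(axis=0)
    pmax = proj.max(axis=0)
    spacing = np.asarray(spacing, float)
    shape = tuple(int(math.ceil((pmax[j] - pmin[j]) / spacing[j] - 1e-6)) + 1 for j in range(3))
    origin = tuple(o + R @ pmin)
    return shape, origin


def _resample_onto(voxels, src_grid, dst_shape, dst_spacing, dst_origin, dst_direction, interpolation, padding):
    src = _to_sitk(voxels, *src_grid)
    ref = sitk.Image(*[int(v) for v in dst_shape], src.GetPixelID())
    ref.SetSpacing(tuple(float(s) for s in dst_spacing))
    ref.SetOrigin(tuple(float(v) for v in dst_origin))
    ref.SetDirection(tuple(np.asarray(dst_direction, float).ravel()))
    out = sitk.Resample(src, ref, sitk.Transform(), _INTERPOLATORS[interpolation], float(padding))
    arr, *_ = _from_sitk(out)
    return arr


def resample_to_frame(
    vol: CTVolume | LabelVolume,
    frame: StemFrame,
    spec: ResampleSpec = ResampleSpec(),
):
    """Resample a volume onto the stem-aligned grid ("rotate the CT").

    Returns ``(resampled_volume, record)`` where the record carries the exact
    grids and rigid transform needed by :func:`resample_from_frame`.  Label
    volumes always use nearest-neighbour interpolation and zero padding.
    """
    is_label = isinstance(vol, LabelVolume)
    data = vol.labels if is_label else vol.voxels
    ref_for_spacing = CTVolume(np.zeros((1, 1, 1)), vol.spacing, vol.origin, vol.direction)
    spacing = spec.output_spacing_mm or default_frame_spacing(ref_for_spacing, frame)
    shape, origin = _frame_grid(vol, frame, spacing)
    interp = "nearest" if is_label else spec.interpolation
    padding = 0 if is_label else spec.padding_value
    arr = _resample_onto(
        data,
        (vol.spacing, vol.origin, vol.direction),
        shape,
        spacing,
        origin,
        frame.rotation,
        interp,
        padding,
    )
    record = FrameResample(
        frame=frame,
        reference_shape=tuple(int(v) for v in vol.shape),
        reference_spacing=vol.spacing,
        reference_origin=vol.origin,
        reference_direction=np.asarray(vol.direction),
        frame_shape=shape,
        frame_spacing=tuple(float(s) for s in spacing),
        frame_origin=origin,
    )
    if is_label:
        out = LabelVolume(arr, spacing, origin, frame.rotation, dict(vol.label_codes))
    else:
        out = CTVolume(arr, spacing, origin, frame.rotation)
    return out, record


def resample_from_frame(
    vol: CTVolume | LabelVolume,
    record: FrameResample,
    reference: CTVolume | LabelVolume,
    interpolation: str = "linear",
    padding_value: float = -1024.0,
):
    """Resample a stem-grid volume back onto the original CT grid (the exact
    inverse of the recorded forward resampling)."""
    ref_stub = CTVolume(
        np.zeros((1, 1, 1)),
        record.reference_spacing,
        record.reference_origin,
        record.reference_direction,
    )
    if tuple(reference.shape) != record.reference_shape or not check_congruent(
        CTVolume(np.zeros(record.reference_shape), record.reference_spacing, record.reference_origin, record.reference_direction),
        reference,
    ):
        raise ValueError("reference grid does not match the grid recorded by resample_to_frame")
    is_label = isinstance(vol, LabelVolume)
    data = vol.labels if is_label else vol.voxels
    interp = "nearest" if is_label else interpolation
    padding = 0 if is_label else padding_value
    arr = _resample_onto(
        data,
        (vol.spacing, vol.origin, vol.direction),
        record.reference_shape,
        record.reference_spacing,
        record.reference_origin,
        record.reference_direction,
        interp,
        padding,
    )
    if is_label:
        return LabelVolume(arr, record.reference_spacing, record.reference_origin, record.reference_direction, dict(vol.label_codes))
    return CTVolume(arr, record.reference_spacing, record.reference_origin, record.reference_direction)
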