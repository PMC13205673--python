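"""Integer-voxel implant shifts in the stem-aligned grid, hole filling, and
follow-up generation.

The simulated migration is exact by construction: inside the stem-aligned
grid the implant voxels (stem + head) are moved by a pure integer array
translation, so the applied displacement in mm is exactly the voxel shift
times the stem-grid spacing.  Voxels the implant vacates are filled with the
HU of their nearest soft-tissue neighbour (Euclidean distance in mm) followed
by a small mean filter restricted to the vacated set.  The filled frame-space
image is then resampled back onto the original CT grid to produce the
follow-up scan.

Shift components are given in the reported stem coordinate convention
(positive = medial / superior / anterior, as if all hips were right-sided);
for a left-sided frame the x component is mirrored onto the grid axis so the
recorded ground truth matches what a convention-following measurement reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frame import FrameResample, ResampleSpec, StemFrame, resample_from_frame, resample_to_frame
from .io import ManifestRecord
from .volume import CTVolume, LabelVolume

__all__ = [
    "ShiftSpec",
    "FillConfig",
    "ShiftOutOfBoundsError",
    "apply_shift",
    "fill_vacated",
    "generate_followup",
    "generate_followup_set",
]

_PROTOCOL_BOUNDS = (4, 5, 4)  # |dx|, |dy|, |dz| caps of the shift protocol
_AXIS_NAMES = ("x", "y", "z")


class ShiftOutOfBoundsError(ValueError):
    """A shift would push implant voxels outside the grid."""


@dataclass(frozen=True)
class ShiftSpec:
    """One integer-voxel migration step in the stem-aligned grid.

    ``generating_axes`` records which protocol family produced the shift
    (one-axis families carry a single axis; the paired two-axis family two;
    the dedicated two-axis zero example none).
    """

    dx: int
    dy: int
    dz: int
    generating_axes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dx", int(self.dx))
        object.__setattr__(self, "dy", int(self.dy))
        object.__setattr__(self, "dz", int(self.dz))
        object.__setattr__(self, "generating_axes", frozenset(self.generating_axes))
        if not self.generating_axes <= set(_AXIS_NAMES):
            raise ValueError(f"generating_axes must be a subset of x/y/z, got {self.generating_axes}")
        for value, bound, name in zip((self.dx, self.dy, self.dz), _PROTOCOL_BOUNDS, _AXIS_NAMES):
            if abs(value) > bound:
                raise ValueError(f"|d{name}| = {abs(value)} exceeds the protocol bound {bound}")

    @property
    def voxels(self) -> tuple[int, int, int]:
        return (self.dx, self.dy, self.dz)

    def truth_mm(self, frame_spacing_mm) -> tuple[float, float, float]:
        return tuple(d * float(s) for d, s in zip(self.voxels, frame_spacing_mm))


@dataclass(frozen=True)
class FillConfig:
    """How vacated implant voxels are filled."""

    fill_source_labels: frozenset[str] = frozenset({"SoftTissue"})
    smoothing_radius_voxels: int = 1
    fallback: str = "nearest_any_nonimplant"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fill_source_labels", frozenset(self.fill_source_labels))
        if self.smoothing_radius_voxels < 0:
            raise ValueError("smoothing_radius_voxels must be >= 0")
        if self.fallback != "nearest_any_nonimplant":
            raise ValueError(f"unknown fallback {self.fallback!r}")


def apply_shift(
    ct_frame: CTVolume,
    lab_frame: LabelVolume,
    implant_labels: tuple[str, ...],
    shift: tuple[int, int, int] | ShiftSpec,
    vacated_label: str = "SoftTissue",
) -> tuple[CTVolume, LabelVolume, np.ndarray, float]:
    """Translate the implant voxels by an integer grid shift.

    Returns ``(shifted_ct, shifted_labels, vacated_mask, overlap_fraction)``.
    The implant's HU and labels move exactly by the shift; destination voxels
    previously holding other tissue are overwritten (the fraction of such
    voxels relative to the implant size is reported); vacated voxels (source
    minus destination) are relabelled ``vacated_label`` and left for
    :func:`fill_vacated`; all other voxels are bit-identical to the input.
    """
    d = shift.voxels if isinstance(shift, ShiftSpec) else tuple(int(v) for v in shift)
    mask = lab_frame.mask(*implant_labels)
    if not mask.any():
        raise ValueError("implant mask is empty")

    src = np.argwhere(mask)
    lo = src.min(axis=0)
    hi = src.max(axis=0)
    shape = np.asarray(ct_frame.shape)
    for ax in range(3):
        if lo[ax] + d[ax] < 0 or hi[ax] + d[ax] > shape[ax] - 1:
            raise ShiftOutOfBoundsError(
                f"shift {d} pushes implant voxels out of bounds along axis {_AXIS_NAMES[ax]}"
            )

    dst_mask = np.zeros_like(mask)
    dst = src + np.asarray(d)
    dst_mask[dst[:, 0], dst[:, 1], dst[:, 2]] = True

    vacated = mask & ~dst_mask
    overwritten = dst_mask & ~mask
    overlap_fraction = float(overwritten.sum()) / float(mask.sum())

    ct_out = ct_frame.copy()
    lab_out = lab_frame.copy()
    hu = ct_frame.voxels[mask]
    lv = lab_frame.labels[mask]
    lab_out.labels[vacated] = lab_frame.code(vacated_label)
    ct_out.voxels[dst[:, 0], dst[:, 1], dst[:, 2]] = hu
    lab_out.labels[dst[:, 0], dst[:, 1], dst[:, 2]] = lv
    return ct_out, lab_out, vacated, overlap_fraction


def fill_vacated(
    ct: CTVolume,
    vacated: np.ndarray,
    lab: LabelVolume,
    cfg: FillConfig = FillConfig(),
    implant_labels: tuple[str, ...] = ("Stem", "Head"),
) -> CTVolume:
    """Fill vacated voxels with the nearest soft-tissue HU, then smooth them.

    Each vacated voxel receives the HU of its nearest (Euclidean, mm-scaled)
    voxel whose label is in ``fill_source_labels`` (excluding the vacated set
    itself); if no donor exists anywhere, the nearest non-implant voxel is
    used.  A mean filter of the configured radius is then applied over the
    vacated voxels only, averaging already-filled and surrounding non-implant
    values.  Non-vacated voxels are returned unchanged.
    """
    out = ct.copy()
    if not vacated.any():
        return out
    implant = lab.mask(*implant_labels)
    if (vacated & implant).any():
        raise ValueError("vacated mask overlaps the current implant mask")

    donors = lab.mask(*cfg.fill_source_labels) & ~vacated & ~implant
    if not donors.any():
        donors = ~implant & ~vacated
    # nearest-donor lookup via the Euclidean distance transform of the
    # non-donor region, scaled by the physical voxel spacing
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~donors, sampling=ct.spacing, return_indices=True
    )
    out.voxels[vacated] = ct.voxels[ix[vacated], iy[vacated], iz[vacated]]

    r = cfg.smoothing_radius_voxels
    if r > 0:
        size = 2 * r + 1
        valid = (~implant).astype(np.float64)
        values = np.where(~implant, out.voxels.astype(np.float64), 0.0)
        num = ndimage.uniform_filter(values, size=size, mode="constant", cval=0.0)
        den = ndimage.uniform_filter(valid, size=size, mode="constant", cval=0.0)
        smoothed = np.divide(num, den, out=np.asarray(out.voxels, dtype=np.float64).copy(), where=den > 0)
        out.voxels[vacated] = smoothed[vacated].astype(out.voxels.dtype)
    return out


def _grid_shift(shift: ShiftSpec, frame: StemFrame) -> tuple[int, int, int]:
    """Reported-convention shift -> stem-grid shift (x mirrored for left hips)."""
    if frame.side == "left":
        return (-shift.dx, shift.dy, shift.dz)
    return shift.voxels


def generate_followup(
    baseline: CTVolume,
    labels: LabelVolume,
    frame: StemFrame,
    shift: ShiftSpec,
    fill: FillConfig = FillConfig(),
    spec: ResampleSpec = ResampleSpec(),
    baseline_id: str = "baseline",
    followup_id: str | None = None,
    implant_labels: tuple[str, ...] = ("Stem", "Head"),
) -> tuple[CTVolume, ManifestRecord]:
    """Full pipeline for one synthetic follow-up CT.

    resample to the stem grid -> shift the implant -> fill vacated voxels ->
    resample back onto the baseline grid.  The manifest records the ground
    truth: shift voxels times the stem-grid spacing.
    """
    ct_f, record = resample_to_frame(baseline, frame, spec)
    lab_f, _ = resample_to_frame(labels, frame, spec)
    followup, manifest = _followup_in_frame(
        ct_f, lab_f, record, baseline, frame, shift, fill, spec,
        baseline_id, followup_id, implant_labels,
    )
    return followup, manifest


def _followup_in_frame(
    ct_f, lab_f, record: FrameResample, baseline, frame, shift, fill, spec,
    baseline_id, followup_id, implant_labels,
):
    d = _grid_shift(shift, frame)
    ct_s, lab_s, vacated, _overlap = apply_shift(ct_f, lab_f, implant_labels, d)
    ct_filled = fill_vacated(ct_s, vacated, lab_s, fill, implant_labels)
    followup = resample_from_frame(ct_filled, record, baseline, spec.interpolation, spec.padding_value)
    if followup_id is None:
        followup_id = f"{baseline_id}_d{shift.dx}_{shift.dy}_{shift.dz}"
    manifest = ManifestRecord.from_shift(
        baseline_id, followup_id, shift.generating_axes, shift.voxels, record.frame_spacing
    )
    return followup, manifest


def generate_followup_set(
    baseline: CTVolume,
    labels: LabelVolume,
    frame: StemFrame,
    shifts,
    fill: FillConfig = FillConfig(),
    spec: ResampleSpec = ResampleSpec(),
    baseline_id: str = "baseline",
    implant_labels: tuple[str, ...] = ("Stem", "Head"),
):
    """Generate many follow-ups from one baseline, resampling to the stem
    grid once.  Yields ``(followup CTVolume, ManifestRecord)`` pairs."""
    ct_f, record = resample_to_frame(baseline, frame, spec)
    lab_f, _ = resample_to_frame(labels, frame, spec)
    for i, shift in enumerate(shifts):
        yield _followup_in_frame(
            ct_f, lab_f, record, baseline, frame, shift, fill, spec,
            baseline_id, f"{baseline_id}_fu{i:03d}", implant_labels,
        )
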