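"""Reading and writing volumes (NIfTI / NRRD), migration manifests and landmarks.

SimpleITK handles the on-disk formats; arrays are transposed so that the
in-memory index order (i, j, k) matches the file-axis order used throughout
the package.  Integer HU is stored as 16-bit signed, real HU as 32-bit float.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .volume import CTVolume, LabelVolume, DEFAULT_LABEL_CODES

__all__ = [
    "VolumeFormatError",
    "ManifestError",
    "ManifestRecord",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "write_manifest",
    "read_manifest",
    "save_landmarks",
    "load_landmarks",
]

_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


class VolumeFormatError(IOError):
    """Unreadable, unwritable or non-3-D image file."""


class ManifestError(ValueError):
    """Malformed migration manifest."""


def _to_sitk(voxels: np.ndarray, spacing, origin, direction) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetDirection(tuple(np.asarray(direction, dtype=float).ravel()))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple, np.ndarray]:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()), direction


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a 3-D CT volume from NIfTI (.nii/.nii.gz) or NRRD."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message depends on ITK
        raise VolumeFormatError(f"could not read image file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D image, got {img.GetDimension()}-D")
    arr, spacing, origin, direction = _from_sitk(img)
    return CTVolume(arr, spacing, origin, direction)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume losslessly: integral HU as int16, real HU as float32."""
    path = Path(path)
    voxels = vol.voxels
    if np.issubdtype(voxels.dtype, np.integer):
        voxels = voxels.astype(np.int16)
    else:
        voxels = voxels.astype(np.float32)
    img = _to_sitk(voxels, vol.spacing, vol.origin, vol.direction)
    try:
        sitk.WriteImage(img, str(path), useCompression=str(path).endswith(".gz"))
    except RuntimeError as exc:  # pragma: no cover
        raise VolumeFormatError(f"could not write image file {path}: {exc}") from exc


def read_label_volume(path: str | os.PathLike, label_codes=None) -> LabelVolume:
    """Read an integer label volume congruent with its CT."""
    vol = read_volume(path)
    labels = vol.voxels
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.array_equal(rounded, labels):
            raise VolumeFormatError(f"{path}: label volume contains non-integer values")
        labels = rounded.astype(np.int16)
    codes = dict(label_codes) if label_codes is not None else dict(DEFAULT_LABEL_CODES)
    return LabelVolume(labels, vol.spacing, vol.origin, vol.direction, codes)


def write_label_volume(lab: LabelVolume, path: str | os.PathLike) -> None:
    img = _to_sitk(lab.labels.astype(np.int16), lab.spacing, lab.origin, lab.direction)
    try:
        sitk.WriteImage(img, str(path), useCompression=str(path).endswith(".gz"))
    except RuntimeError as exc:  # pragma: no cover
        raise VolumeFormatError(f"could not write image file {path}: {exc}") from exc


# --------------------------------------------------------------------------
# migration manifest
# --------------------------------------------------------------------------

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ManifestRecord:
    """Ground truth for one synthetic follow-up.

    ``truth_mm`` is the applied integer voxel shift times the spacing of the
    stem-aligned grid, axis by axis, in the reported stem coordinate system
    (positive = medial / superior / anterior, as if right-sided).
    """

    baseline_id: str
    followup_id: str
    generating_axes: frozenset[str]
    shift_voxels: tuple[int, int, int]
    truth_mm: tuple[float, float, float]
    frame_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "generating_axes", frozenset(self.generating_axes))
        if not self.generating_axes <= set(_AXES):
            raise ManifestError(f"generating_axes must be a subset of x/y/z, got {self.generating_axes}")
        object.__setattr__(self, "shift_voxels", tuple(int(v) for v in self.shift_voxels))
        object.__setattr__(self, "truth_mm", tuple(float(v) for v in self.truth_mm))
        object.__setattr__(self, "frame_spacing_mm", tuple(float(v) for v in self.frame_spacing_mm))
        for i in range(3):
            expected = self.shift_voxels[i] * self.frame_spacing_mm[i]
            if self.truth_mm[i] != expected:
                raise ManifestError(
                    f"truth_mm[{i}]={self.truth_mm[i]!r} != shift*spacing={expected!r}"
                )

    @classmethod
    def from_shift(cls, baseline_id, followup_id, generating_axes, shift_voxels, frame_spacing_mm):
        shift_voxels = tuple(int(v) for v in shift_voxels)
        frame_spacing_mm = tuple(float(s) for s in frame_spacing_mm)
        truth = tuple(v * s for v, s in zip(shift_voxels, frame_spacing_mm))
        return cls(baseline_id, followup_id, frozenset(generating_axes), shift_voxels, truth, frame_spacing_mm)


_MANIFEST_COLUMNS = [
    "baseline_id",
    "followup_id",
    "generating_axes",
    "dx",
    "dy",
    "dz",
    "truth_x_mm",
    "truth_y_mm",
    "truth_z_mm",
    "frame_sx_mm",
    "frame_sy_mm",
    "frame_sz_mm",
]


def manifest_to_frame(records: Iterable[ManifestRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "baseline_id": r.baseline_id,
                "followup_id": r.followup_id,
                "generating_axes": "".join(a for a in _AXES if a in r.generating_axes),
                "dx": r.shift_voxels[0],
                "dy": r.shift_voxels[1],
                "dz": r.shift_voxels[2],
                "truth_x_mm": r.truth_mm[0],
                "truth_y_mm": r.truth_mm[1],
                "truth_z_mm": r.truth_mm[2],
                "frame_sx_mm": r.frame_spacing_mm[0],
                "frame_sy_mm": r.frame_spacing_mm[1],
                "frame_sz_mm": r.frame_spacing_mm[2],
            }
        )
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def write_manifest(records: Sequence[ManifestRecord], path: str | os.PathLike) -> None:
    """Write one CSV row per follow-up; floats round-trip at full precision."""
    df = manifest_to_frame(records)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_MANIFEST_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fields = [str(row[c]) if not isinstance(row[c], float) else repr(row[c]) for c in _MANIFEST_COLUMNS]
            fh.write(",".join(fields) + "\n")


def read_manifest(path: str | os.PathLike) -> list[ManifestRecord]:
    try:
        df = pd.read_csv(
            path,
            dtype={"baseline_id": str, "followup_id": str, "generating_axes": str},
            keep_default_na=False,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ManifestError(f"could not parse manifest {path}: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} lacks columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ManifestRecord(
                    baseline_id=str(row["baseline_id"]),
                    followup_id=str(row["followup_id"]),
                    generating_axes=frozenset(str(row["generating_axes"])) if row["generating_axes"] else frozenset(),
                    shift_voxels=(int(row["dx"]), int(row["dy"]), int(row["dz"])),
                    truth_mm=(float(row["truth_x_mm"]), float(row["truth_y_mm"]), float(row["truth_z_mm"])),
                    frame_spacing_mm=(float(row["frame_sx_mm"]), float(row["frame_sy_mm"]), float(row["frame_sz_mm"])),
                )
            )
        except (ValueError, ManifestError) as exc:
            raise ManifestError(f"manifest {path}, row {idx + 2}: {exc}") from exc
    return records


# --------------------------------------------------------------------------
# landmarks sidecar
# --------------------------------------------------------------------------


def save_landmarks(landmarks, side: str, path: str | os.PathLike) -> None:
    payload = {
        "center_mm": list(map(float, landmarks.center_mm)),
        "tip_mm": list(map(float, landmarks.tip_mm)),
        "neck_point_mm": list(map(float, landmarks.neck_point_mm)),
        "side": side,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_landmarks(path: str | os.PathLike):
    from .phantom import StemLandmarks

    with open(path) as fh:
        payload = json.load(fh)
    lm = StemLandmarks(
        center_mm=tuple(payload["center_mm"]),
        tip_mm=tuple(payload["tip_mm"]),
        neck_point_mm=tuple(payload["neck_point_mm"]),
    )
    return lm, payload.get("side", "right")
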