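"""Grid-aware containers for CT images and congruent label maps.

A CT scan is held as a 3-D array of Hounsfield units (HU) together with the
geometric metadata needed to place every voxel in world space (millimetres):
per-axis spacing, the world position of voxel (0, 0, 0), and a 3x3
orthonormal direction matrix whose *columns* are the world directions of the
voxel axes.  Index order is (i, j, k) matching file-axis order; all indices
are 0-based.  World coordinates of voxel (i, j, k) are

    world = origin + direction @ (spacing * (i, j, k))

Label maps share the identical grid and carry small-integer codes for the
semantic classes used by the migration simulator (background, soft tissue,
femora, hips, stem, head).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_LABEL_CODES",
    "CTVolume",
    "LabelVolume",
    "check_congruent",
    "GridError",
]

#: Default semantic label codes.  The simulator only interprets SoftTissue
#: (fill donor) and Stem/Head (the implant); the rest exist so phantoms and
#: clinical segmentations share one vocabulary.
DEFAULT_LABEL_CODES: dict[str, int] = {
    "Background": 0,
    "SoftTissue": 1,
    "FemurLeft": 2,
    "FemurRight": 3,
    "HipLeft": 4,
    "HipRight": 5,
    "Stem": 6,
    "Head": 7,
}

_ORTHO_TOL = 1e-9


class GridError(ValueError):
    """Raised for invalid or mismatched volume grids."""


def _validate_grid(shape, spacing, origin, direction) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    direction = np.asarray(direction, dtype=float)
    if len(shape) != 3 or any(n < 1 for n in shape):
        raise GridError(f"voxel array must be 3-D with each axis >= 1, got shape {shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GridError(f"spacing must be strictly positive on all axes, got {spacing}")
    if direction.shape != (3, 3):
        raise GridError("direction must be a 3x3 matrix")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=_ORTHO_TOL):
        raise GridError("direction matrix is not orthonormal")
    return spacing, origin, direction


@dataclass(eq=False)
class CTVolume:
    """A 3-D CT image in Hounsfield units with its world-space grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GridError(f"expected a 3-D voxel array, got {self.voxels.ndim}-D")
        self.spacing, self.origin, self.direction = _validate_grid(
            self.voxels.shape, self.spacing, self.origin, self.direction
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, ijk) -> np.ndarray:
        """World coordinates (mm) of voxel centre(s) ``ijk`` (shape (..., 3))."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + (ijk * np.asarray(self.spacing)) @ self.direction.T

    def world_to_index(self, xyz) -> np.ndarray:
        """Continuous voxel index of world point(s) ``xyz``."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - np.asarray(self.origin)) @ self.direction) / np.asarray(self.spacing)

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing, self.origin, self.direction.copy())


@dataclass(eq=False)
class LabelVolume:
    """An integer segmentation congruent with a :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    label_codes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GridError(f"expected a 3-D label array, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GridError("label array must have an integer dtype")
        self.spacing, self.origin, self.direction = _validate_grid(
            self.labels.shape, self.spacing, self.origin, self.direction
        )
        self.label_codes = dict(self.label_codes)
        declared = set(self.label_codes.values())
        present = set(np.unique(self.labels).tolist())
        undeclared = present - declared
        if undeclared:
            raise GridError(f"label values {sorted(undeclared)} are not declared in label_codes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def code(self, name: str) -> int:
        return self.label_codes[name]

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels carrying any of the named labels."""
        codes = [self.label_codes[n] for n in names]
        return np.isin(self.labels, codes)

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.labels.copy(), self.spacing, self.origin, self.direction.copy(), dict(self.label_codes)
        )


def check_congruent(a, b, tol_mm: float = 1e-6) -> bool:
    """True iff two volumes share one grid: equal shapes and spacing/origin/
    direction agreeing within ``tol_mm``.  Symmetric pure predicate."""
    if a.shape != b.shape:
        return False
    if not np.allclose(a.spacing, b.spacing, rtol=0.0, atol=tol_mm):
        return False
    if not np.allclose(a.origin, b.origin, rtol=0.0, atol=tol_mm):
        return False
    return bool(np.allclose(a.direction, b.direction, rtol=0.0, atol=tol_mm))
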