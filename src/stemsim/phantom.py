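"""Synthetic hip phantom: a metal stem + head inside a femur-like bone shell.

The phantom emulates the structure a post-operative hip CT presents to the
migration simulator: a very-high-HU metal implant (tapered stem, neck, and
spherical head), embedded in high-HU cortical bone with a soft-tissue-filled
canal, all inside a soft-tissue ellipsoid surrounded by air.  Geometry is
analytic (frustum + cylinder + sphere) so voxel counts can be checked against
closed-form volumes, and every run is fully determined by the config seed.

World coordinates equal voxel index times spacing (identity direction).  For
a right-sided phantom the medial direction is +x and superior is +z; the stem
centerline is tilted ``stem_tilt_deg`` from the image z-axis in the x-z
plane, and the neck points 45 degrees medially-superior from the stem top.
Left-sided phantoms are exact mirror images across the sagittal mid-plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volume import CTVolume, LabelVolume, DEFAULT_LABEL_CODES

__all__ = [
    "PhantomConfig",
    "StemLandmarks",
    "PhantomConfigError",
    "generate_phantom",
    "add_streak_artifacts",
    "analytic_implant_volume_mm3",
    "COHORT_SPACINGS_MM",
]

#: Per-baseline voxel spacings (xct, yct, zct in mm) of the ten-scan study
#: cohort the simulator is designed around (two scanner vendors; in-plane
#: 0.72-0.86 mm, axial 0.45-0.6 mm).
COHORT_SPACINGS_MM: tuple[tuple[float, float, float], ...] = (
    (0.8594, 0.8594, 0.5),
    (0.7871, 0.7871, 0.5),
    (0.8203, 0.8203, 0.6),
    (0.7207, 0.7207, 0.5),
    (0.7871, 0.7871, 0.5),
    (0.7812, 0.7812, 0.45),
    (0.7812, 0.7812, 0.45),
    (0.7812, 0.7812, 0.45),
    (0.7812, 0.7812, 0.45),
    (0.7812, 0.7812, 0.45),
)


class PhantomConfigError(ValueError):
    """Phantom geometry cannot be realised in the requested grid."""


@dataclass(frozen=True)
class StemLandmarks:
    """World-mm landmarks of the implant: stem center, stem tip, head/neck point."""

    center_mm: tuple[float, float, float]
    tip_mm: tuple[float, float, float]
    neck_point_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.center_mm, float)
        t = np.asarray(self.tip_mm, float)
        n = np.asarray(self.neck_point_mm, float)
        axis = c - t
        if np.linalg.norm(axis) < 1e-9:
            raise PhantomConfigError("stem center and tip coincide")
        v = n - c
        if np.linalg.norm(v) < 1e-9:
            raise PhantomConfigError("neck point coincides with stem center")
        sin_angle = np.linalg.norm(np.cross(axis, v)) / (np.linalg.norm(axis) * np.linalg.norm(v))
        if sin_angle < math.sin(math.radians(1.0)):
            raise PhantomConfigError("neck point is collinear with the stem axis (within 1 degree)")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, HU levels and noise of a synthetic baseline hip CT.

    Defaults target a desk-scale 96 x 96 x 128 grid at the cohort's Philips
    spacing (0.7812, 0.7812, 0.45) mm; HU levels follow typical clinical
    ranges (air -1000, soft tissue 40, cortical bone 1200, metal 3000).
    """

    shape: tuple[int, int, int] = (96, 96, 128)
    spacing_mm: tuple[float, float, float] = (0.7812, 0.7812, 0.45)
    side: str = "right"
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 1200.0
    hu_metal: float = 3000.0
    stem_length_mm: float = 26.0
    stem_radius_mm: float = 5.0
    head_radius_mm: float = 4.5
    neck_length_mm: float = 7.0
    stem_tilt_deg: float = 10.0
    noise_sd_hu: float = 0.0
    artifact_streaks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_air < self.hu_soft < self.hu_bone < self.hu_metal):
            raise PhantomConfigError("HU levels must satisfy air < soft < bone < metal")
        if self.side not in ("left", "right"):
            raise PhantomConfigError(f"side must be 'left' or 'right', got {self.side!r}")
        if min(self.stem_length_mm, self.stem_radius_mm, self.head_radius_mm, self.neck_length_mm) <= 0:
            raise PhantomConfigError("stem geometry lengths must be positive")
        if self.noise_sd_hu < 0:
            raise PhantomConfigError("noise_sd_hu must be non-negative")


# margin (in voxels) the implant must keep from every face so the whole shift
# protocol (up to 5 voxels) stays in bounds after stem-frame resampling
_MARGIN_VOXELS = 6

_TIP_RADIUS_FRACTION = 0.45  # frustum taper: tip radius / top radius
_NECK_RADIUS_FRACTION = 0.45  # neck cylinder radius / stem top radius
_NECK_ANGLE_DEG = 45.0


def _implant_geometry(cfg: PhantomConfig):
    """Centerline endpoints and neck/head centres for a *right*-sided phantom."""
    extent = np.asarray(cfg.shape, float) * np.asarray(cfg.spacing_mm, float)
    centre = extent / 2.0
    tilt = math.radians(cfg.stem_tilt_deg)
    u = np.array([math.sin(tilt), 0.0, math.cos(tilt)])  # distal -> proximal
    medial = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])  # perpendicular, +x-ish
    top = centre + 0.5 * cfg.stem_length_mm * u
    tip = centre - 0.5 * cfg.stem_length_mm * u
    phi = math.radians(_NECK_ANGLE_DEG)
    neck_dir = math.cos(phi) * u + math.sin(phi) * medial
    head_centre = top + cfg.neck_length_mm * neck_dir
    return top, tip, head_centre, u


def analytic_implant_volume_mm3(cfg: PhantomConfig) -> float:
    """Closed-form stem + neck + head volume (mm^3), overlap-corrected.

    Frustum of the stem, the neck cylinder portion outside the head sphere,
    and the sphere.  The small wedge where the neck leaves the stem top is
    ignored (sub-percent for the default proportions).
    """
    r_top = cfg.stem_radius_mm
    r_tip = _TIP_RADIUS_FRACTION * r_top
    frustum = math.pi * cfg.stem_length_mm / 3.0 * (r_top**2 + r_top * r_tip + r_tip**2)
    sphere = 4.0 / 3.0 * math.pi * cfg.head_radius_mm**3
    r_neck = _NECK_RADIUS_FRACTION * r_top
    neck_outside = math.pi * r_neck**2 * max(cfg.neck_length_mm - cfg.head_radius_mm, 0.0)
    return frustum + sphere + neck_outside


def _world_grids(cfg: PhantomConfig):
    axes = [np.arange(n) * s for n, s in zip(cfg.shape, cfg.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _dist_point_to_segment(px, py, pz, a, b):
    """Distance from grid points to segment a-b and the axial parameter in [0,1]."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1] + (pz - a[2]) * ab[2]) / denom
    tc = np.clip(t, 0.0, 1.0)
    dx = px - (a[0] + tc * ab[0])
    dy = py - (a[1] + tc * ab[1])
    dz = pz - (a[2] + tc * ab[2])
    return np.sqrt(dx * dx + dy * dy + dz * dz), t


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, LabelVolume, StemLandmarks]:
    """Build the synthetic baseline CT, its label map and the stem landmarks.

    Raises :class:`PhantomConfigError` if the implant (plus the shift-protocol
    margin of six voxels) does not fit inside the grid.
    """
    cfg = config
    codes = dict(DEFAULT_LABEL_CODES)
    top, tip, head_centre, u = _implant_geometry(cfg)

    px, py, pz = _world_grids(cfg)

    # --- implant solids -----------------------------------------------------
    r_top = cfg.stem_radius_mm
    r_tip = _TIP_RADIUS_FRACTION * r_top
    d_axis, t_axis = _dist_point_to_segment(px, py, pz, tip, top)
    radius_at = r_tip + (r_top - r_tip) * np.clip(t_axis, 0.0, 1.0)
    stem_mask = (t_axis >= 0.0) & (t_axis <= 1.0) & (d_axis <= radius_at)

    r_neck = _NECK_RADIUS_FRACTION * r_top
    d_neck, t_neck = _dist_point_to_segment(px, py, pz, top, head_centre)
    neck_mask = (t_neck >= 0.0) & (t_neck <= 1.0) & (d_neck <= r_neck)

    d_head = np.sqrt((px - head_centre[0]) ** 2 + (py - head_centre[1]) ** 2 + (pz - head_centre[2]) ** 2)
    head_mask = d_head <= cfg.head_radius_mm

    stem_label_mask = (stem_mask | neck_mask) & ~head_mask
    implant_mask = stem_label_mask | head_mask

    # --- margin invariant ---------------------------------------------------
    idx = np.argwhere(implant_mask)
    if idx.size == 0:
        raise PhantomConfigError("implant voxelization is empty; grid too coarse for the geometry")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    for ax in range(3):
        if lo[ax] < _MARGIN_VOXELS or hi[ax] > cfg.shape[ax] - 1 - _MARGIN_VOXELS:
            raise PhantomConfigError(
                f"implant violates the {_MARGIN_VOXELS}-voxel margin on axis {ax} "
                f"(bounds {lo[ax]}..{hi[ax]} in a {cfg.shape[ax]}-voxel axis)"
            )

    # --- bone shell (cortical cylinder with a soft canal around the stem) ---
    bone_a = tip - 10.0 * u
    bone_b = top
    d_bone, t_bone = _dist_point_to_segment(px, py, pz, bone_a, bone_b)
    canal_r = r_top + 2.0
    outer_r = r_top + 6.0
    bone_mask = (t_bone >= 0.0) & (t_bone <= 1.0) & (d_bone > canal_r) & (d_bone <= outer_r) & ~implant_mask

    # --- soft-tissue ellipsoid ---------------------------------------------
    extent = np.asarray(cfg.shape, float) * np.asarray(cfg.spacing_mm, float)
    centre = extent / 2.0
    semi = 0.46 * extent
    ell = ((px - centre[0]) / semi[0]) ** 2 + ((py - centre[1]) / semi[1]) ** 2 + ((pz - centre[2]) / semi[2]) ** 2
    soft_mask = (ell <= 1.0) & ~bone_mask & ~implant_mask

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[soft_mask] = codes["SoftTissue"]
    femur = codes["FemurRight"] if cfg.side == "right" else codes["FemurLeft"]
    labels[bone_mask] = femur
    labels[stem_label_mask] = codes["Stem"]
    labels[head_mask] = codes["Head"]

    image = np.full(cfg.shape, cfg.hu_air, dtype=np.float32)
    image[soft_mask] = cfg.hu_soft
    image[bone_mask] = cfg.hu_bone
    image[implant_mask] = cfg.hu_metal

    # landmarks: pulled slightly inside their solids so they sit on labeled voxels
    inset = 2.0 * min(cfg.spacing_mm)
    lm_center = top - inset * u
    lm_tip = tip + inset * u
    landmarks = StemLandmarks(tuple(lm_center), tuple(lm_tip), tuple(head_centre))

    # left phantoms are sagittal mirrors of the right-sided construction
    if cfg.side == "left":
        image = image[::-1, :, :].copy()
        labels = labels[::-1, :, :].copy()
        mirror_x = (cfg.shape[0] - 1) * cfg.spacing_mm[0]

        def _m(p):
            return (mirror_x - p[0], p[1], p[2])

        landmarks = StemLandmarks(_m(lm_center), _m(lm_tip), _m(head_centre))

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd_hu > 0:
        image = image + rng.normal(0.0, cfg.noise_sd_hu, size=cfg.shape).astype(np.float32)

    ct = CTVolume(image, cfg.spacing_mm)
    lab = LabelVolume(labels, cfg.spacing_mm, label_codes=codes)

    if cfg.artifact_streaks:
        ct = add_streak_artifacts(ct, lab, amplitude_hu=150.0, n_streaks=8, seed=cfg.seed)

    return ct, lab, landmarks


def add_streak_artifacts(
    vol: CTVolume,
    lab: LabelVolume,
    amplitude_hu: float,
    n_streaks: int,
    seed: int,
) -> CTVolume:
    """Cosmetic metal-artifact emulation: radial alternating high/low-HU rays
    from the implant centroid.  Implant voxels are never modified; output is
    deterministic for a fixed seed."""
    if amplitude_hu < 0:
        raise ValueError("amplitude_hu must be >= 0")
    out = vol.copy()
    if amplitude_hu == 0 or n_streaks <= 0:
        return out
    implant = lab.mask("Stem", "Head")
    if not implant.any():
        return out
    rng = np.random.default_rng(seed)
    centroid = np.argwhere(implant).mean(axis=0)
    shape = np.asarray(vol.shape)
    max_len = int(np.linalg.norm(shape))
    spacing = np.asarray(vol.spacing)
    for k in range(n_streaks):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        sign = 1.0 if k % 2 == 0 else -1.0
        steps = np.arange(1, max_len)
        pts = np.rint(centroid[None, :] + steps[:, None] * d[None, :] * spacing.min() / spacing).astype(int)
        inside = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inside]
        if pts.size == 0:
            continue
        falloff = np.exp(-steps[inside] / (0.5 * max_len))
        sel = ~implant[pts[:, 0], pts[:, 1], pts[:, 2]]
        p = pts[sel]
        out.voxels[p[:, 0], p[:, 1], p[:, 2]] += (sign * amplitude_hu * falloff[sel]).astype(out.voxels.dtype)
    return out


def cohort_configs(
    n_baselines: int = 10,
    base: PhantomConfig | None = None,
    seed: int = 0,
) -> list[PhantomConfig]:
    """Configs for a simulated study cohort: one phantom per baseline with the
    cohort voxel spacings, alternating sides, distinct noise seeds."""
    base = base if base is not None else PhantomConfig()
    out = []
    for i in range(n_baselines):
        spacing = COHORT_SPACINGS_MM[i % len(COHORT_SPACINGS_MM)]
        side = "right" if i % 2 == 0 else "left"
        out.append(replace(base, spacing_mm=spacing, side=side, seed=seed + i))
    return out
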