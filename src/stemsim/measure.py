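"""Transparent migration measurement used to exercise the evaluation layer.

This is a deliberately simple, fully open method (HU-threshold segmentation
of the metal implant followed by either an HU-weighted centroid difference or
a normalised cross-correlation search).  It reports stem-frame translations
under the study sign convention (positive = medial / superior / anterior, as
if all hips were right-sided).  It does not measure rotation: a threshold +
centroid approach cannot credibly estimate the rotation of a near-symmetric
metal solid, so rotational differences are accepted by the evaluation layer
as externally supplied inputs instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frame import StemFrame
from .volume import CTVolume, check_congruent

__all__ = [
    "MeasurementConfig",
    "MeasuredMigration",
    "NoImplantError",
    "segment_metal",
    "measure_translation",
]


class NoImplantError(ValueError):
    """No voxels above the metal threshold."""


@dataclass(frozen=True)
class MeasurementConfig:
    hu_threshold: float = 2500.0
    method: str = "centroid"
    xcorr_search_mm: float = 4.0
    subvoxel: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("centroid", "xcorr"):
            raise ValueError("method must be 'centroid' or 'xcorr'")
        if self.xcorr_search_mm <= 0:
            raise ValueError("xcorr_search_mm must be positive")


@dataclass(frozen=True)
class MeasuredMigration:
    """Stem-frame translation in mm (positive medial/superior/anterior)."""

    translation_mm: tuple[float, float, float]
    method_tag: str

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.translation_mm)):
            raise ValueError("translation components must be finite")


def segment_metal(ct: CTVolume, cfg: MeasurementConfig = MeasurementConfig()) -> np.ndarray:
    """Mask of the largest 26-connected component with HU >= threshold."""
    raw = ct.voxels >= cfg.hu_threshold
    if not raw.any():
        raise NoImplantError(f"no voxels at or above {cfg.hu_threshold} HU")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(raw, structure=structure)
    if n == 1:
        return raw
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == int(np.argmax(counts))


def _world_centroid(ct: CTVolume, mask: np.ndarray) -> np.ndarray:
    """HU-weighted centroid of the masked voxels, in world mm."""
    idx = np.argwhere(mask).astype(float)
    w = ct.voxels[mask].astype(float)
    w = w - w.min() + 1.0  # keep weights positive
    centroid_ijk = (idx * w[:, None]).sum(axis=0) / w.sum()
    return ct.index_to_world(centroid_ijk)


def _to_stem_frame(delta_world: np.ndarray, frame: StemFrame) -> tuple[float, float, float]:
    t = frame.rotation.T @ delta_world
    if frame.side == "left":
        t = np.array([-t[0], t[1], t[2]])  # as-if-right-sided reporting
    return tuple(float(v) for v in t)


def _xcorr_translation(baseline: CTVolume, followup: CTVolume, mask: np.ndarray, cfg: MeasurementConfig) -> np.ndarray:
    """Integer (optionally parabolic-refined) voxel translation maximising the
    normalised cross-correlation of the metal neighbourhood."""
    spacing = np.asarray(baseline.spacing)
    radius = np.maximum(1, np.ceil(cfg.xcorr_search_mm / spacing).astype(int))

    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - radius - 1, 0)
    hi = np.minimum(idx.max(axis=0) + radius + 2, np.asarray(baseline.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    a = baseline.voxels[sl].astype(np.float64)
    a = a - a.mean()
    na = np.sqrt((a * a).sum())

    shape = np.asarray(followup.shape)
    scores = np.full(tuple(2 * radius + 1), -np.inf)
    for oi in range(-radius[0], radius[0] + 1):
        for oj in range(-radius[1], radius[1] + 1):
            for ok in range(-radius[2], radius[2] + 1):
                off = np.array([oi, oj, ok])
                src_lo = lo + off
                src_hi = hi + off
                if (src_lo < 0).any() or (src_hi > shape).any():
                    continue
                b = followup.voxels[tuple(slice(int(p), int(q)) for p, q in zip(src_lo, src_hi))].astype(np.float64)
                b = b - b.mean()
                nb = np.sqrt((b * b).sum())
                if na == 0 or nb == 0:
                    continue
                scores[oi + radius[0], oj + radius[1], ok + radius[2]] = (a * b).sum() / (na * nb)

    peak = np.unravel_index(int(np.argmax(scores)), scores.shape)
    t = np.asarray(peak, float) - radius
    if cfg.subvoxel:
        for ax in range(3):
            p = list(peak)
            if 0 < peak[ax] < scores.shape[ax] - 1:
                p[ax] = peak[ax] - 1
                s_m = scores[tuple(p)]
                p[ax] = peak[ax] + 1
                s_p = scores[tuple(p)]
                s_0 = scores[peak]
                denom = s_m - 2.0 * s_0 + s_p
                if np.isfinite(s_m) and np.isfinite(s_p) and denom < 0:
                    t[ax] += 0.5 * (s_m - s_p) / denom
    return t


def measure_translation(
    baseline: CTVolume,
    followup: CTVolume,
    frame: StemFrame,
    cfg: MeasurementConfig = MeasurementConfig(),
) -> MeasuredMigration:
    """Estimate the implant translation between two congruent CT volumes.

    centroid: difference of the HU-weighted metal centroids, expressed in the
    stem frame.  xcorr: the translation maximising normalised
    cross-correlation of the metal neighbourhood, optionally refined to
    sub-voxel precision by parabolic peak interpolation.
    """
    if not check_congruent(baseline, followup):
        raise ValueError("baseline and follow-up volumes are not on congruent grids")
    if cfg.method == "centroid":
        c0 = _world_centroid(baseline, segment_metal(baseline, cfg))
        c1 = _world_centroid(followup, segment_metal(followup, cfg))
        delta_world = c1 - c0
    else:
        mask = segment_metal(baseline, cfg)
        t_vox = _xcorr_translation(baseline, followup, mask, cfg)
        delta_world = baseline.direction @ (t_vox * np.asarray(baseline.spacing))
    return MeasuredMigration(_to_stem_frame(delta_world, frame), method_tag=cfg.method)
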