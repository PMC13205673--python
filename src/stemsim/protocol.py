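"""Enumeration of the one-axis and two-axis shift protocol.

Per baseline the design is: one-voxel steps of -4..+4 along x and z and
-5..+5 along y (29 one-axis shifts including the three per-family zeros),
plus paired moves on each axis pair (a, b) with a in +-1..4 and b = +-a (16
per pair, 48 total) and a single dedicated zero example (49 two-axis shifts)
-- 78 follow-ups per baseline, 780 for a ten-baseline cohort.

Precision under zero migration is pooled per axis from the one-axis families:
for axis q, every follow-up generated along the *other* two axes has zero
true migration on q, so the pools have sizes 20 (x), 18 (y) and 20 (z) per
baseline over 29 distinct follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ManifestRecord
from .migration import ShiftSpec

__all__ = [
    "ProtocolConfig",
    "one_axis_shifts",
    "two_axis_shifts",
    "full_protocol",
    "zero_migration_pool",
]

_AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ProtocolConfig:
    max_xz: int = 4
    max_y: int = 5
    two_axis_max: int = 4
    axis_pairs: tuple[tuple[str, str], ...] = (("x", "y"), ("x", "z"), ("y", "z"))
    include_zero_per_axis: bool = True
    include_two_axis_zero: bool = True

    def __post_init__(self) -> None:
        if min(self.max_xz, self.max_y, self.two_axis_max) < 1:
            raise ValueError("all protocol maxima must be >= 1")
        for a, b in self.axis_pairs:
            if a not in _AXES or b not in _AXES or a == b:
                raise ValueError(f"invalid axis pair ({a}, {b})")


def _spec(values: dict[str, int], axes) -> ShiftSpec:
    return ShiftSpec(values.get("x", 0), values.get("y", 0), values.get("z", 0), frozenset(axes))


def one_axis_shifts(cfg: ProtocolConfig = ProtocolConfig()) -> list[ShiftSpec]:
    """All single-axis steps, tagged by generating axis; default 9+11+9 = 29."""
    out: list[ShiftSpec] = []
    for axis in _AXES:
        maximum = cfg.max_y if axis == "y" else cfg.max_xz
        for step in range(-maximum, maximum + 1):
            if step == 0 and not cfg.include_zero_per_axis:
                continue
            out.append(_spec({axis: step}, {axis}))
    return out


def two_axis_shifts(cfg: ProtocolConfig = ProtocolConfig()) -> list[ShiftSpec]:
    """Paired moves b = +-a per axis pair, plus the single zero example;
    default 16 x 3 + 1 = 49."""
    out: list[ShiftSpec] = []
    for a_axis, b_axis in cfg.axis_pairs:
        for a_val in range(-cfg.two_axis_max, cfg.two_axis_max + 1):
            if a_val == 0:
                continue
            for b_val in (a_val, -a_val):
                out.append(_spec({a_axis: a_val, b_axis: b_val}, {a_axis, b_axis}))
    if cfg.include_two_axis_zero:
        out.append(_spec({}, frozenset()))
    return out


def full_protocol(cfg: ProtocolConfig = ProtocolConfig()) -> list[ShiftSpec]:
    """One-axis followed by two-axis shifts; default 29 + 49 = 78."""
    return one_axis_shifts(cfg) + two_axis_shifts(cfg)


def zero_migration_pool(manifest: list[ManifestRecord]) -> dict[str, list[ManifestRecord]]:
    """Per-axis pools of zero-true-migration records for precision analysis.

    Input must come from the one-axis families only.  For axis q the pool
    holds the records generated along the other two axes (zero-shift records
    of a family count toward the other two axes, matching the study pooling).
    """
    for rec in manifest:
        if len(rec.generating_axes) != 1:
            raise ValueError(
                f"zero-migration pooling expects one-axis records only; got generating_axes="
                f"{sorted(rec.generating_axes)} for {rec.followup_id}"
            )
    pools: dict[str, list[ManifestRecord]] = {axis: [] for axis in _AXES}
    for rec in manifest:
        (family_axis,) = rec.generating_axes
        for axis in _AXES:
            if axis == family_axis:
                continue
            if rec.shift_voxels[_AXIS_INDEX[axis]] != 0:
                raise ValueError(
                    f"record {rec.followup_id} has nonzero shift on axis {axis} outside its family"
                )
            pools[axis].append(rec)
    return pools
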