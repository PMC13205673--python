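"""Accuracy and precision statistics for migration measurements.

All statistics operate on per-axis differences diff = truth - measured (mm
for translations, degrees for rotations).  Accuracy is summarised as
mean/SD/min/max of the differences; precision under zero true migration is
1.96 x SD of the pooled differences (the 95% interval half-width); agreement
is summarised with Bland-Altman limits mean +- 1.96 x SD, with the true
migration on the abscissa; normality of the differences is assessed with Q-Q
data against a fitted normal.  SD uses the sample (n-1) denominator
throughout.  Display rounding is three decimals; internal values are never
rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ManifestRecord

__all__ = [
    "DifferenceRecord",
    "SummaryStats",
    "PrecisionResult",
    "BlandAltmanResult",
    "summarize",
    "precision_zero",
    "bland_altman",
    "qq_data",
    "build_difference_frame",
    "report_tables",
]

_AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class DifferenceRecord:
    """Per-axis (truth - measured) difference for one follow-up."""

    followup_id: str
    axis: str
    truth_mm: float
    measured_mm: float
    generating_axes: frozenset[str] = frozenset()
    quantity: str = "translation"

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")
        if self.quantity not in ("translation", "rotation_deg"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def diff_mm(self) -> float:
        return self.truth_mm - self.measured_mm


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    single_sample: bool = False  # SD undefined for n == 1; reported as 0, flagged


@dataclass(frozen=True)
class PrecisionResult:
    n: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def precision(self) -> float:
        """1.96 x SD: half-width of the 95% interval under zero migration."""
        return 1.96 * self.sd


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    abscissa: np.ndarray  # true migration (plot x-axis)
    diffs: np.ndarray  # truth - measured (plot y-axis)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def summarize(diffs) -> SummaryStats:
    """Mean/SD/min/max of a nonempty difference selection."""
    values = np.asarray(diffs, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty selection")
    return SummaryStats(
        n=int(values.size),
        mean=float(values.mean()),
        sd=_sd(values),
        min=float(values.min()),
        max=float(values.max()),
        single_sample=values.size == 1,
    )


def precision_zero(diffs, truths=None) -> PrecisionResult:
    """Precision (1.96 x SD) over a zero-true-migration pool.

    If ``truths`` is given, any nonzero truth in the pool is a contract
    violation and raises.
    """
    values = np.asarray(diffs, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute precision of an empty pool")
    if truths is not None:
        truths = np.asarray(truths, dtype=float)
        if truths.shape != values.shape:
            raise ValueError("diffs and truths must have equal length")
        if np.any(truths != 0.0):
            raise ValueError("zero-migration pool contains records with nonzero truth")
    return PrecisionResult(
        n=int(values.size),
        mean=float(values.mean()),
        sd=_sd(values),
        min=float(values.min()),
        max=float(values.max()),
    )


def bland_altman(truth, measured) -> BlandAltmanResult:
    """Bland-Altman agreement of measured against ground truth.

    Differences are truth - measured; limits of agreement are
    mean +- 1.96 x SD.  The 95% CI of the mean uses SD/sqrt(n); the CI of
    each limit uses the standard Bland-Altman standard error SD*sqrt(3/n).
    The abscissa is the true migration.
    """
    truth = np.asarray(truth, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if truth.shape != measured.shape:
        raise ValueError("truth and measured must have equal length")
    n = truth.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diffs = truth - measured
    mean = float(diffs.mean())
    sd = _sd(diffs)
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=int(n),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_mean=(float(mean - 1.96 * se_mean), float(mean + 1.96 * se_mean)),
        ci_loa_low=(float(loa_low - 1.96 * se_loa), float(loa_low + 1.96 * se_loa)),
        ci_loa_high=(float(loa_high - 1.96 * se_loa), float(loa_high + 1.96 * se_loa)),
        abscissa=truth.copy(),
        diffs=diffs,
    )


def qq_data(diffs) -> tuple[np.ndarray, np.ndarray]:
    """Q-Q pairs: theoretical normal quantiles (fitted mean/SD, probability
    points (i - 0.5)/n) against the ordered sample."""
    values = np.sort(np.asarray(diffs, dtype=float))
    n = values.size
    if n < 3:
        raise ValueError("Q-Q data needs at least three values")
    p = (np.arange(1, n + 1) - 0.5) / n
    sd = _sd(values)
    theoretical = values.mean() + sd * stats.norm.ppf(p)
    return theoretical, values


# --------------------------------------------------------------------------
# joined difference table and report tables
# --------------------------------------------------------------------------


def build_difference_frame(manifest: list[ManifestRecord], measured: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-axis difference table joining the manifest to measured
    translations.

    ``measured`` needs columns followup_id, mx_mm, my_mm, mz_mm.  Raises on
    follow-ups present on one side only, listing them.
    """
    man_ids = [r.followup_id for r in manifest]
    if len(set(man_ids)) != len(man_ids):
        raise ValueError("manifest contains duplicate followup_ids")
    meas_ids = set(measured["followup_id"].astype(str))
    missing = sorted(set(man_ids) - meas_ids)
    extra = sorted(meas_ids - set(man_ids))
    if missing or extra:
        raise ValueError(
            f"manifest/measured join failure: unmatched manifest ids {missing[:10]}, "
            f"unmatched measured ids {extra[:10]}"
        )
    meas = measured.astype({"followup_id": str}).set_index("followup_id")
    rows = []
    for rec in manifest:
        m = meas.loc[rec.followup_id]
        n_one = len(rec.generating_axes)
        family = next(iter(rec.generating_axes)) if n_one == 1 else "two_axis"
        for axis in _AXES:
            truth = rec.truth_mm[_AXIS_INDEX[axis]]
            measured_mm = float(m[f"m{axis}_mm"])
            rows.append(
                {
                    "followup_id": rec.followup_id,
                    "baseline_id": rec.baseline_id,
                    "axis": axis,
                    "family": family,
                    "generating_axes": "".join(sorted(rec.generating_axes)),
                    "truth_mm": truth,
                    "measured_mm": measured_mm,
                    "diff_mm": truth - measured_mm,
                }
            )
    return pd.DataFrame(rows)


def _axis_summary_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for axis in _AXES:
        s = summarize(df.loc[df["axis"] == axis, "diff_mm"].to_numpy())
        rows.append({"axis": axis, "n": s.n, "mean": s.mean, "sd": s.sd, "min": s.min, "max": s.max})
    return pd.DataFrame(rows)


def round_for_display(df: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def report_tables(
    manifest: list[ManifestRecord],
    measured: pd.DataFrame,
    rotation_diffs: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """The full report set: per-family accuracy, combined accuracy,
    zero-migration precision (with per-axis pool sizes), and optionally
    zero-rotation precision from externally supplied rotation differences
    (columns followup_id, rx_deg, ry_deg, rz_deg: measured - true rotation,
    degrees)."""
    df = build_difference_frame(manifest, measured)
    tables: dict[str, pd.DataFrame] = {}
    for axis in _AXES:
        sel = df[df["family"] == axis]
        if len(sel):
            tables[f"accuracy_one_axis_{axis}"] = _axis_summary_table(sel)
    two = df[df["family"] == "two_axis"]
    if len(two):
        tables["accuracy_two_axis"] = _axis_summary_table(two)
    tables["accuracy_all"] = _axis_summary_table(df)

    one_axis = df[df["family"] != "two_axis"]
    rows = []
    for axis in _AXES:
        pool = one_axis[(one_axis["axis"] == axis) & (one_axis["family"] != axis)]
        p = precision_zero(pool["diff_mm"].to_numpy(), pool["truth_mm"].to_numpy())
        rows.append(
            {"axis": axis, "n": p.n, "mean": p.mean, "sd": p.sd, "min": p.min, "max": p.max, "precision": p.precision}
        )
    tables["precision_zero_migration"] = pd.DataFrame(rows)

    if rotation_diffs is not None:
        rows = []
        for axis in _AXES:
            values = rotation_diffs[f"r{axis}_deg"].to_numpy(dtype=float)
            p = precision_zero(values)
            rows.append(
                {"axis": axis, "n": p.n, "mean": p.mean, "sd": p.sd, "min": p.min, "max": p.max, "precision": p.precision}
            )
        tables["precision_zero_rotation"] = pd.DataFrame(rows)
    return tables
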