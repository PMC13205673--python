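"""Accuracy/precision statistics, Bland-Altman agreement and Q-Q data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stemsim import (
    ManifestRecord,
    bland_altman,
    build_difference_frame,
    one_axis_shifts,
    precision_zero,
    qq_data,
    report_tables,
    summarize,
    two_axis_shifts,
)
from stemsim.evaluate import round_for_display


class TestSummarize:
    def test_all_zero_differences(self):
        s = summarize([0.0, 0.0, 0.0])
        assert (s.mean, s.sd, s.min, s.max) == (0.0, 0.0, 0.0, 0.0)

    def test_two_point_sample_sd_uses_n_minus_1(self):
        s = summarize([-0.1, 0.1])
        assert s.mean == 0.0
        assert s.sd == pytest.approx(0.1 * np.sqrt(2), abs=1e-12)  # 0.1414...
        assert (s.min, s.max) == (-0.1, 0.1)

    def test_single_record_flagged(self):
        s = summarize([0.3])
        assert s.n == 1 and s.sd == 0.0 and s.single_sample

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])

    def test_union_of_disjoint_subsets_adds_counts(self):
        a = np.array([0.1, -0.2, 0.05])
        b = np.array([0.0, 0.3])
        assert summarize(np.concatenate([a, b])).n == summarize(a).n + summarize(b).n


class TestPrecisionZero:
    def test_reported_precision_cells_from_sd(self):
        """1.96 x SD at three-decimal display for the study's zero-migration
        and zero-rotation pools."""
        from stemsim.evaluate import PrecisionResult

        cells = [
            (0.024, 180, 0.047),
            (0.025, 200, 0.049),
            (0.073, 780, 0.143),
        ]
        for sd, n, expected in cells:
            p = PrecisionResult(n=n, mean=0.0, sd=sd, min=0.0, max=0.0)
            assert round(p.precision, 3) == expected

    def test_all_zero_differences_give_zero_precision(self):
        assert precision_zero(np.zeros(20)).precision == 0.0

    def test_nonzero_truth_in_pool_rejected(self):
        with pytest.raises(ValueError, match="nonzero truth"):
            precision_zero([0.1, -0.1], truths=[0.0, 0.45])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(0, 0.05, size=30)
        base = precision_zero(diffs).precision
        scaled = precision_zero(scale * diffs).precision
        assert scaled == pytest.approx(abs(scale) * base, rel=1e-9, abs=1e-12)


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = bland_altman([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert ba.mean_diff == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset_collapses_loa(self):
        truth = np.linspace(-2, 2, 10)
        ba = bland_altman(truth, truth - 0.05)
        assert ba.mean_diff == pytest.approx(0.05)
        assert ba.loa_low == pytest.approx(0.05)
        assert ba.loa_high == pytest.approx(0.05)

    def test_two_level_differences_give_expected_loa(self):
        # differences alternate +-0.05, 50 repeats each: sd = 0.0505 (n-1)
        truth = np.zeros(100)
        measured = np.tile([-0.05, 0.05], 50)
        ba = bland_altman(truth, measured)
        sd = np.std(truth - measured, ddof=1)
        assert ba.loa_high == pytest.approx(1.96 * sd)
        assert ba.loa_high == pytest.approx(0.099, abs=1e-3)
        assert ba.loa_low == pytest.approx(-ba.loa_high)

    def test_antisymmetric_under_swapping(self):
        rng = np.random.default_rng(2)
        t = rng.normal(0, 1, 40)
        m = t + rng.normal(0, 0.05, 40)
        ab = bland_altman(t, m)
        ba = bland_altman(m, t)
        assert ba.mean_diff == pytest.approx(-ab.mean_diff)
        assert ba.loa_low == pytest.approx(-ab.loa_high)
        assert ba.loa_high == pytest.approx(-ab.loa_low)

    def test_ci_widths(self):
        rng = np.random.default_rng(4)
        t = np.zeros(100)
        m = rng.normal(0, 0.03, 100)
        ba = bland_altman(t, m)
        sd = np.std(t - m, ddof=1)
        assert ba.ci_mean[1] - ba.ci_mean[0] == pytest.approx(2 * 1.96 * sd / 10)
        assert ba.ci_loa_low[1] - ba.ci_loa_low[0] == pytest.approx(2 * 1.96 * sd * np.sqrt(3 / 100))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            bland_altman([0.1, 0.2], [0.1])

    def test_abscissa_is_truth(self):
        truth = np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(truth, truth * 0.9)
        np.testing.assert_array_equal(ba.abscissa, truth)


class TestQQ:
    def test_symmetric_sample_gives_symmetric_quantiles(self):
        theo, sample = qq_data([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(theo + theo[::-1], 0.0, atol=1e-12)
        np.testing.assert_array_equal(sample, [-1.0, 0.0, 1.0])

    def test_normal_sample_correlates_on_the_line(self):
        rng = np.random.default_rng(9)
        theo, sample = qq_data(rng.normal(0, 0.03, 500))
        assert np.corrcoef(theo, sample)[0, 1] > 0.99

    def test_constant_sample_degenerates_to_zero_sd(self):
        theo, sample = qq_data([0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(theo, 0.2)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="three"):
            qq_data([0.0, 0.1])


def _synthetic_run(n_baselines=2, noise=0.0, seed=0):
    """Manifest + perfect (optionally noisy) measurements for protocol shifts."""
    from stemsim import full_protocol

    rng = np.random.default_rng(seed)
    manifest, rows = [], []
    for b in range(n_baselines):
        spacing = (0.7812, 0.45, 0.7812)
        for i, s in enumerate(full_protocol()):
            rec = ManifestRecord.from_shift(f"p{b}", f"p{b}_fu{i:03d}", s.generating_axes, s.voxels, spacing)
            manifest.append(rec)
            rows.append(
                {
                    "followup_id": rec.followup_id,
                    "mx_mm": rec.truth_mm[0] + rng.normal(0, noise),
                    "my_mm": rec.truth_mm[1] + rng.normal(0, noise),
                    "mz_mm": rec.truth_mm[2] + rng.normal(0, noise),
                }
            )
    return manifest, pd.DataFrame(rows)


class TestReportTables:
    def test_pool_sizes_in_precision_table(self):
        manifest, measured = _synthetic_run(n_baselines=10)
        tables = report_tables(manifest, measured)
        prec = tables["precision_zero_migration"].set_index("axis")
        assert prec.loc["x", "n"] == 200
        assert prec.loc["y", "n"] == 180
        assert prec.loc["z", "n"] == 200

    def test_family_table_counts(self):
        manifest, measured = _synthetic_run(n_baselines=10)
        tables = report_tables(manifest, measured)
        assert set(tables["accuracy_one_axis_x"]["n"]) == {90}
        assert set(tables["accuracy_one_axis_y"]["n"]) == {110}
        assert set(tables["accuracy_two_axis"]["n"]) == {490}
        assert set(tables["accuracy_all"]["n"]) == {780}

    def test_perfect_measurements_give_zero_differences(self):
        manifest, measured = _synthetic_run(n_baselines=1)
        tables = report_tables(manifest, measured)
        assert np.allclose(tables["accuracy_all"][["mean", "sd", "min", "max"]], 0.0)

    def test_rotation_table_from_supplied_differences(self):
        manifest, measured = _synthetic_run(n_baselines=1)
        rng = np.random.default_rng(1)
        rot = pd.DataFrame(
            {
                "followup_id": [r.followup_id for r in manifest],
                "rx_deg": rng.normal(0, 0.042, len(manifest)),
                "ry_deg": rng.normal(0, 0.073, len(manifest)),
                "rz_deg": rng.normal(0, 0.017, len(manifest)),
            }
        )
        tables = report_tables(manifest, measured, rot)
        prec = tables["precision_zero_rotation"].set_index("axis")
        assert prec.loc["y", "precision"] == pytest.approx(1.96 * rot["ry_deg"].std(ddof=1))

    def test_unmatched_ids_raise_with_listing(self):
        manifest, measured = _synthetic_run(n_baselines=1)
        with pytest.raises(ValueError, match="p0_fu000"):
            report_tables(manifest, measured.iloc[1:])

    def test_display_rounding_three_decimals(self):
        df = pd.DataFrame({"axis": ["x"], "mean": [0.0471234]})
        assert round_for_display(df)["mean"].iloc[0] == 0.047


def test_difference_frame_sign_convention():
    """diff = ground truth - measurement on every axis."""
    manifest, measured = _synthetic_run(n_baselines=1)
    measured = measured.copy()
    measured["my_mm"] += 0.02
    df = build_difference_frame(manifest, measured)
    y = df[df["axis"] == "y"]
    np.testing.assert_allclose(y["diff_mm"], y["truth_mm"] - y["measured_mm"], atol=1e-12)
    assert np.allclose(y["diff_mm"], -0.02)
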