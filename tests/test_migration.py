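"""Implant shifting, hole filling and follow-up generation."""

import numpy as np
import pytest

from stemsim import (
    CTVolume,
    FillConfig,
    LabelVolume,
    ResampleSpec,
    ShiftSpec,
    apply_shift,
    fill_vacated,
    full_protocol,
    generate_followup,
    resample_to_frame,
)
from stemsim.migration import ShiftOutOfBoundsError


def test_shift_spec_protocol_bounds():
    ShiftSpec(4, 5, 4)
    with pytest.raises(ValueError, match=r"\|dx\|"):
        ShiftSpec(5, 0, 0)
    with pytest.raises(ValueError, match=r"\|dy\|"):
        ShiftSpec(0, 6, 0)


def _frame_volumes(small_phantom, small_frame):
    ct, lab, _ = small_phantom
    ct_f, _ = resample_to_frame(ct, small_frame, ResampleSpec(interpolation="nearest"))
    lab_f, _ = resample_to_frame(lab, small_frame)
    return ct_f, lab_f


class TestApplyShift:
    def test_zero_shift_is_identity(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        ct_s, lab_s, vacated, overlap = apply_shift(ct_f, lab_f, ("Stem", "Head"), (0, 0, 0))
        np.testing.assert_array_equal(ct_s.voxels, ct_f.voxels)
        np.testing.assert_array_equal(lab_s.labels, lab_f.labels)
        assert not vacated.any()
        assert overlap == 0.0

    def test_centroid_moves_exactly_one_voxel(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        _, lab_s, _, _ = apply_shift(ct_f, lab_f, ("Stem", "Head"), (0, 1, 0))
        c0 = np.argwhere(lab_f.mask("Stem", "Head")).mean(axis=0)
        c1 = np.argwhere(lab_s.mask("Stem", "Head")).mean(axis=0)
        np.testing.assert_allclose(c1 - c0, [0, 1, 0], atol=1e-12)

    def test_implant_count_conserved_across_full_protocol(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        n0 = int(lab_f.mask("Stem", "Head").sum())
        for shift in full_protocol():
            _, lab_s, _, _ = apply_shift(ct_f, lab_f, ("Stem", "Head"), shift)
            assert int(lab_s.mask("Stem", "Head").sum()) == n0

    def test_untouched_voxels_bit_identical(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        mask = lab_f.mask("Stem", "Head")
        d = (2, -1, 0)
        ct_s, _, vacated, _ = apply_shift(ct_f, lab_f, ("Stem", "Head"), d)
        dst = np.zeros_like(mask)
        src = np.argwhere(mask)
        dst[tuple((src + np.asarray(d)).T)] = True
        outside = ~(mask | dst | vacated)
        np.testing.assert_array_equal(ct_s.voxels[outside], ct_f.voxels[outside])

    def test_vacated_is_source_minus_destination(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        mask = lab_f.mask("Stem", "Head")
        _, _, vacated, _ = apply_shift(ct_f, lab_f, ("Stem", "Head"), (0, 3, 0))
        dst = np.zeros_like(mask)
        src = np.argwhere(mask)
        dst[tuple((src + np.array([0, 3, 0])).T)] = True
        np.testing.assert_array_equal(vacated, mask & ~dst)

    def test_out_of_bounds_shift_names_axis(self):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[4:7, 4:7, 7:10] = 6
        ct = CTVolume(np.where(lab > 0, 3000.0, 40.0), spacing=(1, 1, 1))
        labv = LabelVolume(lab, spacing=(1, 1, 1))
        with pytest.raises(ShiftOutOfBoundsError, match="axis z"):
            apply_shift(ct, labv, ("Stem",), (0, 0, 1))

    def test_overlap_fraction_reported(self):
        lab = np.zeros((12, 8, 8), dtype=np.int16)
        lab[2:6, 3:5, 3:5] = 6  # 4x2x2 stem block
        ct = CTVolume(np.where(lab > 0, 3000.0, 40.0), spacing=(1, 1, 1))
        labv = LabelVolume(lab, spacing=(1, 1, 1))
        _, _, _, overlap = apply_shift(ct, labv, ("Stem",), (1, 0, 0))
        # one slab of 2x2 destination voxels previously soft, of 16 implant voxels
        assert overlap == pytest.approx(4 / 16)

    def test_inverse_shift_restores_implant_mask(self, small_phantom, small_frame):
        ct_f, lab_f = _frame_volumes(small_phantom, small_frame)
        ct_s, lab_s, _, _ = apply_shift(ct_f, lab_f, ("Stem", "Head"), (2, 2, -1))
        _, lab_b, _, _ = apply_shift(ct_s, lab_s, ("Stem", "Head"), (-2, -2, 1))
        np.testing.assert_array_equal(lab_b.mask("Stem", "Head"), lab_f.mask("Stem", "Head"))


def _fill_oracle(ct, vacated, donors, spacing):
    """Brute-force nearest-donor assignment (mm-scaled Euclidean)."""
    out = ct.voxels.copy().astype(float)
    donor_idx = np.argwhere(donors).astype(float)
    donor_vals = ct.voxels[donors]
    s = np.asarray(spacing)
    for p in np.argwhere(vacated):
        d2 = (((donor_idx - p) * s) ** 2).sum(axis=1)
        out[tuple(p)] = donor_vals[int(np.argmin(d2))]
    return out


class TestFillVacated:
    def _small_case(self, seed=0, noisy=False):
        rng = np.random.default_rng(seed)
        shape = (32, 32, 32)
        lab = np.ones(shape, dtype=np.int16)  # all soft tissue
        lab[12:20, 12:20, 6:26] = 6  # stem block
        hu = np.where(lab == 6, 3000.0, 40.0)
        if noisy:
            hu = hu + rng.normal(0, 20, size=shape)
        ct = CTVolume(hu, spacing=(0.8, 0.8, 0.5))
        labv = LabelVolume(lab, spacing=(0.8, 0.8, 0.5))
        return ct, labv

    def test_empty_vacated_mask_is_identity(self):
        ct, lab = self._small_case()
        out = fill_vacated(ct, np.zeros(ct.shape, bool), lab)
        np.testing.assert_array_equal(out.voxels, ct.voxels)

    def test_uniform_soft_tissue_fills_constant(self):
        ct, lab = self._small_case()
        ct_s, lab_s, vacated, _ = apply_shift(ct, lab, ("Stem",), (0, 0, 3))
        for radius in (0, 1, 2):
            filled = fill_vacated(ct_s, vacated, lab_s, FillConfig(smoothing_radius_voxels=radius))
            np.testing.assert_allclose(filled.voxels[vacated], 40.0, atol=1e-6)

    def test_nearest_donor_matches_brute_force_oracle(self):
        ct, lab = self._small_case(seed=3, noisy=True)
        ct_s, lab_s, vacated, _ = apply_shift(ct, lab, ("Stem",), (0, 0, 3))
        filled = fill_vacated(ct_s, vacated, lab_s, FillConfig(smoothing_radius_voxels=0))
        donors = lab_s.mask("SoftTissue") & ~vacated & ~lab_s.mask("Stem")
        oracle = _fill_oracle(ct_s, vacated, donors, ct.spacing)
        # distance ties may pick different donors; values must agree where the
        # nearest donor is unique, and always stay within the donor HU range
        diff = np.abs(filled.voxels[vacated] - oracle[vacated])
        assert np.median(diff) == 0.0
        assert (diff == 0).mean() > 0.9
        assert filled.voxels[vacated].min() >= ct_s.voxels[donors].min()
        assert filled.voxels[vacated].max() <= ct_s.voxels[donors].max()

    def test_non_vacated_voxels_unchanged(self):
        ct, lab = self._small_case(seed=5, noisy=True)
        ct_s, lab_s, vacated, _ = apply_shift(ct, lab, ("Stem",), (2, 0, 0))
        filled = fill_vacated(ct_s, vacated, lab_s)
        np.testing.assert_array_equal(filled.voxels[~vacated], ct_s.voxels[~vacated])


class TestGenerateFollowup:
    def test_zero_shift_identity_axis_aligned(self, small_phantom, small_frame):
        ct, lab, _ = small_phantom
        fu, record = generate_followup(
            ct, lab, small_frame, ShiftSpec(0, 0, 0, {"y"}), spec=ResampleSpec(interpolation="nearest")
        )
        np.testing.assert_array_equal(fu.voxels, ct.voxels)
        assert record.truth_mm == (0.0, 0.0, 0.0)

    def test_truth_from_frame_spacing(self, small_phantom, small_frame):
        ct, lab, _ = small_phantom
        _, record = generate_followup(ct, lab, small_frame, ShiftSpec(0, 1, 0, {"y"}))
        assert record.truth_mm == (0.0, 0.45, 0.0)
        assert record.frame_spacing_mm == (0.7812, 0.45, 0.7812)

    def test_maximum_x_displacement_at_coarsest_spacing(self):
        assert ShiftSpec(4, 0, 0).truth_mm((0.8594, 0.5, 0.8594))[0] == pytest.approx(3.4376)

    def test_ground_truth_linearity(self):
        spacing = (0.7812, 0.45, 0.7812)
        a = ShiftSpec(1, 2, -1).truth_mm(spacing)
        b = ShiftSpec(3, -2, 2).truth_mm(spacing)
        c = ShiftSpec(4, 0, 1).truth_mm(spacing)
        np.testing.assert_allclose(np.add(a, b), c, atol=1e-12)
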