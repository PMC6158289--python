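"""Masked means, contrast, ratios, normalization, pooling, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import wavecargo as wc
from conftest import true_mask_pair
from wavecargo.wavestats import masked_mean_zero_removed


class TestMaskedMean:
    @pytest.mark.parametrize(
        "image, mask, expected",
        [
            ([[1, 2], [3, 4]], [[1, 1], [1, 1]], 2.5),
            ([[1, 2], [3, 4]], [[1, 0], [0, 1]], 2.5),
            # the in-mask zero is dropped by the faithful recipe
            ([[0, 2], [3, 4]], [[1, 1], [0, 0]], 2.0),
        ],
    )
    def test_zero_removal_recipe(self, image, mask, expected):
        got = masked_mean_zero_removed(np.array(image, float), np.array(mask))
        assert got == expected

    def test_corrected_mean_keeps_in_mask_zeros(self):
        image = np.array([[0.0, 2.0], [3.0, 4.0]])
        mask = np.array([[1, 1], [0, 0]])
        assert masked_mean_zero_removed(image, mask, drop_zeros=False) == 1.0

    def test_empty_mask_and_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            masked_mean_zero_removed(np.ones((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            masked_mean_zero_removed(np.zeros((4, 4)), np.ones((4, 4)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        image=hnp.arrays(
            float, (16, 16), elements=st.floats(0, 100, allow_nan=False)
        ),
        mask=hnp.arrays(bool, (16, 16)),
    )
    def test_agrees_with_brute_force_loop(self, image, mask):
        """Independent oracle: an explicit python loop over pixels."""
        kept = [
            image[i, j] * mask[i, j]
            for i in range(16)
            for j in range(16)
            if image[i, j] * mask[i, j] != 0
        ]
        if not mask.any() or not kept:
            with pytest.raises(ValueError):
                masked_mean_zero_removed(image, mask)
        else:
            expected = sum(kept) / len(kept)
            assert masked_mean_zero_removed(image, mask) == pytest.approx(
                expected, rel=1e-12
            )


class TestWaveStats:
    def test_transient_closed_form_on_true_masks(self, planar_square):
        p, stack, truth = planar_square
        stats = wc.compute_wave_stats(stack, true_mask_pair(truth))
        i_min = stats.values("cargo", "I_min_minD")
        i_max = stats.values("cargo", "I_max_minD")
        assert np.allclose(i_min, p.cargo_baseline)
        assert np.allclose(i_max, p.cargo_baseline * (1 - p.depletion_strength))

    def test_uniform_channel_all_three_means_equal(self):
        pixels = np.full((2, 2, 16, 16), 5.0)
        pixels[:, 0, :, :8] = 50.0  # organizer structure
        stack = wc.ImageStack(pixels=pixels)
        masks = true_mask_pair_from_bool(pixels[:, 0] > 10)
        stats = wc.compute_wave_stats(stack, masks)
        row = stats.frame[(stats.frame.channel == 1) & stats.frame.valid].iloc[0]
        assert row.I_full == row.I_min_minD == row.I_max_minD == 5.0

    def test_linearity_under_intensity_scaling(self, planar_square):
        _, stack, truth = planar_square
        masks = true_mask_pair(truth)
        s1 = wc.compute_wave_stats(stack, masks)
        s2 = wc.compute_wave_stats(stack.scaled(2.0), masks)
        for col in ("I_full", "I_min_minD", "I_max_minD"):
            assert np.allclose(2 * s1.values(1, col), s2.values(1, col))

    def test_partition_identity_without_zeros(self, planar_square):
        """I_full is the area-weighted mean of I_min and I_max whenever
        the masks partition the frame and nothing is zero."""
        _, stack, truth = planar_square
        masks = true_mask_pair(truth)
        stats = wc.compute_wave_stats(stack, masks)
        for t in range(stack.n_frames):
            f = masks.wave_mask[t].mean()
            df = stats.frame
            row = df[(df.frame == t) & (df.channel == 1)].iloc[0]
            assert row.I_full == pytest.approx(
                f * row.I_max_minD + (1 - f) * row.I_min_minD, rel=1e-12
            )

    def test_misaligned_masks_rejected(self, planar_square):
        _, stack, truth = planar_square
        masks = true_mask_pair(truth)
        short = wc.ImageStack(pixels=stack.pixels[:-5])
        with pytest.raises(ValueError):
            wc.compute_wave_stats(short, masks)


def true_mask_pair_from_bool(mask):
    from wavecargo.segmentation import WaveMaskPair

    return WaveMaskPair(
        wave_mask=mask,
        complement_mask=~mask,
        threshold_method="ground_truth",
        threshold_values=np.full(mask.shape[0], np.nan),
    )


class TestContrast:
    def test_zero_when_min_equals_max(self):
        pixels = np.full((2, 2, 16, 16), 5.0)
        pixels[:, 0, :, :8] = 50.0
        stack = wc.ImageStack(pixels=pixels)
        stats = wc.compute_wave_stats(stack, true_mask_pair_from_bool(pixels[:, 0] > 10))
        assert np.allclose(wc.contrast(stats, 1), 0.0)

    def test_transient_contrast_equals_kappa_ratio(self, planar_square):
        p, stack, truth = planar_square
        stats = wc.compute_wave_stats(stack, true_mask_pair(truth))
        k = p.depletion_strength
        assert np.allclose(wc.contrast(stats, "cargo"), k / (1 - k))

    def test_organizer_contrast_negative_on_own_masks(self, planar_square):
        _, stack, truth = planar_square
        stats = wc.compute_wave_stats(stack, true_mask_pair(truth))
        assert np.all(wc.contrast(stats, "organizer") < 0)

    def test_invariant_under_global_intensity_scaling(self, planar_square):
        _, stack, truth = planar_square
        masks = true_mask_pair(truth)
        c1 = wc.contrast(wc.compute_wave_stats(stack, masks), 1)
        c2 = wc.contrast(wc.compute_wave_stats(stack.scaled(13.7), masks), 1)
        assert np.allclose(c1, c2)


class TestIntensityRatio:
    def test_identical_conditions_give_unity(self, planar_square):
        _, stack, truth = planar_square
        stats = wc.compute_wave_stats(stack, true_mask_pair(truth))
        ratios = wc.intensity_ratio(stats, stats, "cargo")
        assert all(v == pytest.approx(1.0) for v in ratios.values())

    def test_transient_full_image_ratio_closed_form(self, planar_square):
        """Presence/absence full-image ratio is 1 − κ·⟨Dn⟩ with ⟨Dn⟩
        from the generator's clean organizer fields."""
        p, stack, truth = planar_square
        import dataclasses

        p0 = dataclasses.replace(p, depletion_strength=0.0)
        stack0, truth0 = wc.generate_planar_scene(p0)
        masks = true_mask_pair(truth)
        with_ = wc.compute_wave_stats(stack, masks)
        without = wc.compute_wave_stats(stack0, masks)
        ratios = wc.intensity_ratio(with_, without, "cargo")
        dn = np.array(
            [
                (f - f.min()) / (f.max() - f.min())
                for f in truth.clean_organizer
            ]
        )
        expected = 1 - p.depletion_strength * dn.mean()
        assert ratios["I_full"] == pytest.approx(expected, rel=1e-9)

    def test_anchored_full_image_ratio_unity_by_conservation(self, planar_anchored):
        p, stack, truth = planar_anchored
        import dataclasses

        p0 = dataclasses.replace(p, barrier_coupling=0.0, cargo_mode="transient",
                                 depletion_strength=0.0)
        stack0, _ = wc.generate_planar_scene(p0)
        masks = true_mask_pair(truth)
        with_ = wc.compute_wave_stats(stack, masks)
        without = wc.compute_wave_stats(stack0, masks)
        ratios = wc.intensity_ratio(with_, without, "cargo")
        assert ratios["I_full"] == pytest.approx(1.0, rel=1e-6)


class TestNormalizeAndPool:
    def test_reference_normalization_arithmetic(self):
        assert wc.normalize_to_reference(10.0, 5.0, 0.5) == pytest.approx(4.0)
        assert wc.normalize_to_reference(7.0, 7.0, 1.0) == pytest.approx(1.0)

    def test_round_trip(self):
        v = np.array([3.0, 9.0])
        norm = wc.normalize_to_reference(v, 4.0, 0.8)
        assert np.allclose(norm * 4.0 * 0.8, v)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            wc.normalize_to_reference(1.0, 0.0)
        with pytest.raises(ValueError):
            wc.normalize_to_reference(1.0, 1.0, 0.0)

    def test_pooling_hand_arithmetic(self):
        res = wc.pool_experiments({"e1": [1.0], "e2": [2.0], "e3": [3.0]})
        assert res.grand_mean == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.n_experiments == 3

    def test_single_group_has_no_sd(self):
        res = wc.pool_experiments({"only": [4.0, 6.0]})
        assert res.grand_mean == pytest.approx(5.0)
        assert res.sd is None

    def test_permutation_invariance_and_unweighted_pooling(self):
        a = {"e1": [1.0] * 100, "e2": [5.0]}
        b = {"e2": [5.0], "e1": [1.0] * 100}
        ra, rb = wc.pool_experiments(a), wc.pool_experiments(b)
        assert ra.grand_mean == rb.grand_mean == pytest.approx(3.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wc.pool_experiments({"e1": []})


class TestCoverage:
    def test_reported_membrane_coverage_worked_example(self):
        cov = wc.coverage_fraction(6.6e3, 25.0)
        assert cov == pytest.approx(16.5)
        assert int(np.floor(cov + 0.5)) == 17  # half-up rounding -> "about 17%"

    def test_limits(self):
        assert wc.coverage_fraction(0.0, 25.0) == 0.0
        assert wc.coverage_fraction(4e4, 25.0) == pytest.approx(100.0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            wc.coverage_fraction(-1.0, 25.0)
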