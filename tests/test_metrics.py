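"""Volume, percent change, histogram moments, pixel-fraction curve and AUC."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adctexture.containers import TumorVOI
from adctexture.metrics import (ADC_RANGE, PixelFractionCurve, difference_auc,
                                histogram_summary, percent_change_adc,
                                percent_change_volume, pixel_fraction_curve,
                                threshold_grid, tumor_volume)
from adctexture.phantom import PhantomSpec, generate_phantom

from conftest import VOXEL, adc_map_from


class TestVolume:
    def test_empty_mask_is_zero(self):
        assert tumor_volume(TumorVOI(np.zeros((4, 4, 2), dtype=bool), VOXEL)) == 0.0

    def test_hand_computed_hundred_voxels(self):
        mask = np.zeros((10, 10, 2), dtype=bool)
        mask[:10, :10, 0] = True  # 100 voxels at 0.136 x 0.136 x 1.5 mm
        assert tumor_volume(TumorVOI(mask, VOXEL)) == pytest.approx(2.7744)

    def test_sphere_volume_close_to_analytic(self):
        r = 2.0
        vox = (0.1, 0.1, 0.1)
        n = 50
        ax = (np.arange(n) - (n - 1) / 2) * 0.1
        d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        voi = TumorVOI(d2 <= r ** 2, vox)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        shell = 4.0 * np.pi * r ** 2 * max(vox)  # one voxel-thick shell
        assert abs(tumor_volume(voi) - analytic) < shell

    def test_volume_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        m = rng.random((8, 8, 4)) < 0.4
        a = m.copy(); a[4:] = False
        b = m.copy(); b[:4] = False
        assert tumor_volume(TumorVOI(m, VOXEL)) == pytest.approx(
            tumor_volume(TumorVOI(a, VOXEL)) + tumor_volume(TumorVOI(b, VOXEL))
        )


class TestPercentChange:
    @pytest.mark.parametrize("vt,v0,expected", [(5.0, 5.0, 100.0),
                                                (10.0, 5.0, 200.0),
                                                (750.0, 500.0, 150.0)])
    def test_volume_ratio_convention(self, vt, v0, expected):
        assert percent_change_volume(vt, v0) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change_volume(10.0, 0.0)
        with pytest.raises(ValueError):
            percent_change_adc(1e-3, 0.0)

    def test_adc_ratio_convention_and_delta_mode(self):
        assert percent_change_adc(1.3e-3, 1.0e-3) == pytest.approx(130.0)
        assert percent_change_adc(1.0e-3, 1.0e-3) == pytest.approx(100.0)
        assert percent_change_adc(1.3e-3, 1.0e-3, delta=True) == pytest.approx(30.0)


class TestHistogramSummary:
    def test_constant_voi_mean_exact_moments_zero_by_convention(self):
        amap, voi = adc_map_from(np.full(50, 1.2e-3))
        summ = histogram_summary(amap, voi)
        assert summ.mean_adc == pytest.approx(1.2e-3)
        assert summ.skewness == 0.0
        assert summ.kurtosis == 0.0

    def test_skewness_matches_hand_formula(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 10.0]) * 1e-3
        amap, voi = adc_map_from(values)
        summ = histogram_summary(amap, voi)
        # adjusted Fisher-Pearson, computed from the explicit formula
        n = values.size
        m = values.mean()
        s = values.std(ddof=1)
        hand = n / ((n - 1) * (n - 2)) * np.sum(((values - m) / s) ** 3)
        assert summ.skewness == pytest.approx(hand, rel=1e-12)
        assert summ.kurtosis >= -2.0

    def test_symmetric_gaussian_sample_skewness_near_zero(self):
        rng = np.random.default_rng(42)
        values = rng.normal(1.5e-3, 2e-4, size=40_000)
        amap, voi = adc_map_from(values, shape=(200, 200, 1))
        summ = histogram_summary(amap, voi)
        assert abs(summ.skewness) < 0.05

    def test_too_few_voxels_flagged_with_missing_moments(self):
        amap, voi = adc_map_from(np.array([1e-3, 2e-3]))
        summ = histogram_summary(amap, voi)
        assert not summ.moments_defined
        assert np.isnan(summ.skewness)

    def test_invalid_voxels_excluded_and_counted(self):
        amap, voi = adc_map_from(np.array([1e-3, 2e-3, 3e-3, 4e-3]))
        amap.valid_mask[1, 0, 0] = False
        summ = histogram_summary(amap, voi)
        assert summ.n_voxels == 3
        assert summ.n_excluded == 1
        assert summ.mean_adc == pytest.approx(np.mean([1e-3, 3e-3, 4e-3]))

    def test_empty_voi_rejected(self):
        amap, _ = adc_map_from(np.array([1e-3]))
        voi = TumorVOI(np.zeros((1, 1, 1), dtype=bool), VOXEL)
        with pytest.raises(ValueError):
            histogram_summary(amap, voi)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(values=hnp.arrays(float, st.integers(5, 60),
                             elements=st.floats(1e-4, 4.9e-3)),
           scale=st.floats(0.1, 10.0), shift=st.floats(0, 1e-4))
    def test_moments_invariant_under_positive_affine_rescale(self, values, scale, shift):
        amap1, voi = adc_map_from(values)
        amap2, _ = adc_map_from(values * scale + shift)
        s1 = histogram_summary(amap1, voi)
        s2 = histogram_summary(amap2, voi)
        if np.std(values) > 1e-5 * np.mean(values):  # guard ill-conditioned moments
            assert s2.skewness == pytest.approx(s1.skewness, rel=1e-6, abs=1e-9)
            assert s2.kurtosis == pytest.approx(s1.kurtosis, rel=1e-6, abs=1e-9)


class TestPixelFractionCurve:
    def test_grid_endpoints_and_length(self):
        thr = threshold_grid()
        assert thr.size == 512
        assert thr[0] == pytest.approx(3e-5)
        assert thr[-1] == pytest.approx(5e-3)
        assert np.all(np.diff(thr) > 0)

    def test_all_above_range_saturates_at_one(self):
        amap, voi = adc_map_from(np.full(10, 6e-3))
        curve = pixel_fraction_curve(amap, voi)
        assert np.all(curve.fractions == 1.0)

    def test_all_below_range_is_zero(self):
        amap, voi = adc_map_from(np.full(10, 1e-5))
        curve = pixel_fraction_curve(amap, voi)
        assert np.all(curve.fractions == 0.0)

    def test_brute_force_count_at_interior_threshold(self):
        values = np.array([0.5, 1.0, 1.5, 2.0]) * 1e-3
        amap, voi = adc_map_from(values)
        curve = pixel_fraction_curve(amap, voi)
        i = np.argmin(np.abs(curve.thresholds - 1.2e-3))
        t = curve.thresholds[i]
        assert curve.fractions[i] == np.mean(values > t) == 0.5

    def test_matches_explicit_counting_everywhere(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 6e-3, size=200)
        amap, voi = adc_map_from(values)
        curve = pixel_fraction_curve(amap, voi)
        brute = np.array([(values > t).mean() for t in curve.thresholds])
        np.testing.assert_array_equal(curve.fractions, brute)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(values=hnp.arrays(float, st.integers(1, 100),
                             elements=st.floats(0, 8e-3)))
    def test_curve_bounded_and_monotone_nonincreasing(self, values):
        amap, voi = adc_map_from(values)
        curve = pixel_fraction_curve(amap, voi)
        assert np.all((curve.fractions >= 0) & (curve.fractions <= 1))
        assert np.all(np.diff(curve.fractions) <= 0)

    def test_empty_voi_rejected(self):
        amap, _ = adc_map_from(np.array([1e-3]))
        voi = TumorVOI(np.zeros((1, 1, 1), dtype=bool), VOXEL)
        with pytest.raises(ValueError):
            pixel_fraction_curve(amap, voi)


class TestDifferenceAUC:
    def test_identical_curves_give_zero(self):
        amap, voi = adc_map_from(np.linspace(1e-4, 4e-3, 20))
        c = pixel_fraction_curve(amap, voi)
        assert difference_auc(c, c).value == 0.0

    def test_full_shift_equals_threshold_range_width(self):
        lo_map, voi = adc_map_from(np.full(10, 1e-5))   # all below range
        hi_map, _ = adc_map_from(np.full(10, 6e-3))     # all above range
        pre = pixel_fraction_curve(lo_map, voi)
        post = pixel_fraction_curve(hi_map, voi)
        width = ADC_RANGE[1] - ADC_RANGE[0]
        assert width == pytest.approx(4.97e-3)
        assert difference_auc(pre, post).value == pytest.approx(4.97e-3, abs=1e-6)

    def test_antisymmetry_is_exact(self):
        rng = np.random.default_rng(2)
        a_map, voi = adc_map_from(rng.uniform(0, 5e-3, 30))
        b_map, _ = adc_map_from(rng.uniform(0, 5e-3, 30))
        a = pixel_fraction_curve(a_map, voi)
        b = pixel_fraction_curve(b_map, voi)
        assert difference_auc(a, b).value == -difference_auc(b, a).value

    def test_uniform_upward_shift_gives_positive_auc_and_exact_mean_shift(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(5e-4, 2e-3, 100)
        delta = 5e-4
        pre_map, voi = adc_map_from(values)
        post_map, _ = adc_map_from(values + delta)
        auc = difference_auc(pixel_fraction_curve(pre_map, voi),
                             pixel_fraction_curve(post_map, voi))
        assert auc.value > 0
        pre_mean = histogram_summary(pre_map, voi).mean_adc
        post_mean = histogram_summary(post_map, voi).mean_adc
        assert post_mean - pre_mean == pytest.approx(delta, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        t1 = threshold_grid()
        t2 = threshold_grid(n=256)
        c1 = PixelFractionCurve(t1, np.ones_like(t1))
        c2 = PixelFractionCurve(t2, np.ones_like(t2))
        with pytest.raises(ValueError, match="grid"):
            difference_auc(c1, c2)

    def test_shifted_phantom_auc_positive(self, small_spec):
        from adctexture.fitting import fit_adc_map
        from adctexture.phantom import TreatmentEffect, simulate_treatment_effect

        series, ground = generate_phantom(small_spec)
        voi = TumorVOI(ground.voi_mask, small_spec.voxel_size)
        shifted = simulate_treatment_effect(ground, TreatmentEffect(1.3))
        import dataclasses

        from adctexture.phantom import synthesize_signal
        rng = np.random.default_rng(99)
        post_series = synthesize_signal(shifted, small_spec.bvalues,
                                        small_spec.sigma, rng)
        pre = pixel_fraction_curve(fit_adc_map(series, voi), voi)
        post = pixel_fraction_curve(fit_adc_map(post_series, voi), voi)
        assert difference_auc(pre, post).value > 0
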