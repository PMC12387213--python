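"""Polar orientation statistics, high-energy feature masks, histogram tests."""

import numpy as np
import pytest

from conftest import clean_fibre_texture
from poremap.design import PoreLattice
from poremap.image import RasterImage
from poremap.orientation import analyze_orientation
from poremap.polar import (
    circular_summary,
    compare_histograms,
    high_energy_mask,
    orientation_polar,
    scale_for_display,
)
from poremap.synth import (
    Domain,
    FilamentTextureSpec,
    SceneConfig,
    make_filament_texture,
    make_pore_scene,
    sample_orientations,
)


class TestCircularSummary:
    def test_single_angle(self):
        cs = circular_summary(np.full(10, 37.0))
        assert cs.circular_mean_deg == pytest.approx(37.0)
        assert cs.resultant_length == pytest.approx(1.0)

    def test_axial_wrap_average(self):
        # 85 and -85 deg are 10 deg apart axially; mean is +/-90, not 0
        cs = circular_summary(np.array([85.0, -85.0]))
        assert abs(cs.circular_mean_deg) == pytest.approx(90.0, abs=1e-9)
        assert cs.resultant_length == pytest.approx(np.cos(np.radians(10.0)), abs=1e-9)

    def test_orthogonal_pair_cancels(self):
        cs = circular_summary(np.array([0.0, 90.0]))
        assert cs.resultant_length == pytest.approx(0.0, abs=1e-12)

    def test_weights(self):
        cs = circular_summary(np.array([0.0, 90.0]), weights=np.array([3.0, 1.0]))
        assert cs.circular_mean_deg == pytest.approx(0.0, abs=1e-9)
        assert cs.resultant_length == pytest.approx(0.5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            circular_summary(np.array([0.0]), weights=np.array([-1.0]))

    def test_empty_input(self):
        cs = circular_summary(np.array([]))
        assert np.isnan(cs.circular_mean_deg)
        assert cs.resultant_length == 0.0

    def test_variance_complements_resultant(self):
        cs = circular_summary(np.array([10.0, 20.0, 30.0]))
        assert cs.circular_variance == pytest.approx(1.0 - cs.resultant_length)


class TestHighEnergyMask:
    def test_quantile_keeps_five_percent(self, rng):
        img = RasterImage(rng.normal(size=(200, 200)), 1.0)
        tf = analyze_orientation(img, window_sigma_px=2)
        mask, meta = high_energy_mask(tf, quantile=0.95)
        assert mask.mean() == pytest.approx(0.05, abs=0.001)
        assert meta["method"] == "quantile"
        assert meta["threshold"] > 0

    def test_invalid_quantile_rejected(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        with pytest.raises(ValueError):
            high_energy_mask(tf, quantile=1.5)

    def test_unknown_method_rejected(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        with pytest.raises(ValueError):
            high_energy_mask(tf, method="triangle")

    def test_zero_energy_warns_empty(self):
        from poremap.orientation import riesz_gradient, structure_tensor

        gx, gy = riesz_gradient(np.full((32, 32), 1.0))
        tf = structure_tensor(gx, gy, 2.0)
        with pytest.warns(UserWarning, match="zero"):
            mask, _ = high_energy_mask(tf)
        assert not mask.any()

    def test_pore_rims_are_energy_hotspots(self):
        # sharp texture silencing at pore rims concentrates gradient energy:
        # the high-energy mask density near rims exceeds the bulk by >= 2x
        cfg = SceneConfig(width_px=256, height_px=256, pixel_size_um=0.5, seed=3)
        img, gt = make_pore_scene(
            cfg,
            PoreLattice(16.0, 48.0),
            FilamentTextureSpec(n_filaments=2000, kappa=0.0, spatial_period_um=4.0),
        )
        tf = analyze_orientation(img, window_sigma_px=2)
        mask, _ = high_energy_mask(tf, quantile=0.95)
        from scipy.ndimage import distance_transform_edt

        dist_um = distance_transform_edt(~gt.pore_mask) * cfg.pixel_size_um
        near = (dist_um > 0) & (dist_um < 3.0)
        far = dist_um > 6.0
        assert mask[near].mean() > 2.0 * mask[far].mean()


class TestOrientationPolar:
    def test_single_orientation_mode_and_alignment(self):
        img = clean_fibre_texture(40.0, seed=2)
        tf = analyze_orientation(img, window_sigma_px=2)
        h = orientation_polar(tf, n_bins=36)
        assert h.summary.resultant_length > 0.9
        assert h.bin_centers_deg[np.argmax(h.weights)] == pytest.approx(40.0, abs=5.0)

    def test_isotropic_field_low_resultant(self, rng):
        img = RasterImage(rng.normal(size=(256, 256)), 1.0)
        tf = analyze_orientation(img, window_sigma_px=3)
        h = orientation_polar(tf)
        assert h.summary.resultant_length < 0.1

    def test_two_domain_texture_bimodal_but_roi_unimodal(self):
        cfg = SceneConfig(width_px=256, height_px=256, pixel_size_um=0.5, seed=5)
        # finite filaments stay inside their half-frame domain; frame-spanning
        # fibres would leak across the boundary and mix the two modes
        spec = FilamentTextureSpec(
            n_filaments=160,
            length_um=50.0,
            width_um=1.3,
            domain_map=(
                Domain(0.0, 0.0, 0.5, 1.0, -50.0, 1e5),
                Domain(0.5, 0.0, 0.5, 1.0, 40.0, 1e5),
            ),
        )
        img, _ = make_filament_texture(cfg, spec)
        tf = analyze_orientation(img, window_sigma_px=2)
        full = orientation_polar(tf, n_bins=36)
        # full frame: two well-separated modes -> weak global resultant
        assert full.summary.resultant_length < 0.5
        p = full.normalized
        top = np.sort(p)[::-1]
        # both modes carry substantial probability mass
        centers = full.bin_centers_deg
        mass_a = p[np.abs(centers + 50.0) <= 10.0].sum()
        mass_b = p[np.abs(centers - 40.0) <= 10.0].sum()
        assert mass_a > 0.1 and mass_b > 0.1
        # ROI confined to the left half: unimodal at -50 deg
        left = orientation_polar(tf, roi=(16, 16, 224, 96), n_bins=36)
        assert left.summary.resultant_length > 0.8
        assert left.summary.circular_mean_deg == pytest.approx(-50.0, abs=5.0)

    def test_energy_weighting_changes_weights_not_support(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        hw = orientation_polar(tf, weighting="energy")
        hu = orientation_polar(tf, weighting="none")
        assert hw.weights.sum() != pytest.approx(hu.weights.sum())
        assert np.argmax(hw.weights) == np.argmax(hu.weights)

    def test_invalid_weighting_rejected(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        with pytest.raises(ValueError):
            orientation_polar(tf, weighting="amplitude")

    def test_roi_out_of_bounds_rejected(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        with pytest.raises(ValueError):
            orientation_polar(tf, roi=(100, 100, 64, 64))

    def test_empty_selection_warns(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        with pytest.warns(UserWarning, match="empty"):
            h = orientation_polar(tf, mask=np.zeros(grating30.shape, dtype=bool))
        assert h.weights.sum() == 0


class TestScaleForDisplay:
    def test_identity(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        h = orientation_polar(tf)
        s = scale_for_display(h, 1.0)
        np.testing.assert_array_equal(s.weights, h.weights)

    def test_times_ten_scales_weights_only(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        h = orientation_polar(tf)
        s = scale_for_display(h, 10.0)
        np.testing.assert_allclose(s.weights, 10.0 * h.weights)
        np.testing.assert_allclose(s.normalized, h.normalized)
        assert s.display_scale == 10.0
        assert s.summary == h.summary

    def test_nonpositive_factor_rejected(self, grating30):
        tf = analyze_orientation(grating30, window_sigma_px=2)
        h = orientation_polar(tf)
        with pytest.raises(ValueError):
            scale_for_display(h, 0.0)


class TestCompareHistograms:
    def _hist(self, mu, seed, n=4000, kappa=20.0):
        rng = np.random.default_rng(seed)
        angles = sample_orientations(rng, mu, kappa, n)
        edges = np.linspace(-90.0, 90.0, 37)
        w, _ = np.histogram(angles, bins=edges)
        from poremap.polar import OrientationHistogram

        return OrientationHistogram(
            bin_edges_deg=edges,
            weights=w.astype(float),
            summary=circular_summary(angles),
        )

    def test_self_comparison_not_significant(self):
        a = self._hist(20.0, seed=1)
        b = self._hist(20.0, seed=2)
        res = compare_histograms(a, b, n_perm=499, seed=0)
        assert res.p_value > 0.05
        assert res.circular_mean_difference_deg < 3.0

    def test_forty_five_degree_shift_detected(self):
        a = self._hist(0.0, seed=1)
        b = self._hist(45.0, seed=2)
        res = compare_histograms(a, b, n_perm=499, seed=0)
        assert res.circular_mean_difference_deg == pytest.approx(45.0, abs=3.0)
        assert res.p_value < 0.01

    def test_mismatched_binning_rejected(self):
        from poremap.polar import OrientationHistogram

        a = self._hist(0.0, seed=1)
        b = OrientationHistogram(
            bin_edges_deg=np.linspace(-90.0, 90.0, 19), weights=np.ones(18)
        )
        with pytest.raises(ValueError):
            compare_histograms(a, b)

    def test_null_calibration(self):
        # under the null (same distribution), p-values should not be
        # systematically tiny: over modest replication the rejection rate
        # at alpha = 0.2 stays near alpha
        rejections = 0
        reps = 20
        for i in range(reps):
            a = self._hist(10.0, seed=100 + 2 * i, n=1500)
            b = self._hist(10.0, seed=101 + 2 * i, n=1500)
            res = compare_histograms(a, b, n_perm=99, seed=i)
            rejections += res.p_value < 0.2
        assert rejections <= 9  # ~4 expected; allow generous binomial slack


class TestVonMisesRecovery:
    def test_resultant_monotone_in_concentration(self):
        # full loop: generator -> rendered texture -> tensor -> polar summary
        rs = []
        for kappa in (0.0, 2.0, 10.0, 50.0):
            reps = []
            for seed in range(3):
                cfg = SceneConfig(width_px=192, height_px=192, pixel_size_um=0.5, seed=seed)
                spec = FilamentTextureSpec(
                    mu_deg=15.0, kappa=kappa, n_filaments=60, length_um=1e5, width_um=1.3
                )
                img, _ = make_filament_texture(cfg, spec)
                tf = analyze_orientation(img, window_sigma_px=2)
                reps.append(orientation_polar(tf).summary.resultant_length)
            rs.append(np.mean(reps))
        assert rs == sorted(rs)
        assert rs[0] < 0.35
        assert rs[-1] > 0.85

    def test_mean_recovered_for_concentrated_fields(self):
        for kappa in (10.0, 50.0):
            errs = []
            for seed in range(10):
                cfg = SceneConfig(width_px=192, height_px=192, pixel_size_um=0.5, seed=seed)
                spec = FilamentTextureSpec(
                    mu_deg=-25.0, kappa=kappa, n_filaments=60, length_um=1e5, width_um=1.3
                )
                img, gt = make_filament_texture(cfg, spec)
                tf = analyze_orientation(img, window_sigma_px=2)
                est = orientation_polar(tf).summary.circular_mean_deg
                truth = circular_summary(
                    np.asarray(gt.params_used["sampled_orientations_deg"])
                ).circular_mean_deg
                d = abs(est - truth)
                errs.append(min(d, 180.0 - d))
            assert np.mean(errs) < 3.0
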