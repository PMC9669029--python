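"""Imaging metrics: preprocessing, orientation/nematic order, pores,
RDF, and temporal autocorrelation."""

import numpy as np
import pytest

from actomech import imaging as im
from actomech import synthetic as syn
from actomech.imaging import OrientationField
from actomech.types import ImageStack


class TestPreprocess:
    def test_bleach_correction_equalizes_means(self):
        rng = np.random.default_rng(0)
        base = rng.random((64, 64)) * 50 + 20
        stack = ImageStack(
            np.stack([base * f for f in (1.0, 0.7, 0.5)]), pixel_size=0.1
        )
        out = im.preprocess(stack, register=False)
        means = out.frames.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=1e-9)

    def test_registration_recovers_known_shift(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(1)
        base = gaussian_filter(rng.random((128, 128)), 2) * 100
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        stack = ImageStack(np.stack([base, shifted]), pixel_size=0.1)
        out = im.preprocess(stack, bleach_correct=False)
        # after registration frame 1 should align with frame 0
        err = np.abs(out.frames[1] - out.frames[0])[10:-10, 10:-10].mean()
        err_raw = np.abs(shifted - base)[10:-10, 10:-10].mean()
        assert err < 0.2 * err_raw

    def test_zero_mean_frame_rejected(self):
        stack = ImageStack(np.zeros((2, 32, 32)), pixel_size=0.1)
        with pytest.raises(ValueError):
            im.preprocess(stack, register=False)


class TestOrientation:
    @pytest.mark.parametrize("deg", [0, 30, 60, 135])
    def test_stripes_recovered_within_two_degrees(self, deg):
        st = syn.gen_image(
            "stripes", 200, 0.1, {"angle": np.deg2rad(deg), "period": 12}
        )
        field = im.orientation_field(st.frame(0), 0.1)
        ang = np.rad2deg(field.angles[np.isfinite(field.angles)])
        err = (ang - deg + 90) % 180 - 90
        assert np.abs(err).max() < 2.0

    def test_white_noise_has_no_preferred_axis(self):
        rng = np.random.default_rng(2)
        field = im.orientation_field(rng.random((200, 200)), 0.1)
        ang = field.angles[np.isfinite(field.angles)]
        # circular mean resultant of the doubled angles is small
        resultant = np.abs(np.mean(np.exp(2j * ang)))
        assert resultant < 0.3

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            im.orientation_field(np.zeros((16, 16)), 0.1, window_um=3.5)


class TestNematicOrder:
    def test_uniform_angles_give_exactly_one(self):
        f = OrientationField(
            np.arange(5.0), np.arange(5.0), np.full((5, 5), 0.3), 3.5, 0.8
        )
        om = im.nematic_order(f)
        assert om.mean == pytest.approx(1.0)
        assert np.allclose(om.order, 1.0)

    def test_orthogonal_neighbors_give_minus_one(self):
        # the formula's lower limit: every neighbour differs by 90 deg
        a = np.full((3, 3), np.pi / 4)
        a[1, 1] = -np.pi / 4
        f = OrientationField(np.arange(3.0), np.arange(3.0), a, 3.5, 0.8)
        om = im.nematic_order(f)
        assert om.order[0, 0] == pytest.approx(-1.0)

    def test_random_angles_average_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-np.pi / 2, np.pi / 2, (40, 40))
        f = OrientationField(np.arange(40.0), np.arange(40.0), a, 3.5, 0.8)
        om = im.nematic_order(f)
        assert abs(om.mean) < 0.05

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-0.3, 0.3, (8, 8))
        f1 = OrientationField(np.arange(8.0), np.arange(8.0), a, 3.5, 0.8)
        f2 = OrientationField(np.arange(8.0), np.arange(8.0), a + 0.5, 3.5, 0.8)
        np.testing.assert_allclose(
            im.nematic_order(f1).order, im.nematic_order(f2).order, atol=1e-12
        )

    def test_aligned_image_pipeline_near_one(self):
        st = syn.gen_image("stripes", 200, 0.1, {"angle": 0.4, "period": 12})
        field = im.orientation_field(st.frame(0), 0.1)
        om = im.nematic_order(field)
        assert om.mean > 0.99


class TestPores:
    def test_counts_and_areas(self):
        st = syn.gen_image(
            "porous", 100, 0.1, {"pores": [(20, 20, 5, 5), (60, 70, 8, 4)]}
        )
        ps = im.pore_sizes(st.frame(0), 0.1)
        assert len(ps.areas) == 2
        assert sorted(ps.areas) == pytest.approx([0.25, 0.32])

    def test_all_bright_has_no_pores(self):
        with pytest.warns(UserWarning):
            ps = im.pore_sizes(np.ones((32, 32)), 0.1)
        assert len(ps.areas) == 0

    def test_border_touching_region_excluded(self):
        img = np.ones((40, 40))
        img[0:10, 5:10] = 0.0  # touches the top border
        img[20:24, 20:24] = 0.0
        ps = im.pore_sizes(img, 0.1)
        assert len(ps.areas) == 1

    def test_threshold_is_relative(self):
        st = syn.gen_image("porous", 64, 0.1, {"pores": [(10, 10, 5, 5)]})
        a = im.pore_sizes(st.frame(0), 0.1)
        b = im.pore_sizes(st.frame(0) * 37.0, 0.1)
        np.testing.assert_allclose(a.areas, b.areas)


class TestRdf:
    def test_uniform_random_is_flat(self):
        rng = np.random.default_rng(5)
        img = (rng.random((200, 200)) > 0.5).astype(float)
        res = im.radial_distribution(img, 0.1, dr=0.2, r_max=4.0, seed=1)
        inner = res.g[2:]
        assert inner.std() / inner.mean() < 0.05

    def test_invalid_binning_rejected(self):
        with pytest.raises(ValueError):
            im.radial_distribution(np.ones((64, 64)), 0.1, dr=5.0, r_max=2.0)

    def test_exponential_cluster_decay_recovered(self):
        # white pixels scattered with an exponential radial profile
        # (scale 0.5 um) around seed centres; the pixel-pair profile is
        # the profile's self-convolution, whose fitted decay length is
        # 1.03 um (numeric autocorrelation oracle, same fit range)
        rng = np.random.default_rng(6)
        lam_true = 0.5  # um
        lam_pair = 1.03  # um, from the convolution oracle
        img = np.zeros((300, 300))
        centers = rng.uniform(30, 270, (40, 2))
        for c in centers:
            n = 200
            r = rng.exponential(lam_true / 0.1, n)
            th = rng.uniform(0, 2 * np.pi, n)
            rr = np.clip((c[0] + r * np.cos(th)).astype(int), 0, 299)
            cc = np.clip((c[1] + r * np.sin(th)).astype(int), 0, 299)
            img[rr, cc] = 1.0
        res = im.radial_distribution(
            img, 0.1, dr=0.1, r_max=3.0, center_subsample=1500, seed=2
        )
        assert res.decay_length == pytest.approx(lam_pair, rel=0.25)


class TestAutocorr:
    def test_lag_zero_is_one_and_noise_uncorrelated(self):
        rng = np.random.default_rng(7)
        stack = ImageStack(rng.random((40, 32, 32)), pixel_size=0.1)
        fit = im.fluctuation_autocorr(stack)
        assert fit.correlation[0] == 1.0
        assert np.abs(fit.correlation[1:]).max() < 0.1

    def test_single_exponential_recovered(self):
        stack = syn.gen_correlated_stack(300, 96, tau_frames=50.0, seed=8)
        fit = im.fluctuation_autocorr(stack)
        assert fit.time_constant == pytest.approx(50.0, rel=0.10)
        # the fitted curve must reproduce the single-exponential decay
        # (when both time constants coincide a1 itself is unidentifiable)
        model = (
            fit.a1 * np.exp(-50.0 / fit.tau_fast)
            + (1 - fit.a1) * np.exp(-50.0 / fit.tau_slow)
            + fit.offset
        )
        assert model == pytest.approx(np.exp(-1.0), abs=0.05)

    def test_time_reversal_invariance(self):
        stack = syn.gen_correlated_stack(60, 24, tau_frames=8.0, seed=9)
        rev = ImageStack(stack.frames[::-1].copy(), pixel_size=0.1)
        a = im.fluctuation_autocorr(stack)
        b = im.fluctuation_autocorr(rev)
        np.testing.assert_allclose(a.correlation, b.correlation, atol=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            im.fluctuation_autocorr(ImageStack(np.ones((5, 8, 8)), 0.1))

    def test_intensity_timecourse_normalized(self):
        frames = np.stack([np.full((8, 8), v) for v in (4.0, 2.0, 1.0)])
        t, inorm = im.intensity_timecourse(ImageStack(frames, 0.1))
        np.testing.assert_allclose(inorm, [1.0, 0.5, 0.25])
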