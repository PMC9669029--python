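"""MSD, van Hove, NGP and kinematics against closed forms."""

import numpy as np
import pandas as pd
import pytest

from actomech import synthetic as syn
from actomech import trajstats as ts
from actomech.types import TrajectorySet


def _dense(pos, dt=1.0, **kw):
    return TrajectorySet.from_arrays(np.asarray(pos, dtype=float), dt, **kw)


class TestMsd:
    def test_ballistic_exponent_two(self):
        t = np.arange(100.0)
        pos = np.stack(
            [np.stack([v * t, np.zeros_like(t)], axis=-1) for v in (0.5, 1.0, 2.0)]
        )
        res = ts.msd(_dense(pos))
        assert res.alpha == pytest.approx(2.0, abs=1e-6)

    def test_frozen_flagged_degenerate(self):
        pos = np.zeros((5, 50, 2))
        res = ts.msd(_dense(pos))
        assert res.degenerate
        assert np.all(res.msd[np.isfinite(res.msd)] == 0)

    def test_concatenation_weighting(self, brownian_300):
        """MSD of a concatenated set equals the count-weighted mean of
        the separate curves."""
        half_a = TrajectorySet(
            brownian_300.data[brownian_300.data["id"] < 20].copy(),
            frame_interval=1.0,
        )
        half_b = TrajectorySet(
            brownian_300.data[
                (brownian_300.data["id"] >= 20) & (brownian_300.data["id"] < 40)
            ].copy(),
            frame_interval=1.0,
        )
        both = half_a.concat(half_b)
        lags = [1, 5, 10]
        ra = ts.msd(half_a, lags=lags)
        rb = ts.msd(half_b, lags=lags)
        rc = ts.msd(both, lags=lags)
        merged = (ra.msd * ra.counts + rb.msd * rb.counts) / (
            ra.counts + rb.counts
        )
        np.testing.assert_allclose(rc.msd, merged, rtol=1e-12)

    def test_rotation_translation_invariance(self, brownian_300):
        df = brownian_300.data.copy()
        c, s = np.cos(0.7), np.sin(0.7)
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        df["x"], df["y"] = c * x - s * y + 5.0, s * x + c * y - 3.0
        moved = TrajectorySet(df, frame_interval=1.0)
        lags = [1, 4, 16]
        np.testing.assert_allclose(
            ts.msd(brownian_300, lags=lags).msd,
            ts.msd(moved, lags=lags).msd,
            rtol=1e-9,
        )

    def test_rotational_nematic_unwrap_invariance(self):
        rng = np.random.default_rng(3)
        n, m = 20, 80
        theta = np.cumsum(rng.normal(0, 0.1, (n, m)), axis=1)
        pos = np.zeros((n, m, 2))
        a = _dense(pos, theta=((theta + np.pi / 2) % np.pi) - np.pi / 2)
        b = _dense(pos, theta=((theta + np.pi + np.pi / 2) % np.pi) - np.pi / 2)
        lags = [1, 3, 9]
        np.testing.assert_allclose(
            ts.msd(a, kind="rotational", lags=lags).msd,
            ts.msd(b, kind="rotational", lags=lags).msd,
            atol=1e-12,
        )


class TestNgp:
    def test_isotropic_3d_gaussian_is_zero(self):
        r = np.linalg.norm(
            np.random.default_rng(0).normal(size=(100000, 3)), axis=1
        )
        assert ts.ngp_of_magnitudes(r) == pytest.approx(0.0, abs=0.02)

    def test_fixed_magnitude_gives_minus_point_four(self):
        assert ts.ngp_of_magnitudes(np.full(50, 1.3)) == pytest.approx(-0.4)

    def test_isotropic_2d_gaussian_gives_point_two(self):
        r = np.linalg.norm(
            np.random.default_rng(1).normal(size=(100000, 2)), axis=1
        )
        assert ts.ngp_of_magnitudes(r) == pytest.approx(0.2, abs=0.02)

    def test_curve_on_brownian_near_zero_2d_value(self, brownian_300):
        df = ts.ngp(brownian_300, lags=[1, 5])
        # 2-D Gaussian steps with the printed 3/5 normalization sit at 0.2
        assert df["ngp"].to_numpy() == pytest.approx([0.2, 0.2], abs=0.05)


class TestVanHove:
    def test_gaussian_steps_match_fit(self, brownian_300):
        d = ts.van_hove(brownian_300, lag=1)
        sigma_exp = np.sqrt(2 * 0.01 * 1.0)
        # 2-D magnitudes: mean = sigma*sqrt(pi/2)
        assert d.gauss_mu == pytest.approx(sigma_exp * np.sqrt(np.pi / 2), rel=0.05)
        assert abs(d.density.sum() * np.diff(d.bin_centers)[0] - 1) < 0.05

    def test_constant_steps_degenerate_spike(self):
        t = np.arange(30.0)
        pos = np.stack([np.stack([t, np.zeros_like(t)], -1)] * 3)
        d = ts.van_hove(_dense(pos), lag=1)
        assert d.gauss_sigma == pytest.approx(0.0, abs=1e-12)

    def test_frozen_plus_mobile_mixture_has_central_spike(self):
        mobile = syn.gen_brownian(50, 100, 1.0, 0.05, seed=1)
        frozen = _dense(np.zeros((50, 100, 2)))
        mix = mobile.concat(frozen)
        d = ts.van_hove(mix, lag=1, bins=60)
        # half of all steps are exactly zero: first bin dominates
        assert d.density[0] > 3 * d.density[1:].max()


class TestKinematics:
    def test_straight_track_speeds_equal(self):
        t = np.arange(20.0)
        pos = np.stack([np.stack([0.3 * t, np.zeros_like(t)], -1)])
        res = ts.kinematics(_dense(pos, lengths=np.array([1.0])))
        row = res.table.iloc[0]
        assert row["v_max"] == pytest.approx(0.3)
        assert row["v_ee"] == pytest.approx(0.3)
        assert not row["immobile"]

    def test_closed_loop_zero_net_speed(self):
        ang = np.linspace(0, 2 * np.pi, 41)
        pos = np.stack([np.stack([np.cos(ang), np.sin(ang)], -1)])
        res = ts.kinematics(_dense(pos))
        row = res.table.iloc[0]
        assert row["v_ee"] == pytest.approx(0.0, abs=1e-12)
        assert row["v_max"] > 0

    def test_recovers_imposed_speed_length_slope(self):
        rng = np.random.default_rng(7)
        n, m = 200, 40
        lengths = rng.uniform(0.2, 1.5, n)
        v = 1.0 - 0.4 * lengths + rng.normal(0, 0.01, n)
        t = np.arange(m, dtype=float)
        pos = np.stack(
            [np.stack([vi * t, np.zeros_like(t)], -1) for vi in v]
        )
        res = ts.kinematics(_dense(pos, lengths=lengths))
        assert res.slope == pytest.approx(-0.4, rel=0.10)
        assert res.abs_slope == pytest.approx(0.4, rel=0.10)

    def test_immobile_flag_uses_floor(self):
        t = np.arange(10.0)
        slow = np.stack([np.stack([0.01 * t, np.zeros_like(t)], -1)])
        res = ts.kinematics(_dense(slow), immobile_floor=0.1)
        assert bool(res.table.iloc[0]["immobile"])
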