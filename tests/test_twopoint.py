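"""Two-point displacement correlation: projection algebra, brute-force
oracle equivalence, normalization invariances, power-law fitting."""

import numpy as np
import pytest

from actomech import twopoint as tp
from actomech.types import TrajectorySet


def _dense(pos, dt=1.0):
    return TrajectorySet.from_arrays(np.asarray(pos, dtype=float), dt)


def brute_force_drr(traj, lags, r_range, n_bins, normalized, floor=1e-12):
    """Naive O(N^2 T) enumeration of Eq.-10-style pair products."""
    edges = np.linspace(r_range[0], r_range[1], n_bins + 1)
    sums = np.zeros((len(lags), n_bins))
    counts = np.zeros((len(lags), n_bins))
    frames = {
        int(f): g.set_index("id")[["x", "y"]]
        for f, g in traj.data.groupby("frame")
    }
    for li, lag in enumerate(lags):
        for f0, tab0 in frames.items():
            tab1 = frames.get(f0 + lag)
            if tab1 is None:
                continue
            ids = sorted(set(tab0.index) & set(tab1.index))
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    pa = tab0.loc[ids[a]].to_numpy()
                    pb = tab0.loc[ids[b]].to_numpy()
                    sep = pb - pa
                    dist = np.linalg.norm(sep)
                    if not (r_range[0] <= dist < r_range[1]) or dist == 0:
                        continue
                    nhat = sep / dist
                    da = tab1.loc[ids[a]].to_numpy() - pa
                    db = tab1.loc[ids[b]].to_numpy() - pb
                    prod = (da @ nhat) * (db @ nhat)
                    if normalized:
                        ma, mb = np.linalg.norm(da), np.linalg.norm(db)
                        if ma <= floor or mb <= floor:
                            continue
                        prod /= ma * mb
                    bidx = min(
                        np.searchsorted(edges, dist, side="right") - 1, n_bins - 1
                    )
                    sums[li, bidx] += prod
                    counts[li, bidx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@pytest.fixture(scope="module")
def random_small_set():
    rng = np.random.default_rng(5)
    pos = np.cumsum(rng.normal(0, 0.5, (8, 15, 2)), axis=1)
    pos += rng.uniform(0, 25, (8, 1, 2))
    return _dense(pos)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_naive_enumeration(self, random_small_set, normalized):
        lags = [1, 2, 3]
        fn = tp.crr if normalized else tp.drr
        kwargs = dict(lags=lags, r_range=(1.0, 15.0), n_bins=10)
        if normalized:
            res = fn(random_small_set, fit=False, **kwargs)
        else:
            res = fn(random_small_set, **kwargs)
        ref = brute_force_drr(
            random_small_set, lags, (1.0, 15.0), 10, normalized
        )
        np.testing.assert_allclose(res.matrix, ref, rtol=1e-10, equal_nan=True)


class TestProjectionAlgebra:
    def test_identical_translation_along_separation(self):
        # two particles moved identically by d along their separation
        pos = np.zeros((2, 2, 2))
        pos[0, 0] = [0, 0]
        pos[1, 0] = [10, 0]
        pos[:, 1] = pos[:, 0] + [0.7, 0.0]
        res = tp.drr(_dense(pos), lags=[1], r_range=(3, 20), n_bins=40)
        vals = res.matrix[0][np.isfinite(res.matrix[0])]
        assert vals == pytest.approx([0.49])

    def test_perpendicular_displacements_vanish(self):
        pos = np.zeros((2, 2, 2))
        pos[0, 0] = [0, 0]
        pos[1, 0] = [10, 0]
        pos[:, 1] = pos[:, 0] + [0.0, 0.5]
        res = tp.drr(_dense(pos), lags=[1], r_range=(3, 20), n_bins=40)
        vals = res.matrix[0][np.isfinite(res.matrix[0])]
        assert vals == pytest.approx([0.0], abs=1e-14)

    def test_comoving_pair_normalizes_to_one(self):
        pos = np.zeros((2, 3, 2))
        pos[0, 0] = [0, 0]
        pos[1, 0] = [8, 0]
        for k in (1, 2):
            pos[:, k] = pos[:, k - 1] + [0.3, 0.0]
        res = tp.crr(_dense(pos), lags=[1], r_range=(3, 20), n_bins=40, fit=False)
        vals = res.profile[np.isfinite(res.profile)]
        assert vals == pytest.approx([1.0])

    def test_antiparallel_pair_gives_minus_one(self):
        pos = np.zeros((2, 2, 2))
        pos[0, 0] = [0, 0]
        pos[1, 0] = [8, 0]
        pos[0, 1] = [0.3, 0]
        pos[1, 1] = [7.7, 0]
        res = tp.crr(_dense(pos), lags=[1], r_range=(3, 20), n_bins=40, fit=False)
        vals = res.profile[np.isfinite(res.profile)]
        assert vals == pytest.approx([-1.0])


class TestInvariances:
    def test_crr_scale_invariant(self):
        # two-frame set: identical start positions, every displacement
        # multiplied by 5 -> normalization cancels the scale exactly
        rng = np.random.default_rng(9)
        starts = rng.uniform(0, 20, (10, 2))
        steps = rng.normal(0, 0.1, (10, 2))
        a_pos = np.stack([starts, starts + steps], axis=1)
        b_pos = np.stack([starts, starts + 5 * steps], axis=1)
        a = tp.crr(_dense(a_pos), lags=[1], r_range=(1, 15), n_bins=8, fit=False)
        b = tp.crr(_dense(b_pos), lags=[1], r_range=(1, 15), n_bins=8, fit=False)
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-10, equal_nan=True)

    def test_drr_pair_symmetry_via_reversal(self, random_small_set):
        df = random_small_set.data.copy()
        df["id"] = df["id"].max() - df["id"]  # relabel: exchange members
        rev = TrajectorySet(df, frame_interval=1.0)
        a = tp.drr(random_small_set, lags=[1, 2], r_range=(1, 15), n_bins=8)
        b = tp.drr(rev, lags=[1, 2], r_range=(1, 15), n_bins=8)
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-12, equal_nan=True)


class TestPowerLawFit:
    def test_exact_inverse_r(self):
        r = np.linspace(3, 20, 40)
        alpha, r2, frac = tp.power_law_fit(r, 2.0 / r)
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)
        assert frac == 1.0

    def test_exact_inverse_r_squared(self):
        r = np.linspace(3, 20, 40)
        alpha, _, _ = tp.power_law_fit(r, 5.0 / r**2)
        assert alpha == pytest.approx(2.0, abs=1e-12)

    def test_too_few_positive_bins_raises(self):
        r = np.linspace(3, 20, 40)
        c = -np.ones(40)
        with pytest.raises(ValueError):
            tp.power_law_fit(r, c)
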