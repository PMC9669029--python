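"""Ensemble trajectory statistics: MSD, van Hove, NGP, kinematics.

Translational MSD follows 4 D_T tau^alpha = <dr^2>, rotational MSD
2 D_th tau^alpha = <dtheta^2>; the exponent alpha classifies sub-
(<1), normal (=1) and super- (>1) diffusion.  The non-Gaussian
parameter is evaluated with the 3/5 moment-ratio normalisation exactly
as used in the source analyses (the normalisation that vanishes for
3-D Gaussian steps; isotropic 2-D Gaussian steps give 0.2 and
fixed-magnitude steps give -0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import TrajectorySet

__all__ = [
    "MSDResult",
    "StepDistribution",
    "KinematicsResult",
    "msd",
    "van_hove",
    "ngp",
    "ngp_of_magnitudes",
    "kinematics",
    "steps_at_lag",
]


@dataclass
class MSDResult:
    lags: np.ndarray  # s
    msd: np.ndarray  # um^2 (translational) or rad^2 (rotational)
    counts: np.ndarray
    kind: str = "translational"
    alpha: float = np.nan
    coefficient: float = np.nan  # D_T (um^2/s^alpha) or D_theta (rad^2/s^alpha)
    fit_range: Optional[Tuple[float, float]] = None
    degenerate: bool = False


@dataclass
class StepDistribution:
    lag: float
    steps: np.ndarray
    bin_centers: np.ndarray
    density: np.ndarray
    gauss_mu: float
    gauss_sigma: float
    tail_fraction: float  # observed mass beyond 3 fitted sigma


@dataclass
class KinematicsResult:
    table: pd.DataFrame  # per trajectory: v_max, v_ee, L_myo, ratio, immobile
    slope: float  # least-squares slope of v_EE vs L_myo
    abs_slope: float
    intercept: float


def _unwrap_nematic(theta: np.ndarray) -> np.ndarray:
    """Accumulate axis angles treating theta and theta + pi as the same
    orientation: successive differences are mapped into (-pi/2, pi/2]."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) < 2:
        return theta.copy()
    d = np.diff(theta)
    d = -((-d + np.pi / 2) % np.pi - np.pi / 2)  # maps into (-pi/2, pi/2]
    return np.concatenate([[theta[0]], theta[0] + np.cumsum(d)])


def _per_traj_arrays(traj: TrajectorySet, kind: str, use_z: bool = False):
    """Yield (frames, values) per trajectory; values is (n, 2) or (n, 3)
    positions, or (n,) unwrapped angles."""
    pos_cols = ["x", "y", "z"] if use_z and "z" in traj.data.columns else ["x", "y"]
    for _, grp in traj.data.groupby("id"):
        frames = grp["frame"].to_numpy()
        if kind == "translational":
            vals = grp[pos_cols].to_numpy()
        else:
            vals = _unwrap_nematic(grp["theta"].to_numpy())
        yield frames, vals


def _diffs_at_lag(frames: np.ndarray, vals: np.ndarray, lag: int) -> np.ndarray:
    """Displacements over all (overlapping) windows of ``lag`` frames,
    respecting gaps in the frame index."""
    if len(frames) > lag and frames[-1] - frames[0] == len(frames) - 1:
        # contiguous frames: pure array slicing
        return vals[lag:] - vals[:-lag]
    lookup = {f: i for i, f in enumerate(frames)}
    pairs = [(i, lookup[f + lag]) for i, f in enumerate(frames) if f + lag in lookup]
    if not pairs:
        return np.empty((0,) + vals.shape[1:])
    ii, jj = map(np.asarray, zip(*pairs))
    return vals[jj] - vals[ii]


def steps_at_lag(
    traj: TrajectorySet, lag: int, kind: str = "translational"
) -> np.ndarray:
    """Step values at an integer frame lag: translational step
    magnitudes (um) or signed angular steps (rad)."""
    steps: List[np.ndarray] = []
    for frames, vals in _per_traj_arrays(traj, kind):
        d = _diffs_at_lag(frames, vals, lag)
        if len(d) == 0:
            continue
        steps.append(np.linalg.norm(d, axis=1) if d.ndim == 2 else d)
    if not steps:
        return np.empty(0)
    return np.concatenate(steps)


def msd(
    traj: TrajectorySet,
    kind: str = "translational",
    fit_range: Optional[Tuple[float, float]] = None,
    lags: Optional[Sequence[int]] = None,
    max_lag_frac: float = 2.0 / 3.0,
    use_z: bool = False,
) -> MSDResult:
    """Time-and-ensemble averaged MSD with a log-log power-law fit.

    Parameters
    ----------
    fit_range
        (tau_min, tau_max) in seconds for the exponent fit.  Defaults
        to all evaluated lags, which themselves span at most
        ``max_lag_frac`` of the longest trajectory (long lags have too
        few windows to be reliable).
    use_z
        Include a ``z`` column (if present) in the squared
        displacement, e.g. for simulated motors in a 3-D domain.
    """
    if kind not in ("translational", "rotational"):
        raise ValueError("kind must be 'translational' or 'rotational'")
    dt = traj.frame_interval
    span = int(traj.data["frame"].max() - traj.data["frame"].min())
    if lags is None:
        lags = np.arange(1, max(2, int(span * max_lag_frac)) + 1)
    lags = np.asarray(sorted(set(int(l) for l in lags if l > 0)))

    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    per_traj = list(_per_traj_arrays(traj, kind, use_z))
    for frames, vals in per_traj:
        for k, lag in enumerate(lags):
            d = _diffs_at_lag(frames, vals, lag)
            if len(d):
                sq = np.sum(d * d, axis=1) if d.ndim == 2 else d * d
                sums[k] += sq.sum()
                counts[k] += len(sq)
    valid = counts > 0
    curve = np.full(len(lags), np.nan)
    curve[valid] = sums[valid] / counts[valid]
    tau = lags * dt

    res = MSDResult(tau, curve, counts, kind=kind)
    prefactor = 4.0 if kind == "translational" else 2.0

    sel = valid & (curve > 0)
    if fit_range is not None:
        sel &= (tau >= fit_range[0]) & (tau <= fit_range[1])
        res.fit_range = tuple(fit_range)
    if sel.sum() < 4:
        res.degenerate = True
        return res
    fit = sstats.linregress(np.log(tau[sel]), np.log(curve[sel]))
    res.alpha = float(fit.slope)
    res.coefficient = float(np.exp(fit.intercept) / prefactor)
    return res


def van_hove(
    traj: TrajectorySet,
    lag: int = 1,
    kind: str = "translational",
    bins: int = 50,
) -> StepDistribution:
    """Distribution of step sizes at a lag, with a Gaussian reference
    fit; diffusive motion gives a Gaussian, caged or persistent motion
    deviates near the peak or in the tails."""
    steps = steps_at_lag(traj, lag, kind)
    if len(steps) < 100:
        import warnings

        warnings.warn(f"only {len(steps)} steps at lag {lag}; histogram unreliable")
    density, edges = np.histogram(steps, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu, sigma = float(np.mean(steps)), float(np.std(steps))
    if sigma == 0:
        tail = 0.0
    else:
        tail = float(np.mean(np.abs(steps - mu) > 3 * sigma))
    return StepDistribution(
        lag=lag * traj.frame_interval,
        steps=steps,
        bin_centers=centers,
        density=density,
        gauss_mu=mu,
        gauss_sigma=sigma,
        tail_fraction=tail,
    )


def ngp_of_magnitudes(r: np.ndarray) -> float:
    """NGP(tau) = 3<r^4> / (5 <r^2>^2) - 1 on displacement magnitudes."""
    r = np.asarray(r, dtype=float)
    m2 = np.mean(r**2)
    if m2 == 0:
        return np.nan
    return float(3 * np.mean(r**4) / (5 * m2**2) - 1)


def ngp(
    traj: TrajectorySet, lags: Sequence[int], kind: str = "translational"
) -> pd.DataFrame:
    """Non-Gaussian parameter versus lag time."""
    rows = []
    for lag in lags:
        steps = steps_at_lag(traj, int(lag), kind)
        val = ngp_of_magnitudes(np.abs(steps)) if len(steps) else np.nan
        rows.append({"lag": lag * traj.frame_interval, "ngp": val, "n": len(steps)})
    return pd.DataFrame(rows)


def kinematics(
    traj: TrajectorySet,
    immobile_floor: float = 0.1,
) -> KinematicsResult:
    """Per-trajectory speeds and the speed-length relation.

    v_max is the maximum instantaneous speed, v_EE the end-to-end
    distance over the total time; trajectories whose consecutive
    displacements never exceed ``immobile_floor`` (um, the pixel
    resolution) are flagged immobile.  Reports the least-squares slope
    of v_EE against filament length L_myo and its absolute value.
    """
    dt = traj.frame_interval
    rows = []
    for pid, grp in traj.data.groupby("id"):
        if len(grp) < 2:
            continue
        xy = grp[["x", "y"]].to_numpy()
        t = grp["t"].to_numpy()
        disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        dts = np.diff(t)
        v_inst = disp / dts
        total_t = t[-1] - t[0]
        v_ee = float(np.linalg.norm(xy[-1] - xy[0]) / total_t)
        l_myo = float(grp["length"].mean())
        rows.append(
            {
                "id": pid,
                "v_max": float(v_inst.max()),
                "v_ee": v_ee,
                "L_myo": l_myo,
                "v_ee_per_length": v_ee / l_myo,
                "immobile": bool(np.all(disp < immobile_floor)),
                "n_samples": len(grp),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["L_myo"].nunique() > 1:
        fit = sstats.linregress(table["L_myo"], table["v_ee"])
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = np.nan, np.nan
    return KinematicsResult(
        table=table, slope=slope, abs_slope=abs(slope), intercept=intercept
    )
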