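"""Two-point displacement correlations of tracked thick filaments.

For every ordered pair (i != j) coexisting at a start time t with lag
tau, both displacement vectors are projected onto the unit separation
vector at t; the product is accumulated into the radial bin of the
start-time separation R_ij(t):

    D_rr(r, tau) = < dr_i,par(t, tau) dr_j,par(t, tau) delta[r - R_ij(t)] >

The normalised variant C_rr divides each pair product by the product of
the two displacement magnitudes before bin-averaging, and the reported
C_rr(r) averages the 10 smallest lags.  A 1/r decay of C_rr signals
coarse-grained continuum stress transmission; the exponent is obtained
from a log-log power-law fit over a configurable range (default
3-20 um, 40 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import TrajectorySet

__all__ = ["TPCResult", "drr", "crr", "power_law_fit"]


@dataclass
class TPCResult:
    lags: np.ndarray  # s
    r_centers: np.ndarray  # um
    matrix: np.ndarray  # (n_lags, n_bins) per-lag binned correlation
    counts: np.ndarray  # (n_lags, n_bins) pair counts
    profile: np.ndarray  # correlation vs r averaged over first 10 lags
    normalized: bool
    alpha: float = np.nan
    fit_r2: float = np.nan
    fit_range: Optional[Tuple[float, float]] = None
    positive_fraction: float = np.nan


def _frame_table(traj: TrajectorySet):
    """Per-frame arrays of (ids, positions) for pairwise evaluation."""
    out = {}
    for f, grp in traj.data.groupby("frame"):
        out[int(f)] = (grp["id"].to_numpy(), grp[["x", "y"]].to_numpy())
    return out


def _accumulate(
    traj: TrajectorySet,
    lags: Sequence[int],
    r_range: Tuple[float, float],
    n_bins: int,
    normalized: bool,
    magnitude_floor: float,
) -> TPCResult:
    frames = _frame_table(traj)
    edges = np.linspace(r_range[0], r_range[1], n_bins + 1)
    lags = np.asarray(sorted(set(int(l) for l in lags if l > 0)))
    sums = np.zeros((len(lags), n_bins))
    counts = np.zeros((len(lags), n_bins), dtype=np.int64)

    for li, lag in enumerate(lags):
        for f0, (ids0, pos0) in frames.items():
            nxt = frames.get(f0 + lag)
            if nxt is None:
                continue
            ids1, pos1 = nxt
            common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
            if len(common) < 2:
                continue
            p = pos0[i0]
            d = pos1[i1] - p
            iu, ju = np.triu_indices(len(common), k=1)
            sep = p[ju] - p[iu]
            dist = np.hypot(sep[:, 0], sep[:, 1])
            inr = (dist >= r_range[0]) & (dist < r_range[1]) & (dist > 0)
            if not inr.any():
                continue
            iu, ju, sep, dist = iu[inr], ju[inr], sep[inr], dist[inr]
            nhat = sep / dist[:, None]
            pi = np.einsum("pk,pk->p", d[iu], nhat)
            pj = np.einsum("pk,pk->p", d[ju], nhat)
            prod = pi * pj
            if normalized:
                mi = np.linalg.norm(d[iu], axis=1)
                mj = np.linalg.norm(d[ju], axis=1)
                ok = (mi > magnitude_floor) & (mj > magnitude_floor)
                if not ok.any():
                    continue
                prod = prod[ok] / (mi[ok] * mj[ok])
                dist = dist[ok]
            b = np.minimum(
                np.searchsorted(edges, dist, side="right") - 1, n_bins - 1
            )
            np.add.at(sums[li], b, prod)
            np.add.at(counts[li], b, 1)

    matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    first = min(10, len(lags))
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix[:first], axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TPCResult(
        lags=lags * traj.frame_interval,
        r_centers=centers,
        matrix=matrix,
        counts=counts,
        profile=profile,
        normalized=normalized,
    )


def drr(
    traj: TrajectorySet,
    lags: Sequence[int] = range(1, 11),
    r_range: Tuple[float, float] = (3.0, 20.0),
    n_bins: int = 40,
) -> TPCResult:
    """Unnormalised two-point displacement correlation D_rr(r, tau)."""
    if len(traj) < 2:
        raise ValueError("need at least 2 trajectories")
    return _accumulate(traj, lags, r_range, n_bins, False, 0.0)


def crr(
    traj: TrajectorySet,
    lags: Sequence[int] = range(1, 11),
    r_range: Tuple[float, float] = (3.0, 20.0),
    n_bins: int = 40,
    magnitude_floor: float = 1e-12,
    fit: bool = True,
) -> TPCResult:
    """Normalised two-point correlation C_rr with power-law fit.

    Pairs in which either displacement magnitude falls below
    ``magnitude_floor`` are excluded (the normalisation would diverge).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 trajectories")
    res = _accumulate(traj, lags, r_range, n_bins, True, magnitude_floor)
    if fit:
        try:
            alpha, r2, frac = power_law_fit(
                res.r_centers, res.profile, r_fit=r_range
            )
            res.alpha, res.fit_r2, res.positive_fraction = alpha, r2, frac
            res.fit_range = r_range
        except ValueError:
            pass
    return res


def power_law_fit(
    r: np.ndarray,
    c: np.ndarray,
    r_fit: Tuple[float, float] = (3.0, 20.0),
) -> Tuple[float, float, float]:
    """Fit C_rr ~ 1/r^alpha by least squares of log C vs log r.

    Returns (alpha, R^2 of the log-log fit, fraction of in-range bins
    with positive correlation).  Non-positive bins are excluded; fewer
    than 6 usable bins is an error.
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    inr = (r >= r_fit[0]) & (r <= r_fit[1]) & np.isfinite(c)
    if not inr.any():
        raise ValueError("no finite bins in fit range")
    pos = inr & (c > 0)
    frac = pos.sum() / inr.sum()
    if pos.sum() < 6:
        raise ValueError("fewer than 6 positive bins in fit range")
    fit = sstats.linregress(np.log(r[pos]), np.log(c[pos]))
    return float(-fit.slope), float(fit.rvalue**2), float(frac)
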