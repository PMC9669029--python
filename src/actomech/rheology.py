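"""One-point passive microrheology from tracer MSD curves.

The local log-slope alpha(tau) = d ln<dr^2>/d ln tau feeds the
algebraic form of the generalized Stokes-Einstein relation,

    |G*(w)| ~ k_B T / (pi a <dr^2(tau=1/w)> Gamma[1 + alpha(tau=1/w)]),

which assumes purely thermally driven fluctuations.  The formula is
dimension-agnostic as printed; with 2-D tracking MSDs it carries a
constant offset relative to the 3-D convention (4D tau vs 6D tau), so
the MSD convention used should be stated alongside results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.special import gamma as gamma_fn

from .trajstats import MSDResult

__all__ = ["RheoResult", "log_slope", "gser", "KB"]

KB = 1.380649e-23  # J/K


@dataclass
class RheoResult:
    omega: np.ndarray  # 1/s (w = 1/tau)
    g_mod: np.ndarray  # |G*| in Pa
    alpha: np.ndarray  # local log-slope at tau = 1/w
    lags: np.ndarray  # s
    bead_radius: float  # um
    temperature: float  # K


def _as_arrays(msd_curve: Union[MSDResult, Tuple[np.ndarray, np.ndarray]]):
    if isinstance(msd_curve, MSDResult):
        tau, m = msd_curve.lags, msd_curve.msd
    else:
        tau, m = msd_curve
    tau = np.asarray(tau, dtype=float)
    m = np.asarray(m, dtype=float)
    ok = np.isfinite(m) & (m > 0) & (tau > 0)
    return tau[ok], m[ok]


def log_slope(
    msd_curve: Union[MSDResult, Tuple[np.ndarray, np.ndarray]]
) -> Tuple[np.ndarray, np.ndarray]:
    """Local logarithmic slope of the MSD.

    Centered finite differences in (ln tau, ln MSD); the two boundary
    lags fall back to one-sided differences.  Returns (tau, alpha).
    """
    tau, m = _as_arrays(msd_curve)
    if len(tau) < 2:
        raise ValueError("need at least 2 positive MSD points")
    lt, lm = np.log(tau), np.log(m)
    alpha = np.gradient(lm, lt)
    return tau, alpha


def gser(
    msd_curve: Union[MSDResult, Tuple[np.ndarray, np.ndarray]],
    bead_radius: float = 0.25,
    temperature: float = 298.0,
    trim_frac: float = 2.0 / 3.0,
) -> RheoResult:
    """Complex-modulus magnitude |G*(w)| from a tracer MSD.

    Parameters
    ----------
    bead_radius
        Tracer radius in um (default 0.25, i.e. 0.5 um beads).
    temperature
        K.
    trim_frac
        Only the first fraction of lags is used; long lags average too
        few windows to be reliable.

    Lags where alpha <= -1 (pole of the gamma function) are masked.
    """
    tau, m = _as_arrays(msd_curve)
    n_keep = max(2, int(np.ceil(len(tau) * trim_frac)))
    tau, m = tau[:n_keep], m[:n_keep]
    _, alpha = log_slope((tau, m))
    msd_m2 = m * 1e-12  # um^2 -> m^2
    a_m = bead_radius * 1e-6
    with np.errstate(over="ignore", invalid="ignore"):
        gam = np.where(alpha > -1, gamma_fn(1 + np.clip(alpha, -0.999, None)), np.nan)
        g = KB * temperature / (np.pi * a_m * msd_m2 * gam)
    g = np.where(alpha > -1, g, np.nan)
    return RheoResult(
        omega=1.0 / tau,
        g_mod=g,
        alpha=alpha,
        lags=tau,
        bead_radius=bead_radius,
        temperature=temperature,
    )
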