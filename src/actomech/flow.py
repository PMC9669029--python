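"""PIV displacement fields, divergence strain, and Kelvin-Voigt fits.

The network deformation readout is the spatial-mean strain
<eps> = <div x_c> computed from cumulative PIV displacement fields;
negative strain means contraction.  Post-ablation relaxation is fitted
with the Kelvin-Voigt step response eps(t) = (sigma/E_v)(1 - exp(-t/tau_v)),
whose characteristic time tau_v = eta_v/E_v summarises network
viscoelasticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats as sstats

from .synthetic import kelvin_voigt
from .types import DisplacementField, ImageStack

__all__ = ["piv", "StrainSeries", "strain_series", "KVFit", "kv_fit"]


def _subpixel(c_m: float, c_0: float, c_p: float) -> float:
    """3-point Gaussian peak interpolation; ties between equal
    neighbours resolve to zero offset (smaller displacement)."""
    vals = np.array([c_m, c_0, c_p], dtype=float)
    if np.any(vals <= 0):
        # fall back to parabolic on shifted values
        vals = vals - vals.min() + 1e-12
    lm, l0, lp = np.log(vals)
    denom = 2 * (lm - 2 * l0 + lp)
    if denom == 0:
        return 0.0
    off = (lm - lp) / denom
    return float(np.clip(off, -1.0, 1.0))


def _window_correlation(wa: np.ndarray, wb: np.ndarray):
    """Overlap-normalized linear cross-correlation of two windows.

    Returns (corr, lag0) where ``corr[i, j]`` estimates the
    correlation coefficient of wb displaced by (i - lag0, j - lag0)
    relative to wa; normalising by the overlap count removes the
    triangular envelope that otherwise biases peaks toward zero lag.
    """
    from scipy.signal import fftconvolve

    win = wa.shape[0]
    wa = wa - wa.mean()
    wb = wb - wb.mean()
    corr = fftconvolve(wb, wa[::-1, ::-1], mode="full")
    lag = np.arange(-(win - 1), win)
    n_ov = np.maximum(
        (win - np.abs(lag))[:, None] * (win - np.abs(lag))[None, :], 1
    )
    sa, sb = wa.std(), wb.std()
    if sa == 0 or sb == 0:
        return None, 0
    corr = corr / (n_ov * sa * sb)
    return corr, win - 1


def piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 32,
    overlap: float = 0.5,
    min_corr: float = 0.3,
    search: Optional[int] = None,
) -> DisplacementField:
    """Single-pass cross-correlation PIV with sub-pixel peaks.

    Per window the overlap-normalized linear cross-correlation of the
    mean-subtracted contents gives the displacement of ``frame_b``
    relative to ``frame_a``; the search is limited to ``search`` px
    (default a quarter window, the usual single-pass displacement
    limit) and the peak is refined per axis with 3-point Gaussian
    interpolation.  Ties between equally high peaks resolve toward the
    smaller displacement.  Windows whose peak correlation coefficient
    falls below ``min_corr`` are masked (NaN).
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have equal shape")
    h, w = frame_a.shape
    if window > min(h, w):
        raise ValueError("window larger than image")
    step = max(1, int(round(window * (1.0 - overlap))))
    rows = np.arange(0, h - window + 1, step)
    cols = np.arange(0, w - window + 1, step)
    u = np.full((len(rows), len(cols)), np.nan)
    v = np.full((len(rows), len(cols)), np.nan)
    half = window // 4 if search is None else int(search)
    # tie-break toward smaller displacement: tiny penalty growing with |lag|
    lag1 = np.arange(-(window - 1), window)
    tie = 1e-9 * (np.abs(lag1)[:, None] + np.abs(lag1)[None, :])
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            wa = frame_a[r : r + window, c : c + window]
            wb = frame_b[r : r + window, c : c + window]
            corr, lag0 = _window_correlation(wa, wb)
            if corr is None:
                continue
            sl = slice(lag0 - half, lag0 + half + 1)
            sub = corr[sl, sl] - tie[sl, sl]
            pr, pc = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[pr, pc] < min_corr:
                continue
            spr, spc = pr + lag0 - half, pc + lag0 - half  # back to full corr
            if 0 < spr < corr.shape[0] - 1:
                dr = _subpixel(corr[spr - 1, spc], corr[spr, spc], corr[spr + 1, spc])
            else:
                dr = 0.0
            if 0 < spc < corr.shape[1] - 1:
                dc = _subpixel(corr[spr, spc - 1], corr[spr, spc], corr[spr, spc + 1])
            else:
                dc = 0.0
            v[i, j] = (pr - half) + dr
            u[i, j] = (pc - half) + dc
    return DisplacementField(
        x=cols + window / 2.0,
        y=rows + window / 2.0,
        u=u,
        v=v,
        window=window,
        overlap=overlap,
    )


@dataclass
class StrainSeries:
    t: np.ndarray  # s
    mean_strain: np.ndarray  # <eps>(t), cumulative, <eps>(0) = 0
    rms_strain: np.ndarray
    eps_max: float  # signed extremum of <eps>
    abs_eps_max: float
    strain_rate: float  # d<eps>/dt over the 10%-80% rise window
    gaps: np.ndarray  # frame indices whose field was interpolated


def strain_series(
    stack: ImageStack,
    window: int = 32,
    overlap: float = 0.5,
    min_corr: float = 0.3,
    cumulative: bool = True,
) -> StrainSeries:
    """Mean divergence strain of a movie from consecutive-frame PIV.

    Consecutive-frame displacement fields are accumulated into a
    cumulative displacement (so <eps>(t) is a strain relative to frame
    0, matching the Kelvin-Voigt step-response convention); divergence
    is taken by central differences on the window grid.  The strain
    rate is a linear fit over the contiguous window in which |<eps>|
    rises from 10% to 80% of its extremum.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames")
    n = stack.n_frames
    dt = stack.frame_interval
    cum_u = cum_v = None
    mean_eps = [0.0]
    rms_eps = [0.0]
    gaps = []
    prev_div = 0.0
    prev_rms = 0.0
    for k in range(n - 1):
        field = piv(
            stack.frames[k], stack.frames[k + 1], window, overlap, min_corr
        )
        if np.all(np.isnan(field.u)):
            gaps.append(k + 1)
            mean_eps.append(mean_eps[-1] + prev_div)
            rms_eps.append(prev_rms)
            continue
        u = np.nan_to_num(field.u, nan=np.nanmean(field.u))
        v = np.nan_to_num(field.v, nan=np.nanmean(field.v))
        if cum_u is None:
            cum_u = np.zeros_like(u)
            cum_v = np.zeros_like(v)
        if cumulative:
            cum_u += u
            cum_v += v
            du, dv = cum_u, cum_v
        else:
            du, dv = u, v
        f = DisplacementField(field.x, field.y, du, dv, window, overlap)
        div = f.divergence()
        prev_div = float(np.mean(div) - (mean_eps[-1] if cumulative else 0.0))
        mean_eps.append(float(np.mean(div)))
        rms_eps.append(float(np.sqrt(np.mean(div**2))))
        prev_rms = rms_eps[-1]
    mean_eps = np.asarray(mean_eps)
    rms_eps = np.asarray(rms_eps)
    t = np.arange(n) * dt

    abs_eps = np.abs(mean_eps)
    i_max = int(np.argmax(abs_eps))
    eps_max = float(mean_eps[i_max])
    rate = np.nan
    if abs_eps[i_max] > 0:
        lo, hi = 0.1 * abs_eps[i_max], 0.8 * abs_eps[i_max]
        rising = np.where((abs_eps[: i_max + 1] >= lo) & (abs_eps[: i_max + 1] <= hi))[0]
        if len(rising) >= 2:
            fit = sstats.linregress(t[rising], mean_eps[rising])
            rate = float(fit.slope)
    return StrainSeries(
        t=t,
        mean_strain=mean_eps,
        rms_strain=rms_eps,
        eps_max=eps_max,
        abs_eps_max=abs(eps_max),
        strain_rate=rate,
        gaps=np.asarray(gaps, dtype=int),
    )


@dataclass
class KVFit:
    amplitude: float  # sigma / E_v
    tau_v: float  # s
    r_squared: float
    degenerate: bool = False


def kv_fit(
    t: np.ndarray,
    eps: np.ndarray,
    t_start: float = 0.0,
) -> KVFit:
    """Bounded least-squares fit of the Kelvin-Voigt step response.

    ``t_start`` discards the earliest samples (e.g. pre-ablation
    frames); time is re-zeroed at the first retained sample.  A series
    with no rising phase is flagged degenerate.
    """
    t = np.asarray(t, dtype=float)
    eps = np.asarray(eps, dtype=float)
    sel = t >= t_start
    t, eps = t[sel] - t[sel][0], eps[sel]
    if len(t) < 4:
        raise ValueError("too few samples for a Kelvin-Voigt fit")
    span = float(np.max(np.abs(eps)))
    if span == 0 or np.max(np.abs(eps[len(eps) // 2 :])) < 1e-12:
        return KVFit(0.0, np.nan, np.nan, degenerate=True)
    sign = np.sign(eps[np.argmax(np.abs(eps))])
    y = eps * sign  # fit on the rising branch
    p0 = (max(y.max(), 1e-9), max(t[-1] / 5, t[1] - t[0]))
    try:
        popt, _ = optimize.curve_fit(
            kelvin_voigt,
            t,
            y,
            p0=p0,
            bounds=([0, 1e-9], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return KVFit(np.nan, np.nan, np.nan, degenerate=True)
    resid = y - kelvin_voigt(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return KVFit(float(popt[0] * sign), float(popt[1]), r2)
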