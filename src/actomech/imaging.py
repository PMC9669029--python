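"""Structure metrics from fluorescence images.

Covers the image-based readouts of network architecture: movie
preprocessing (smoothing, background subtraction, bleach correction,
registration), windowed-FFT local orientation and the nematic order
parameter n = 2<cos^2(theta_d) - 1/2>, pore-size statistics, the
radial distribution function with its exponential decay length, and
pixel-fluctuation temporal autocorrelation with a double-exponential
fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize
from skimage import measure, morphology
from skimage.registration import phase_cross_correlation

from .types import ImageStack, wrap_nematic

__all__ = [
    "preprocess",
    "OrientationField",
    "orientation_field",
    "OrderMap",
    "nematic_order",
    "PoreStats",
    "pore_sizes",
    "RDFResult",
    "radial_distribution",
    "AutocorrFit",
    "fluctuation_autocorr",
    "intensity_timecourse",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    stack: ImageStack,
    smooth_width: float = 0.1,
    bg_width: float = 0.5,
    register: bool = True,
    bleach_correct: bool = True,
) -> ImageStack:
    """Standard movie conditioning before tracking or correlation.

    1. Gaussian smoothing at ``smooth_width`` (um).
    2. Rolling background subtraction at ``bg_width`` (um): a
       morphological opening with a disk of that radius is removed.
    3. Simple-ratio bleach correction: each frame is scaled so its
       mean matches frame 0.
    4. Translation-only registration to frame 0 by phase
       cross-correlation.
    """
    px = stack.pixel_size
    sig = smooth_width / px
    bg_r = max(1, int(round(bg_width / px)))
    selem = morphology.disk(bg_r)
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        f = ndimage.gaussian_filter(frame, sig)
        f = f - morphology.opening(f, selem)
        out[i] = f
    if bleach_correct:
        ref_mean = out[0].mean()
        if ref_mean == 0:
            raise ValueError("frame 0 has zero mean; cannot bleach-correct")
        for i in range(len(out)):
            m = out[i].mean()
            if m == 0:
                raise ValueError(f"frame {i} has zero mean; cannot bleach-correct")
            out[i] *= ref_mean / m
    if register:
        for i in range(1, len(out)):
            shift, _, _ = phase_cross_correlation(
                out[0], out[i], upsample_factor=10, normalization=None
            )
            out[i] = ndimage.shift(out[i], shift, order=1, mode="nearest")
    return ImageStack(
        out,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        channel=stack.channel,
    )


# ---------------------------------------------------------------------------
# Local orientation and nematic order
# ---------------------------------------------------------------------------


@dataclass
class OrientationField:
    centers_x: np.ndarray  # um, window-centre columns
    centers_y: np.ndarray  # um, window-centre rows
    angles: np.ndarray  # rad in [-pi/2, pi/2), NaN = masked
    window_um: float
    overlap: float


@dataclass
class OrderMap:
    order: np.ndarray  # local nematic order, NaN = masked
    mean: float


def _window_orientation(win: np.ndarray, sigma_px: float) -> float:
    """Axis angle of a window from second moments of its Fourier power
    spectrum; the spectrum elongates perpendicular to the real-space
    texture, so the result is rotated by 90 degrees."""
    w = ndimage.gaussian_filter(win, sigma_px)
    w = w - w.mean()
    if np.allclose(w, 0):
        return np.nan
    # apodize to suppress spectral leakage along the array axes, which
    # otherwise biases the moment-based orientation by several degrees
    hann_r = np.hanning(w.shape[0])[:, None]
    hann_c = np.hanning(w.shape[1])[None, :]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(w * hann_r * hann_c))) ** 2
    rows, cols = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]].astype(float)
    tot = spec.sum()
    r0 = (rows * spec).sum() / tot
    c0 = (cols * spec).sum() / tot
    mu20 = ((cols - c0) ** 2 * spec).sum() / tot
    mu02 = ((rows - r0) ** 2 * spec).sum() / tot
    mu11 = ((cols - c0) * (rows - r0) * spec).sum() / tot
    if mu20 == mu02 and mu11 == 0:
        return np.nan
    # long axis (least second moment) of the spectrum, then rotate 90 deg
    axis = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return float(wrap_nematic(axis + np.pi / 2))


def orientation_field(
    image: np.ndarray,
    pixel_size: float,
    window_um: float = 3.5,
    overlap: float = 0.8,
    smooth_sigma_px: float = 1.0,
) -> OrientationField:
    """Local texture-axis angles on a grid of overlapping windows.

    Windows that do not fit completely inside the image are dropped
    (padding would bias the spectrum moments); zero-variance windows
    are masked (NaN).
    """
    win_px = int(round(window_um / pixel_size))
    step = max(1, int(round(win_px * (1.0 - overlap))))
    h, w = image.shape
    if win_px > min(h, w):
        raise ValueError("image smaller than one analysis window")
    rows = np.arange(0, h - win_px + 1, step)
    cols = np.arange(0, w - win_px + 1, step)
    angles = np.full((len(rows), len(cols)), np.nan)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            angles[i, j] = _window_orientation(
                image[r : r + win_px, c : c + win_px], smooth_sigma_px
            )
    cy = (rows + win_px / 2) * pixel_size
    cx = (cols + win_px / 2) * pixel_size
    return OrientationField(cx, cy, angles, window_um, overlap)


def nematic_order(field: OrientationField) -> OrderMap:
    """Local nematic order n = 2<cos^2(theta_d) - 1/2> over the angle
    differences theta_d between each interior window and its 8
    neighbours; masked neighbours are excluded, fully masked kernels
    are masked.  Perfect alignment gives n = 1, an alternating 0/90
    checkerboard gives n = -1."""
    a = field.angles
    nr, nc = a.shape
    if nr < 3 or nc < 3:
        raise ValueError("need at least a 3x3 window grid")
    out = np.full((nr - 2, nc - 2), np.nan)
    for i in range(1, nr - 1):
        for j in range(1, nc - 1):
            c = a[i, j]
            if np.isnan(c):
                continue
            neigh = np.concatenate(
                [a[i - 1, j - 1 : j + 2], a[i, [j - 1, j + 1]], a[i + 1, j - 1 : j + 2]]
            )
            neigh = neigh[~np.isnan(neigh)]
            if len(neigh) == 0:
                continue
            d = neigh - c
            out[i - 1, j - 1] = 2 * np.mean(np.cos(d) ** 2 - 0.5)
    mean = float(np.nanmean(out)) if np.isfinite(out).any() else np.nan
    return OrderMap(order=out, mean=mean)


# ---------------------------------------------------------------------------
# Pore sizes and radial distribution
# ---------------------------------------------------------------------------


@dataclass
class PoreStats:
    areas: np.ndarray  # um^2
    mean: float
    threshold: float


def pore_sizes(image: np.ndarray, pixel_size: float) -> PoreStats:
    """Closed-pore areas of a binarized network image.

    The frame is thresholded at its mean intensity; 8-connected dark
    components fully enclosed by bright pixels (i.e. not touching the
    image border) are pores.
    """
    thr = float(image.mean())
    bright = image > thr
    if bright.all() or (~bright).all():
        warnings.warn("image entirely dark or bright; no pores measurable")
        return PoreStats(np.empty(0), np.nan, thr)
    dark = ~bright
    labels = measure.label(dark, connectivity=2)
    border = np.unique(
        np.concatenate(
            [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
        )
    )
    areas = []
    for region in measure.regionprops(labels):
        if region.label in border:
            continue
        areas.append(region.area * pixel_size**2)
    areas = np.asarray(areas)
    mean = float(areas.mean()) if len(areas) else np.nan
    return PoreStats(areas, mean, thr)


@dataclass
class RDFResult:
    r: np.ndarray  # um, bin centres
    g: np.ndarray  # circumference-averaged white-pixel counts
    amplitude: float  # A of the exponential fit A exp(-r/lambda)
    decay_length: float  # lambda, um


def radial_distribution(
    image: np.ndarray,
    pixel_size: float,
    dr: float = 0.2,
    r_max: float = 5.0,
    center_subsample: int = 2000,
    seed: int = 0,
) -> RDFResult:
    """Radial distribution of white pixels around white-pixel centres.

    The image is binarized at its mean; for each (optionally
    subsampled) white-pixel centre the number of white pixels between
    r and r+dr is counted and divided by the ring circumference.  The
    profile is fitted with A exp(-r/lambda); lambda is the structural
    correlation length.
    """
    if dr >= r_max:
        raise ValueError("dr must be smaller than r_max")
    bright = image > image.mean()
    coords = np.column_stack(np.nonzero(bright)).astype(float) * pixel_size
    if len(coords) < 100:
        raise ValueError(f"only {len(coords)} white pixels; need >= 100")
    # centres keep a margin of r_max from the borders so every ring is
    # complete; incomplete rings would bias g(r) downward at large r
    h_um = image.shape[0] * pixel_size
    w_um = image.shape[1] * pixel_size
    interior = (
        (coords[:, 0] >= r_max)
        & (coords[:, 0] <= h_um - r_max)
        & (coords[:, 1] >= r_max)
        & (coords[:, 1] <= w_um - r_max)
    )
    eligible = coords[interior] if interior.sum() >= 100 else coords
    rng = np.random.default_rng(seed)
    if center_subsample and len(eligible) > center_subsample:
        centers = eligible[rng.choice(len(eligible), center_subsample, replace=False)]
    else:
        centers = eligible
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    chunk = 200
    for s in range(0, len(centers), chunk):
        d = np.linalg.norm(
            centers[s : s + chunk, None, :] - coords[None, :, :], axis=2
        )
        h, _ = np.histogram(d.ravel(), bins=edges)
        counts += h
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    circumference = 2 * np.pi * centers_r * dr
    g = counts / (len(centers) * circumference)
    ok = (centers_r > 0) & (g > 0)
    p0 = (g[ok][0], max(centers_r[ok][-1] / 3, dr))
    try:
        popt, _ = optimize.curve_fit(
            lambda r, A, lam: A * np.exp(-r / lam),
            centers_r[ok],
            g[ok],
            p0=p0,
            maxfev=10000,
        )
        amp, lam = float(popt[0]), float(popt[1])
    except RuntimeError:
        amp, lam = np.nan, np.nan
    return RDFResult(centers_r, g, amp, lam)


# ---------------------------------------------------------------------------
# Temporal fluctuation autocorrelation
# ---------------------------------------------------------------------------


@dataclass
class AutocorrFit:
    lags: np.ndarray  # s
    correlation: np.ndarray  # normalized to 1 at lag 0
    a1: float  # weight of the tau_fast component, in [0, 1]
    tau_fast: float  # s
    tau_slow: float  # s
    offset: float  # a4
    time_constant: float  # reported: the larger of the two


def _double_exp(t, a1, t1, t2, a4):
    return a1 * np.exp(-t / t1) + (1 - a1) * np.exp(-t / t2) + a4


def fluctuation_autocorr(
    stack: ImageStack,
    max_lag_frac: float = 0.5,
    fit_frac: float = 0.4,
) -> AutocorrFit:
    """Pixel-fluctuation temporal autocorrelation with a
    double-exponential fit.

    For each lag the mean-subtracted frames t and t+lag are multiplied
    pixel-wise and averaged over all valid start frames; the curve is
    normalized by lag 0 and fitted with
    a1*exp(-t/a2) + (1-a1)*exp(-t/a3) + a4 over the first ``fit_frac``
    of lags (long lags have too few frame pairs).  The larger time
    constant is the reported network timescale; the smaller one
    absorbs fast processes such as monomer-aggregate diffusion.
    """
    if stack.n_frames < 20:
        raise ValueError("need at least 20 frames")
    fl = stack.frames - stack.frames.mean(axis=(1, 2), keepdims=True)
    n = stack.n_frames
    max_lag = max(2, int(n * max_lag_frac))
    lags = np.arange(0, max_lag + 1)
    corr = np.empty(len(lags))
    for k, lag in enumerate(lags):
        corr[k] = np.mean(fl[: n - lag] * fl[lag:] if lag else fl * fl)
    if corr[0] == 0:
        raise ValueError("zero variance at lag 0")
    corr = corr / corr[0]
    t = lags * stack.frame_interval

    n_fit = max(5, int(len(lags) * fit_frac))
    tf, cf = t[:n_fit], corr[:n_fit]
    t_scale = max(tf[-1] / 3, stack.frame_interval)
    # single-exponential prefit for initial guesses
    try:
        pre, _ = optimize.curve_fit(
            lambda x, tau: np.exp(-x / tau), tf, cf, p0=(t_scale,), maxfev=5000
        )
        tau0 = abs(float(pre[0]))
    except RuntimeError:
        tau0 = t_scale
    eps = stack.frame_interval * 1e-3
    # multi-start: a near-degenerate single-exponential start first, a
    # split two-timescale start second.  The split solution is kept
    # only if it improves the residual meaningfully; otherwise the
    # double-exponential would overfit sampling noise by drifting one
    # time constant away from a genuinely single-exponential truth.
    best = None
    for k, p0 in enumerate([(0.95, tau0, tau0, 0.0), (0.7, tau0 / 3, tau0 * 3, 0.0)]):
        try:
            popt, _ = optimize.curve_fit(
                _double_exp,
                tf,
                cf,
                p0=p0,
                bounds=([0, eps, eps, -1], [1, np.inf, np.inf, 1]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((_double_exp(tf, *popt) - cf) ** 2))
        if best is None or ssr < best[0] * 0.95:
            best = (ssr, popt)
    if best is None:
        a1, t1, t2, a4 = np.nan, np.nan, np.nan, np.nan
    else:
        a1, t1, t2, a4 = map(float, best[1])
    # order the components by time constant, keeping each one's weight;
    # a component with negligible weight has an unconstrained time
    # constant, so the other one is reported for both roles
    comps = sorted([(t1, a1), (t2, 1 - a1)])
    if comps[0][1] <= 1e-3 and np.isfinite(comps[1][0]):
        comps[0] = comps[1]
    if comps[1][1] <= 1e-3 and np.isfinite(comps[0][0]):
        comps[1] = comps[0]
    return AutocorrFit(
        lags=t,
        correlation=corr,
        a1=comps[0][1],
        tau_fast=comps[0][0],
        tau_slow=comps[1][0],
        offset=a4,
        time_constant=comps[1][0],
    )


def intensity_timecourse(stack: ImageStack) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized network fluorescence I/I0: per-frame mean intensity
    over the frame-0 mean (used to follow debranching)."""
    means = stack.frames.mean(axis=(1, 2))
    if means[0] == 0:
        raise ValueError("frame 0 has zero mean intensity")
    t = np.arange(stack.n_frames) * stack.frame_interval
    return t, means / means[0]
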