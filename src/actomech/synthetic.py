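"""Synthetic-data generators with known ground truth.

Every downstream stage (tracking, MSD/NGP statistics, two-point
correlation, PIV strain, microrheology, imaging metrics) can be
validated against inputs produced here, so no experimental data is
required.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numpy.fft import fft, ifft

from .types import ImageStack, TrajectorySet, wrap_nematic

__all__ = [
    "gen_brownian",
    "gen_fbm",
    "gen_correlated_field",
    "gen_image",
    "gen_kv_strain",
    "gen_correlated_stack",
    "gen_spot_movie",
    "gen_flow_movie",
    "FieldRealization",
    "kelvin_voigt",
]

#: Experimental thick-filament length range (um) used as the default
#: uniform length distribution for generated trajectories.
LENGTH_RANGE = (0.2, 1.5)


def _lengths_and_angles(rng: np.random.Generator, n: int):
    theta = rng.uniform(-np.pi / 2, np.pi / 2, n)
    lengths = rng.uniform(*LENGTH_RANGE, n)
    return theta, lengths


def gen_brownian(
    n_traj: int,
    n_steps: int,
    dt: float,
    D: float,
    seed: int = 0,
    origin_span: float = 0.0,
) -> TrajectorySet:
    """Free 2-D Brownian trajectories with per-axis increment variance
    ``2 D dt`` (ensemble MSD = 4 D tau).

    Axis angles are frozen per trajectory, uniform on [-pi/2, pi/2).
    ``origin_span`` scatters starting points uniformly in a square of
    that side length (0 = all at the origin).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2 * D * dt), (n_traj, n_steps - 1, 2))
    pos = np.zeros((n_traj, n_steps, 2))
    pos[:, 1:] = np.cumsum(steps, axis=1)
    if origin_span > 0:
        pos += rng.uniform(0, origin_span, (n_traj, 1, 2))
    theta, lengths = _lengths_and_angles(rng, n_traj)
    return TrajectorySet.from_arrays(pos, dt, theta=theta, lengths=lengths)


def _fgn_davies_harte(
    rng: np.random.Generator, hurst: float, n: int, size: Tuple[int, ...]
) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Returns increments with Var = 1 per unit step; the covariance is
    exact (no autoregressive approximation).  Output shape is
    ``size + (n,)``.
    """
    k = np.arange(n + 1)
    # fGn autocovariance for unit-variance increments
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n
    eig = fft(row).real
    # Davies-Harte eigenvalues are non-negative for fGn; clip tiny negatives
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    n_series = int(np.prod(size)) if size else 1
    out = np.empty((n_series, n))
    for i in range(n_series):
        z = rng.normal(size=m) + 1j * rng.normal(size=m)
        w = ifft(np.sqrt(eig) * z) * np.sqrt(m)
        out[i] = w.real[:n] / np.sqrt(2)
    return out.reshape(size + (n,))


def gen_fbm(
    n_traj: int,
    n_steps: int,
    dt: float,
    hurst: float,
    scale: float = 1.0,
    seed: int = 0,
) -> TrajectorySet:
    """2-D fractional Brownian motion; each axis an independent fBm.

    Per-axis variance at lag tau is ``scale**2 * tau**(2H)`` so the
    ensemble 2-D MSD is ``2 * scale**2 * tau**(2H)`` and the fitted
    log-log exponent converges to ``2 * hurst``.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    incr = _fgn_davies_harte(rng, hurst, n_steps - 1, (n_traj, 2))
    incr = incr * scale * dt**hurst
    pos = np.zeros((n_traj, n_steps, 2))
    pos[:, 1:, :] = np.cumsum(incr, axis=2).transpose(0, 2, 1)
    theta, lengths = _lengths_and_angles(rng, n_traj)
    return TrajectorySet.from_arrays(pos, dt, theta=theta, lengths=lengths)


# ---------------------------------------------------------------------------
# Correlated displacement field (point-force superposition)
# ---------------------------------------------------------------------------


@dataclass
class FieldRealization:
    """Tracer positions plus per-epoch displacement vectors whose
    longitudinal pair covariance decays as 1/r.

    Displacements are the superposed in-plane responses to random 3-D
    point forces through a Stokeslet-form kernel (unit viscosity),
    re-drawn independently every epoch (temporally white forcing).
    """

    positions: np.ndarray  # (n_particles, 2) um, in the z = Lz/2 plane
    displacements: np.ndarray  # (n_epochs, n_particles, 2) um
    box_size: Tuple[float, float, float]
    kernel_exponent: float = 1.0  # prescribed covariance decay ~ 1/r

    def to_trajectories(self, dt: float = 1.0) -> TrajectorySet:
        """Integrate the epoch displacements into trajectories whose
        lag-1 steps are exactly the epoch fields."""
        n_epochs, n_part, _ = self.displacements.shape
        pos = np.empty((n_part, n_epochs + 1, 2))
        pos[:, 0] = self.positions
        pos[:, 1:] = self.positions[:, None, :] + np.cumsum(
            self.displacements, axis=0
        ).transpose(1, 0, 2)
        return TrajectorySet.from_arrays(pos, dt)

    def longitudinal_covariance(
        self, r_edges: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Brute-force pair-averaged longitudinal covariance
        <(u_i . n_ij)(u_j . n_ij)> binned by separation.

        This is the independent oracle the generator must satisfy
        (decay ~ 1/r) before it is used to validate the two-point
        correlation pipeline.
        """
        p = self.positions
        n = len(p)
        iu, ju = np.triu_indices(n, k=1)
        sep = p[ju] - p[iu]
        dist = np.linalg.norm(sep, axis=1)
        nhat = sep / dist[:, None]
        prods = np.zeros(len(iu))
        for u in self.displacements:
            prods += np.einsum("pk,pk->p", u[iu], nhat) * np.einsum(
                "pk,pk->p", u[ju], nhat
            )
        prods /= len(self.displacements)
        idx = np.digitize(dist, r_edges) - 1
        nb = len(r_edges) - 1
        cov = np.full(nb, np.nan)
        for b in range(nb):
            m = idx == b
            if m.any():
                cov[b] = prods[m].mean()
        centers = 0.5 * (r_edges[:-1] + r_edges[1:])
        return centers, cov


def _stokeslet_response(
    targets3: np.ndarray, sources: np.ndarray, forces: np.ndarray, d_min: float
) -> np.ndarray:
    """In-plane response of plane tracers to 3-D point forces.

    u_i = (F_i + (F.n)n_i) / (8 pi d), unit viscosity; distances below
    ``d_min`` are clipped to keep near-field responses finite.
    """
    diff = targets3[:, None, :] - sources[None, :, :]  # (P, S, 3)
    d = np.linalg.norm(diff, axis=2)
    d = np.maximum(d, d_min)
    nhat = diff / d[..., None]
    fdotn = np.einsum("psk,sk->ps", nhat, forces)
    u = (forces[None, :, :] + fdotn[..., None] * nhat) / (8 * np.pi * d[..., None])
    return u.sum(axis=1)[:, :2]


def gen_correlated_field(
    n_particles: int = 250,
    n_epochs: int = 2000,
    box_size: Tuple[float, float, float] = (60.0, 60.0, 30.0),
    amplitude: float = 1e-4,
    self_variance_factor: float = 1.05,
    mode: str = "thermal",
    n_sources: int = 100,
    dipole_separation: float = 2.0,
    seed: int = 0,
    d_min: float = 1.0,
) -> FieldRealization:
    """Tracers in the mid-height plane of a 3-D box whose per-epoch
    displacements carry a prescribed 1/r longitudinal pair covariance.

    ``mode='thermal'`` (default): epochs are drawn from a multivariate
    Gaussian whose inter-particle covariance is the unit-viscosity
    Stokeslet (Oseen) tensor, amplitude * (I + n n^T)/(8 pi r) -- the
    thermal two-point correlation of a viscous continuum, which decays
    exactly as 1/r.  The self-variance is set to
    ``self_variance_factor`` times the magnitude of the most negative
    eigenvalue of the interaction matrix: the smallest diagonal that
    keeps the covariance positive definite, i.e. the strongest
    admissible pair correlation.

    ``mode='sources'``: epochs superpose in-plane responses of
    ``n_sources`` random point-force dipoles (pairs of opposite unit
    Stokeslets ``dipole_separation`` apart; net-force-free forcing, as
    for motors acting as force dipoles).  Its covariance also decays
    ~1/r, but the normalized C_rr of this heavy-tailed field is biased
    shallow; it is kept for cross-checks.

    ``mode='independent'``: i.i.d. displacements (kernel off), the
    null case with C_rr -> 0 at all r.

    In every mode sources/epochs are i.i.d. (temporally white
    forcing), and the realized covariance should be verified with the
    brute-force oracle ``FieldRealization.longitudinal_covariance``.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = box_size
    pos = np.column_stack(
        [rng.uniform(0, lx, n_particles), rng.uniform(0, ly, n_particles)]
    )
    if mode == "thermal":
        n2 = 2 * n_particles
        C = np.zeros((n2, n2))
        d = pos[None, :, :] - pos[:, None, :]
        r = np.linalg.norm(d, axis=2)
        for i in range(n_particles):
            for j in range(n_particles):
                if i == j:
                    continue
                nh = d[i, j] / r[i, j]
                C[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = (
                    np.eye(2) + np.outer(nh, nh)
                ) / (8 * np.pi * max(r[i, j], d_min))
        lam_min = np.linalg.eigvalsh(C)[0]
        C[np.arange(n2), np.arange(n2)] = self_variance_factor * abs(lam_min)
        C *= amplitude
        L = np.linalg.cholesky(C)
        z = rng.normal(size=(n_epochs, n2))
        disp = (z @ L.T).reshape(n_epochs, n_particles, 2)
    elif mode == "sources":
        if n_sources <= 0:
            raise ValueError("n_sources must be positive (zero field is degenerate)")
        targets3 = np.column_stack([pos, np.full(n_particles, lz / 2)])
        disp = np.empty((n_epochs, n_particles, 2))
        for e in range(n_epochs):
            src = rng.uniform([0, 0, 0], [lx, ly, lz], (n_sources, 3))
            axis = rng.normal(size=(n_sources, 3))
            axis /= np.linalg.norm(axis, axis=1)[:, None]
            f = rng.normal(size=(n_sources, 3))
            f *= amplitude / np.linalg.norm(f, axis=1)[:, None]
            half = 0.5 * dipole_separation * axis
            disp[e] = _stokeslet_response(
                targets3, src + half, f, d_min
            ) + _stokeslet_response(targets3, src - half, -f, d_min)
    elif mode == "independent":
        disp = rng.normal(0, amplitude, (n_epochs, n_particles, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FieldRealization(pos, disp, box_size)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def gen_image(
    pattern: str,
    size_px: int = 256,
    pixel_size: float = 0.1,
    params: Optional[Dict] = None,
    seed: int = 0,
    n_frames: int = 1,
) -> ImageStack:
    """Reproducible synthetic intensity images.

    Patterns
    --------
    ``stripes``: sinusoidal stripes; params ``angle`` (rad, axis of the
        stripes, math convention with y up) and ``period`` (px).
    ``random_filaments``: random straight segments blurred to a
        filamentous texture; params ``density`` (segments per kpx^2),
        ``length`` (px).
    ``porous``: bright background with dark rectangular pores; params
        ``pores`` = list of (row, col, h, w) pixel footprints.
    ``checkerboard_orientations``: tiles of stripes with alternating
        orientations; params ``angles`` (pair, rad), ``tile`` (px),
        ``period`` (px).
    ``tiled_noise``: random texture tiled with period ``tile`` px
        (exactly periodic; useful for translation-invariance checks).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:size_px, 0:size_px].astype(float)
    # angles are measured in the array frame: x along columns, y along rows
    x, y = cols, rows

    def stripes(angle, period, xx, yy):
        nx, ny = -np.sin(angle), np.cos(angle)  # stripe normal
        return 0.5 + 0.5 * np.cos(2 * np.pi * (xx * nx + yy * ny) / period)

    if pattern == "stripes":
        img = stripes(params.get("angle", 0.0), params.get("period", 16.0), x, y)
    elif pattern == "random_filaments":
        from skimage.draw import line
        from scipy.ndimage import gaussian_filter

        density = params.get("density", 40.0)
        seg_len = params.get("length", 60.0)
        n_seg = max(1, int(density * size_px**2 / 1000.0**2 * 1000))
        img = np.zeros((size_px, size_px))
        for _ in range(n_seg):
            r0, c0 = rng.integers(0, size_px, 2)
            ang = rng.uniform(0, np.pi)
            r1 = int(np.clip(r0 + seg_len * np.sin(ang), 0, size_px - 1))
            c1 = int(np.clip(c0 + seg_len * np.cos(ang), 0, size_px - 1))
            rr, cc = line(r0, c0, r1, c1)
            img[rr, cc] += 1.0
        img = gaussian_filter(img, 1.0)
    elif pattern == "porous":
        img = np.ones((size_px, size_px))
        for (r0, c0, h, w) in params.get("pores", []):
            img[r0 : r0 + h, c0 : c0 + w] = 0.0
    elif pattern == "checkerboard_orientations":
        angles = params.get("angles", (0.0, np.pi / 2))
        tile = int(params.get("tile", 32))
        period = params.get("period", 8.0)
        a = stripes(angles[0], period, x, y)
        b = stripes(angles[1], period, x, y)
        tiles = ((rows // tile).astype(int) + (cols // tile).astype(int)) % 2
        img = np.where(tiles == 0, a, b)
    elif pattern == "tiled_noise":
        tile = int(params.get("tile", 16))
        patch = rng.random((tile, tile))
        reps = int(np.ceil(size_px / tile))
        img = np.tile(patch, (reps, reps))[:size_px, :size_px]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    frames = np.repeat(img[None], n_frames, axis=0)
    return ImageStack(frames, pixel_size=pixel_size, channel=pattern)


# ---------------------------------------------------------------------------
# Strain time courses and movies
# ---------------------------------------------------------------------------


def kelvin_voigt(t: np.ndarray, amplitude: float, tau_v: float) -> np.ndarray:
    """Kelvin-Voigt step response: eps(t) = (sigma/E_v)(1 - exp(-t/tau_v))."""
    return amplitude * (1.0 - np.exp(-np.asarray(t, dtype=float) / tau_v))


def gen_kv_strain(
    amplitude: float,
    tau_v: float,
    dt: float,
    t_max: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sampled Kelvin-Voigt strain response plus i.i.d. Gaussian noise.

    Returns (t, eps).
    """
    if tau_v <= 0:
        raise ValueError("tau_v must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    eps = kelvin_voigt(t, amplitude, tau_v)
    if noise_sd > 0:
        eps = eps + np.random.default_rng(seed).normal(0, noise_sd, t.shape)
    return t, eps


def gen_correlated_stack(
    n_frames: int,
    size_px: int,
    tau_frames: float,
    pixel_size: float = 0.1,
    seed: int = 0,
) -> ImageStack:
    """Movie whose pixel fluctuations have a single-exponential temporal
    autocorrelation exp(-tau/tau_frames) (stationary AR(1) per pixel)."""
    rng = np.random.default_rng(seed)
    rho = np.exp(-1.0 / tau_frames)
    frames = np.empty((n_frames, size_px, size_px))
    frames[0] = rng.normal(size=(size_px, size_px))
    for k in range(1, n_frames):
        frames[k] = rho * frames[k - 1] + np.sqrt(1 - rho**2) * rng.normal(
            size=(size_px, size_px)
        )
    return ImageStack(frames + 10.0, pixel_size=pixel_size)


def gen_spot_movie(
    traj: TrajectorySet,
    size_px: int,
    pixel_size: float,
    spot_sigma_px: float = 2.0,
    aspect: float = 1.0,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Render trajectories as (optionally elongated) Gaussian spots.

    Spot long axes follow each sample's ``theta``; ``aspect`` > 1
    elongates the spot along that axis.  Positions are interpreted in
    um and converted with ``pixel_size``.
    """
    rng = np.random.default_rng(seed)
    frames_idx = np.sort(traj.data["frame"].unique())
    n_frames = int(frames_idx.max()) + 1
    stack = np.full((n_frames, size_px, size_px), background, dtype=float)
    rr, cc = np.mgrid[0:size_px, 0:size_px].astype(float)
    for _, row in traj.data.iterrows():
        f = int(row["frame"])
        cx = row["x"] / pixel_size
        cy = row["y"] / pixel_size
        th = row["theta"]
        sl = spot_sigma_px * aspect
        ss = spot_sigma_px
        # rotated anisotropic Gaussian in the array frame (y along rows)
        dx = cc - cx
        dy = rr - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        w = -dx * np.sin(th) + dy * np.cos(th)
        stack[f] += amplitude * np.exp(-(u**2 / (2 * sl**2) + w**2 / (2 * ss**2)))
    if noise_sd > 0:
        stack += rng.normal(0, noise_sd, stack.shape)
    return ImageStack(stack, pixel_size=pixel_size, frame_interval=traj.frame_interval)


def gen_flow_movie(
    base: np.ndarray,
    n_frames: int,
    flow: str = "radial",
    rate: float = 0.01,
    shift: Tuple[float, float] = (0.0, 0.0),
    pixel_size: float = 0.1,
    crop_margin: int = 0,
) -> ImageStack:
    """Advect a texture by a prescribed per-frame displacement field.

    ``radial``: material displacement u = -rate * (x - x0) per frame
    (divergence -2*rate); ``translation``: constant integer-pixel shift
    per frame applied with wrap-around.  ``crop_margin`` trims that many
    border pixels from every output frame, so the retained region is
    advected with true (not edge-padded) content.
    """
    from scipy.ndimage import map_coordinates

    base = np.asarray(base, dtype=float)
    h, w = base.shape
    frames = [base]
    if flow == "translation":
        dr, dc = int(round(shift[1])), int(round(shift[0]))
        cur = base
        for _ in range(n_frames - 1):
            cur = np.roll(cur, (dr, dc), axis=(0, 1))
            frames.append(cur)
    elif flow == "radial":
        r0, c0 = (h - 1) / 2.0, (w - 1) / 2.0
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        for k in range(1, n_frames):
            # sample frame k from the base: X = x0 + (x - x0)/(1-rate)^k
            fac = (1.0 - rate) ** (-k)
            src_r = r0 + (rows - r0) * fac
            src_c = c0 + (cols - c0) * fac
            frames.append(
                map_coordinates(base, [src_r, src_c], order=3, mode="nearest")
            )
    else:
        raise ValueError(f"unknown flow {flow!r}")
    out = np.stack(frames)
    if crop_margin > 0:
        m = crop_margin
        out = out[:, m:-m, m:-m]
    return ImageStack(out, pixel_size=pixel_size)
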