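"""Overdamped Brownian-dynamics engine for the branched actomyosin model.

One step applies deterministic forces (extensional springs along
segments, angular springs at intra-filament and branch joints, dihedral
torsion at branch joints, soft bead-bead repulsion when volume
exclusion is on, repulsive z-walls, motor-arm crossbridge springs with
their reaction on the filament) plus thermal forces satisfying
fluctuation-dissipation for each bead's drag, then an Euler-Maruyama
update x += F dt / gamma + sqrt(2 kT dt / gamma) xi.  x and y are
periodic: coordinates stay unwrapped, and the minimum image is applied
to every non-bonded interaction.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ..types import TrajectorySet
from .params import SimParams
from .state import SimState

__all__ = [
    "step",
    "run",
    "run_motors",
    "potential_energy",
    "dihedral_angles",
    "StabilityError",
]


class StabilityError(RuntimeError):
    """Per-step displacement exceeded the stability threshold; reduce dt."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, params: SimParams) -> np.ndarray:
    lx, ly, _ = params.domain
    d = d.copy()
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def dihedral_angles(pos: np.ndarray, quads: np.ndarray) -> np.ndarray:
    i, j, k, l = quads.T
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# force terms (each adds into f and returns its potential energy)
# ---------------------------------------------------------------------------


def _bond_forces(state: SimState, f: np.ndarray) -> float:
    if len(state.bonds) == 0:
        return 0.0
    i, j = state.bonds.T
    d = state.pos[j] - state.pos[i]
    r = np.linalg.norm(d, axis=1)
    r = np.maximum(r, 1e-12)
    stretch = r - state.bond_rest
    fmag = state.bond_k * stretch
    fv = (fmag / r)[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    return float(0.5 * np.sum(state.bond_k * stretch**2))


def _angle_forces(state: SimState, f: np.ndarray) -> float:
    if len(state.angles) == 0:
        return 0.0
    i, j, k = state.angles.T
    u = state.pos[i] - state.pos[j]
    v = state.pos[k] - state.pos[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    nu = np.maximum(nu, 1e-12)
    nv = np.maximum(nv, 1e-12)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c**2, 1e-12))
    theta = np.arccos(c)
    dE = state.angle_k * (theta - state.angle_rest)
    di = -(vh - c[:, None] * uh) / (nu * s)[:, None]
    dk = -(uh - c[:, None] * vh) / (nv * s)[:, None]
    np.add.at(f, i, -dE[:, None] * di)
    np.add.at(f, k, -dE[:, None] * dk)
    np.add.at(f, j, dE[:, None] * (di + dk))
    return float(0.5 * np.sum(state.angle_k * (theta - state.angle_rest) ** 2))


def _dihedral_forces(state: SimState, f: np.ndarray) -> float:
    if len(state.dihedrals) == 0:
        return 0.0
    quads = state.dihedrals
    i, j, k, l = quads.T
    pos = state.pos
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2n = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
    # the dihedral is undefined (and its gradient singular) when either
    # bonded triple is near-collinear; such joints exert no torsion
    l1 = np.linalg.norm(b1, axis=1) * b2n
    l3 = np.linalg.norm(b3, axis=1) * b2n
    ok = (n1sq > (0.05 * l1) ** 2) & (n2sq > (0.05 * l3) ** 2)
    if not ok.any():
        return 0.0
    quads = quads[ok]
    i, j, k, l = quads.T
    b1, b2, b3 = b1[ok], b2[ok], b3[ok]
    n1, n2 = n1[ok], n2[ok]
    n1sq, n2sq, b2n = n1sq[ok], n2sq[ok], b2n[ok]
    rest = state.dihedral_rest[ok]
    kdi = state.dihedral_k[ok]
    phi = dihedral_angles(pos, quads)
    dphi = np.arctan2(np.sin(phi - rest), np.cos(phi - rest))
    dE = kdi * dphi
    dphi_di = -(b2n / n1sq)[:, None] * n1
    dphi_dl = (b2n / n2sq)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / b2n**2
    c32 = np.einsum("ij,ij->i", b3, b2) / b2n**2
    dphi_dj = -(1 + c12)[:, None] * dphi_di + c32[:, None] * dphi_dl
    dphi_dk = -dphi_di - dphi_dj - dphi_dl
    # regularize: cap the (jointly scaled) gradient magnitude so
    # near-degenerate joints cannot produce destabilising torques;
    # scaling all four gradients together preserves force balance
    gmax = np.maximum.reduce(
        [np.linalg.norm(g, axis=1) for g in (dphi_di, dphi_dj, dphi_dk, dphi_dl)]
    )
    cap = 30.0  # 1/um
    scale = np.minimum(1.0, cap / np.maximum(gmax, 1e-12))[:, None]
    dphi_di = dphi_di * scale
    dphi_dj = dphi_dj * scale
    dphi_dk = dphi_dk * scale
    dphi_dl = dphi_dl * scale
    np.add.at(f, i, -dE[:, None] * dphi_di)
    np.add.at(f, j, -dE[:, None] * dphi_dj)
    np.add.at(f, k, -dE[:, None] * dphi_dk)
    np.add.at(f, l, -dE[:, None] * dphi_dl)
    return float(0.5 * np.sum(kdi * dphi**2))


def _wall_forces(state: SimState, f: np.ndarray) -> float:
    lz = state.params.domain[2]
    kw = state.params.k_wall
    z = state.pos[:, 2]
    low = z < 0
    high = z > lz
    f[low, 2] += -kw * z[low]
    f[high, 2] += -kw * (z[high] - lz)
    return float(0.5 * kw * (np.sum(z[low] ** 2) + np.sum((z[high] - lz) ** 2)))


class _NeighborList:
    def __init__(self):
        self.pairs: Optional[np.ndarray] = None
        self.countdown = 0

    def rebuild(self, state: SimState) -> None:
        p = state.params
        lx, ly, _ = p.domain
        wrapped = state.pos.copy()
        wrapped[:, 0] %= lx
        wrapped[:, 1] %= ly
        zmin = wrapped[:, 2].min()
        wrapped[:, 2] -= zmin - 1.0
        fil_idx = np.nonzero(state.is_filament)[0]
        mot_idx = np.nonzero(~state.is_filament)[0]
        cut_ff = 2 * p.filament_repulsion_radius + p.neighbor_skin
        cut_mx = (
            p.motor_repulsion_radius
            + max(p.filament_repulsion_radius, p.motor_repulsion_radius)
            + p.neighbor_skin
        )
        pair_list = []
        fil_tree = cKDTree(wrapped[fil_idx], boxsize=[lx, ly, 1e6])
        ff = fil_tree.query_pairs(cut_ff, output_type="ndarray")
        if len(ff):
            pair_list.append(np.column_stack([fil_idx[ff[:, 0]], fil_idx[ff[:, 1]]]))
        if len(mot_idx):
            all_tree = cKDTree(wrapped, boxsize=[lx, ly, 1e6])
            near = all_tree.query_ball_point(wrapped[mot_idx], cut_mx)
            mm_pairs = []
            for mi, cands in zip(mot_idx, near):
                for c in cands:
                    if c != mi and (c > mi or state.is_filament[c]):
                        mm_pairs.append((mi, c))
            if mm_pairs:
                pair_list.append(np.asarray(mm_pairs, dtype=int))
        if pair_list:
            pairs = np.vstack(pair_list)
            keep = [
                (a, b)
                for a, b in pairs
                if (min(a, b), max(a, b)) not in state.exclusions
            ]
            self.pairs = np.asarray(keep, dtype=int).reshape(-1, 2)
        else:
            self.pairs = np.empty((0, 2), dtype=int)


def _bead_radii(state: SimState) -> np.ndarray:
    p = state.params
    return np.where(
        state.is_filament, p.filament_repulsion_radius, p.motor_repulsion_radius
    )


def _repulsion_forces(state: SimState, f: np.ndarray, nl: _NeighborList) -> float:
    p = state.params
    if nl.pairs is None or len(nl.pairs) == 0:
        return 0.0
    i, j = nl.pairs.T
    radii = _bead_radii(state)
    d = _min_image(state.pos[j] - state.pos[i], p)
    r = np.linalg.norm(d, axis=1)
    ov = (radii[i] + radii[j]) - r
    m = ov > 0
    if not m.any():
        return 0.0
    i, j, d, r, ov = i[m], j[m], d[m], np.maximum(r[m], 1e-9), ov[m]
    fv = (p.k_repulsion * ov / r)[:, None] * d
    np.add.at(f, i, -fv)
    np.add.at(f, j, fv)
    return float(0.5 * p.k_repulsion * np.sum(ov**2))


def _arm_points(state: SimState):
    """Anchor and filament attachment points of bound arms.

    Returns (mi, ai) flat indices of bound arms plus geometry arrays.
    """
    bound = state.arm_bound_bond >= 0
    if not bound.any():
        return None
    mi, ai = np.nonzero(bound)
    ab = state.arm_anchor_bond[mi, ai]
    af = state.arm_anchor_frac[mi, ai]
    fb = state.arm_bound_bond[mi, ai]
    ff = state.arm_bound_frac[mi, ai]
    r0 = state.arm_bound_rest[mi, ai]
    b = state.bonds
    anchor = (1 - af)[:, None] * state.pos[b[ab, 0]] + af[:, None] * state.pos[
        b[ab, 1]
    ]
    fil = (1 - ff)[:, None] * state.pos[b[fb, 0]] + ff[:, None] * state.pos[b[fb, 1]]
    return mi, ai, ab, af, fb, ff, r0, anchor, fil


def _arm_forces(state: SimState, f: np.ndarray) -> float:
    pts = _arm_points(state)
    if pts is None:
        return 0.0
    mi, ai, ab, af, fb, ff, r0, anchor, fil = pts
    p = state.params
    d = _min_image(fil - anchor, p)  # spring vector anchor -> filament point
    dist = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
    # the tether is born relaxed at its binding separation r0; only
    # deviations from r0 exert force (no energy injected on binding)
    fv = (p.k_arm * (dist - r0) / dist)[:, None] * d
    b = state.bonds
    np.add.at(f, b[ab, 0], (1 - af)[:, None] * fv)
    np.add.at(f, b[ab, 1], af[:, None] * fv)
    np.add.at(f, b[fb, 0], -(1 - ff)[:, None] * fv)
    np.add.at(f, b[fb, 1], -ff[:, None] * fv)
    return float(0.5 * p.k_arm * np.sum((dist - r0) ** 2))


def potential_energy(state: SimState, nl: Optional[_NeighborList] = None) -> float:
    """Total potential energy of the current configuration."""
    f = np.zeros_like(state.pos)
    e = _bond_forces(state, f)
    e += _angle_forces(state, f)
    e += _dihedral_forces(state, f)
    e += _wall_forces(state, f)
    e += _arm_forces(state, f)
    if state.params.volume_exclusion:
        if nl is None:
            nl = _NeighborList()
            nl.rebuild(state)
        e += _repulsion_forces(state, f, nl)
    return e


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def _forces(state: SimState, nl: _NeighborList) -> np.ndarray:
    f = np.zeros_like(state.pos)
    _bond_forces(state, f)
    _angle_forces(state, f)
    _dihedral_forces(state, f)
    _wall_forces(state, f)
    _arm_forces(state, f)
    if state.params.volume_exclusion:
        _repulsion_forces(state, f, nl)
    return f


def step(
    state: SimState,
    nl: Optional[_NeighborList] = None,
    thermal: bool = True,
) -> SimState:
    """One in-place Euler-Maruyama update; returns the state."""
    p = state.params
    if nl is None:
        nl = _NeighborList()
    if p.volume_exclusion and (nl.pairs is None or nl.countdown <= 0):
        nl.rebuild(state)
        nl.countdown = p.neighbor_every
    nl.countdown -= 1
    f = _forces(state, nl)
    dx = f * (p.dt / state.gamma[:, None])
    if thermal:
        noise = state.rng.normal(size=state.pos.shape)
        dx += noise * np.sqrt(2 * p.temperature_kT * p.dt / state.gamma)[:, None]
    norms = np.linalg.norm(dx, axis=1)
    max_dx = float(norms.max()) if len(norms) else 0.0
    if max_dx > p.max_step_frac * p.segment_length:
        raise StabilityError(
            f"step displacement {max_dx:.3g} um exceeds "
            f"{p.max_step_frac} * segment_length; reduce dt={p.dt}"
        )
    # displacement limiter: rare contact/thermal force spikes are
    # capped per bead (a diagonal PSD rescaling, so relaxation still
    # descends the energy) instead of aborting the run
    cap = p.limit_step_frac * p.segment_length
    over = norms > cap
    if over.any():
        dx[over] *= (cap / norms[over])[:, None]
    state.pos += dx
    state.time += p.dt
    return state


# ---------------------------------------------------------------------------
# motor kinetics (binding, walking, unbinding)
# ---------------------------------------------------------------------------


def _filament_bond_ends(state: SimState):
    n_fil_bonds = sum(len(cb) for cb in state.chain_bonds)
    return n_fil_bonds


def _react(state: SimState, dt_react: float) -> None:
    """Stochastic binding/unbinding and deterministic walking of arms."""
    p = state.params
    b = state.bonds
    rng = state.rng

    # --- unbinding (Bell law) ---------------------------------------
    pts = _arm_points(state)
    if pts is not None:
        mi, ai, ab, af, fb, ff, r0, anchor, fil = pts
        fmag = p.k_arm * np.abs(
            np.linalg.norm(_min_image(fil - anchor, p), axis=1) - r0
        )
        k_off = p.k_off0 * np.exp(fmag / p.f_bell)
        unbind = rng.random(len(mi)) < 1 - np.exp(-k_off * dt_react)
        state.arm_bound_bond[mi[unbind], ai[unbind]] = -1

    # --- walking ------------------------------------------------------
    if p.walking:
        pts = _arm_points(state)
        if pts is not None:
            mi, ai, ab, af, fb, ff, r0, anchor, fil = pts
            d = _min_image(fil - anchor, p)
            dist = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
            # walking direction: toward the barbed end (higher bond idx)
            e = state.pos[b[fb, 1]] - state.pos[b[fb, 0]]
            elen = np.maximum(np.linalg.norm(e, axis=1), 1e-12)
            eh = e / elen[:, None]
            # load on the head from the tether spring
            f_head = -(p.k_arm * (dist - r0) / dist)[:, None] * d
            f_par = np.einsum("ij,ij->i", f_head, eh)
            load = np.maximum(0.0, -f_par)
            v = p.v_walk * np.maximum(0.0, 1.0 - load / p.f_stall)
            new_ff = ff + v * dt_react / elen
            for idx in range(len(mi)):
                m_, a_ = mi[idx], ai[idx]
                bond = fb[idx]
                s = new_ff[idx]
                # advance across bond boundaries within the chain
                ci, local = _bond_chain_lookup(state)[bond]
                cbs = state.chain_bonds[ci]
                while s > 1.0 and local + 1 < len(cbs):
                    s -= 1.0
                    local += 1
                    bond = cbs[local]
                state.arm_bound_bond[m_, a_] = bond
                state.arm_bound_frac[m_, a_] = min(s, 1.0)

    # --- binding ------------------------------------------------------
    if p.binding:
        free = state.arm_bound_bond < 0
        if free.any() and len(state.motor_chains):
            mi, ai = np.nonzero(free)
            ab = state.arm_anchor_bond[mi, ai]
            af = state.arm_anchor_frac[mi, ai]
            anchor = (1 - af)[:, None] * state.pos[b[ab, 0]] + af[:, None] * state.pos[
                b[ab, 1]
            ]
            fil_beads = np.nonzero(state.is_filament)[0]
            lx, ly, _ = p.domain
            wrapped = state.pos[fil_beads].copy()
            wrapped[:, 0] %= lx
            wrapped[:, 1] %= ly
            aw = anchor.copy()
            aw[:, 0] %= lx
            aw[:, 1] %= ly
            zshift = min(wrapped[:, 2].min(), aw[:, 2].min()) - 1.0
            wrapped[:, 2] -= zshift
            aw[:, 2] -= zshift
            ztree = cKDTree(wrapped, boxsize=[lx, ly, 1e6])
            cand = ztree.query_ball_point(aw, p.capture_radius)
            p_bind = 1 - np.exp(-p.k_on * dt_react)
            bead_bond = _bead_to_bond(state)
            for idx, cands in enumerate(cand):
                if not cands or rng.random() >= p_bind:
                    continue
                bead = fil_beads[cands[int(rng.integers(len(cands)))]]
                bond = bead_bond.get(int(bead))
                if bond is None:
                    continue
                # attach at the projection of the anchor onto the bond
                p0, p1 = state.pos[b[bond, 0]], state.pos[b[bond, 1]]
                seg_v = _min_image(p1[None] - p0[None], p)[0]
                rel = _min_image(anchor[idx][None] - p0[None], p)[0]
                denom = max(seg_v @ seg_v, 1e-12)
                s = float(np.clip(rel @ seg_v / denom, 0.0, 1.0))
                attach = state.pos[b[bond, 0]] + s * seg_v
                sep = _min_image(attach[None] - anchor[idx][None], p)[0]
                state.arm_bound_bond[mi[idx], ai[idx]] = bond
                state.arm_bound_frac[mi[idx], ai[idx]] = s
                state.arm_bound_rest[mi[idx], ai[idx]] = float(
                    np.linalg.norm(sep)
                )


def _bond_chain_lookup(state: SimState):
    if not hasattr(state, "_bond_chain") or state._bond_chain is None:
        lookup = {}
        for ci, cbs in enumerate(state.chain_bonds):
            for local, bond in enumerate(cbs):
                lookup[int(bond)] = (ci, local)
        state._bond_chain = lookup
    return state._bond_chain


def _bead_to_bond(state: SimState):
    if not hasattr(state, "_bead_bond") or state._bead_bond is None:
        lookup = {}
        for cbs in state.chain_bonds:
            for bond in cbs:
                a, bb = state.bonds[bond]
                lookup.setdefault(int(a), int(bond))
                lookup.setdefault(int(bb), int(bond))
        state._bead_bond = lookup
    return state._bead_bond


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def run(state: SimState, n_steps: int, thermal: bool = True) -> SimState:
    """Advance ``n_steps`` with motor kinetics every ``react_every``."""
    p = state.params
    nl = _NeighborList()
    for k in range(n_steps):
        step(state, nl, thermal=thermal)
        if (k + 1) % p.react_every == 0 and len(state.motor_chains):
            _react(state, p.react_every * p.dt)
    return state


def run_motors(
    state: SimState,
    n_record: int,
    record_interval: float,
    seed: Optional[int] = None,
    equilibrate_steps: int = 0,
) -> TrajectorySet:
    """Run the assembled system and record motor backbone centres.

    ``record_interval`` (s) must be a multiple of the timestep.  The
    returned TrajectorySet holds x/y (um, unwrapped) plus a z column;
    theta is the backbone axis angle in the x-y plane and length the
    backbone end-to-end extent.
    """
    import pandas as pd

    p = state.params
    if seed is not None:
        state.rng = np.random.default_rng(seed)
    steps_per = int(round(record_interval / p.dt))
    if abs(steps_per * p.dt - record_interval) > 1e-9 * max(record_interval, p.dt):
        raise ValueError("record_interval must be a multiple of the timestep")
    if equilibrate_steps:
        run(state, equilibrate_steps)
    rows = []

    def record(frame: int):
        for m, chain in enumerate(state.motor_chains):
            c = state.pos[chain].mean(axis=0)
            ee = state.pos[chain[-1]] - state.pos[chain[0]]
            theta = np.arctan2(ee[1], ee[0])
            theta = (theta + np.pi / 2) % np.pi - np.pi / 2
            rows.append(
                {
                    "id": m,
                    "frame": frame,
                    "t": frame * record_interval,
                    "x": c[0],
                    "y": c[1],
                    "theta": theta,
                    "length": float(np.linalg.norm(ee)),
                    "z": c[2],
                }
            )

    record(0)
    for fr in range(1, n_record):
        run(state, steps_per)
        record(fr)
    df = pd.DataFrame(rows)
    return TrajectorySet(df, frame_interval=record_interval)
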