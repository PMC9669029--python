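"""Simulation state: filament network, branch joints, and motors.

The network is a forest of bead-spring chains; an Arp2/3 branch joint
is a bead shared between a mother chain and the first segment of its
daughter (so connectivity is a tree plus branch links), with an
angular spring holding the preferred branch angle and a weak dihedral
spring resisting torsion about the mother axis.  Motors are separate
backbone chains carrying arms at fixed arc positions; each arm is free
or bound to a filament segment at an arc fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .params import SimParams

__all__ = ["SimState", "assemble_network", "place_motors"]


@dataclass
class SimState:
    params: SimParams
    pos: np.ndarray  # (N, 3) bead positions, um (unwrapped in x/y)
    gamma: np.ndarray  # (N,) drag coefficients
    is_filament: np.ndarray  # (N,) bool

    chains: List[np.ndarray] = field(default_factory=list)  # bead indices, pointed->barbed
    bonds: np.ndarray = None  # (nb, 2) int
    bond_rest: np.ndarray = None  # (nb,)
    bond_k: np.ndarray = None
    angles: np.ndarray = None  # (na, 3) int, centre second
    angle_rest: np.ndarray = None
    angle_k: np.ndarray = None
    dihedrals: np.ndarray = None  # (nd, 4) int
    dihedral_rest: np.ndarray = None
    dihedral_k: np.ndarray = None
    branch_joints: np.ndarray = None  # (n_branch, 2): shared bead, daughter chain idx

    # chain bookkeeping for walking: bond index ranges per chain
    chain_bonds: List[np.ndarray] = field(default_factory=list)

    # motors
    motor_chains: List[np.ndarray] = field(default_factory=list)
    # arms: per motor, arrays of (backbone bond local idx, frac) anchors
    arm_anchor_bond: np.ndarray = None  # (n_motors, n_arms) global bond idx
    arm_anchor_frac: np.ndarray = None
    # bound state: -1 free, else global filament bond index; frac along it
    arm_bound_bond: np.ndarray = None
    arm_bound_frac: np.ndarray = None
    arm_bound_rest: np.ndarray = None  # tether rest length at binding

    exclusions: set = field(default_factory=set)
    rng: np.random.Generator = None
    time: float = 0.0

    @property
    def n_beads(self) -> int:
        return len(self.pos)

    def copy(self) -> "SimState":
        import copy as _copy

        new = _copy.copy(self)
        new.pos = self.pos.copy()
        if self.arm_bound_bond is not None:
            new.arm_bound_bond = self.arm_bound_bond.copy()
            new.arm_bound_frac = self.arm_bound_frac.copy()
            new.arm_bound_rest = self.arm_bound_rest.copy()
        return new

    def motor_centers(self) -> np.ndarray:
        return np.array([self.pos[c].mean(axis=0) for c in self.motor_chains])

    def z_density(self, n_bins: int = 10, which: str = "filament"):
        """Histogram of bead z positions (actin network by default)."""
        lz = self.params.domain[2]
        sel = self.is_filament if which == "filament" else ~self.is_filament
        h, edges = np.histogram(
            np.clip(self.pos[sel, 2], 0, lz), bins=n_bins, range=(0, lz)
        )
        return 0.5 * (edges[:-1] + edges[1:]), h

    def save(self, path) -> None:
        """Checkpoint to an .npz container (positions, topology, arms)."""
        np.savez_compressed(
            path,
            pos=self.pos,
            gamma=self.gamma,
            is_filament=self.is_filament,
            bonds=self.bonds,
            bond_rest=self.bond_rest,
            bond_k=self.bond_k,
            angles=self.angles,
            angle_rest=self.angle_rest,
            angle_k=self.angle_k,
            dihedrals=self.dihedrals,
            dihedral_rest=self.dihedral_rest,
            dihedral_k=self.dihedral_k,
            chains=np.array([c for c in self.chains], dtype=object),
            chain_bonds=np.array([c for c in self.chain_bonds], dtype=object),
            motor_chains=np.array([c for c in self.motor_chains], dtype=object),
            arm_anchor_bond=self.arm_anchor_bond,
            arm_anchor_frac=self.arm_anchor_frac,
            arm_bound_bond=self.arm_bound_bond,
            arm_bound_frac=self.arm_bound_frac,
            arm_bound_rest=self.arm_bound_rest,
            time=self.time,
            allow_pickle=True,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def _branch_direction(rng, mother_dir: np.ndarray, branch_angle: float) -> np.ndarray:
    """Direction at ``branch_angle`` from the mother axis, random azimuth."""
    m = _unit(mother_dir)
    perp = np.cross(m, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(m, _random_unit(rng))
    perp = _unit(perp)
    return _unit(m * np.cos(branch_angle) + perp * np.sin(branch_angle))


def assemble_network(params: SimParams, seed: Optional[int] = None) -> SimState:
    """Grow a branched network by stochastic segment addition.

    Seed filaments elongate at their barbed tips with direction noise
    set by the persistence length; branch events consume the Arp2/3
    budget by starting a daughter chain at the preferred branch angle
    off a randomly chosen existing bead.  Growth stops when the actin
    segment budget (from C_A and the domain volume) is consumed.
    'biased' seeding starts near z = 0 growing outward (+z biased),
    emulating nucleation at a supported bilayer; 'random' seeds
    uniformly with isotropic orientations.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lx, ly, lz = params.domain
    seg = params.segment_length
    budget = params.segment_budget
    n_seeds = min(params.n_seeds, budget)
    if budget < 1 or n_seeds < 1:
        raise ValueError("actin budget too small to form any filament")
    arp_budget = params.n_branches
    branch_angle = np.deg2rad(params.branch_angle_deg)
    sigma_dir = np.sqrt(seg / params.persistence_length)
    z_margin = 0.02

    positions: List[np.ndarray] = []
    chains: List[List[int]] = []
    chain_dirs: List[np.ndarray] = []  # current tip direction per chain
    blocked: set = set()  # chains whose tip cannot grow without overlap
    branch_records = []  # (shared bead, daughter chain idx)
    branch_hosts: set = set()

    # self-avoidance during growth: new beads may not overlap existing
    # ones (otherwise the assembled state stores a large contact-energy
    # reservoir whose slow relaxation masquerades as network motion)
    d_avoid = (
        2 * params.filament_repulsion_radius * params.assembly_clearance_factor
    )
    cell = max(d_avoid, 1e-3)
    grid: dict = {}

    def _cell_key(p):
        return (
            int(np.floor((p[0] % lx) / cell)),
            int(np.floor((p[1] % ly) / cell)),
            int(np.floor(p[2] / cell)),
        )

    def _clear(p, exempt: set) -> bool:
        kx, ky, kz = _cell_key(p)
        nx = int(np.ceil(lx / cell))
        ny = int(np.ceil(ly / cell))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for b in grid.get(((kx + dx) % nx, (ky + dy) % ny, kz + dz), ()):
                        if b in exempt:
                            continue
                        d = positions[b] - p
                        d[0] -= lx * np.round(d[0] / lx)
                        d[1] -= ly * np.round(d[1] / ly)
                        if d @ d < d_avoid**2:
                            return False
        return True

    def new_bead(p) -> int:
        positions.append(np.asarray(p, dtype=float))
        idx = len(positions) - 1
        grid.setdefault(_cell_key(p), []).append(idx)
        return idx

    # --- seeds -------------------------------------------------------
    for _ in range(n_seeds):
        if params.arrangement == "biased":
            p0 = np.array(
                [rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(0.02, 0.1)]
            )
            d = _random_unit(rng)
            d[2] = abs(d[2])  # outward growth bias
            d = _unit(d)
        else:
            p0 = np.array(
                [
                    rng.uniform(0, lx),
                    rng.uniform(0, ly),
                    rng.uniform(z_margin, lz - z_margin),
                ]
            )
            d = _random_unit(rng)
        b = new_bead(p0)
        chains.append([b])
        chain_dirs.append(d)
    used = 0

    def grow(ci: int) -> bool:
        nonlocal used
        tip_idx = chains[ci][-1]
        tip = positions[tip_idx]
        for attempt in range(40):
            # escalate direction noise when straight growth is blocked:
            # the tip deflects around obstacles rather than stalling
            sig = sigma_dir * (1.0 + 0.5 * attempt)
            d = _unit(chain_dirs[ci] + rng.normal(0, sig, 3))
            p = tip + d * seg
            if p[2] < z_margin or p[2] > lz - z_margin:
                d = d.copy()
                d[2] = -d[2]
                p = tip + d * seg
            if _clear(p, {tip_idx}):
                chains[ci].append(new_bead(p))
                chain_dirs[ci] = d
                used += 1
                return True
        return False

    # give every seed its first segment
    for ci in range(len(chains)):
        if used >= budget:
            break
        if not grow(ci):
            blocked.add(ci)

    stall = 0
    while used < budget and stall < 200:
        remaining = budget - used
        p_branch = min(1.0, arp_budget / max(remaining, 1)) if arp_budget > 0 else 0.0
        if arp_budget > 0 and rng.random() < p_branch:
            # branch: pick a random bead with an incoming direction;
            # one Arp2/3 (daughter) per bead at most
            host_ci = int(rng.integers(len(chains)))
            if len(chains[host_ci]) < 2:
                stall += 1
                continue
            k = int(rng.integers(1, len(chains[host_ci])))
            shared = chains[host_ci][k]
            if shared in branch_hosts:
                stall += 1
                continue
            mother_dir = _unit(
                positions[shared] - positions[chains[host_ci][k - 1]]
            )
            placed = False
            for _ in range(25):
                d = _branch_direction(rng, mother_dir, branch_angle)
                p = positions[shared] + d * seg
                if p[2] < z_margin or p[2] > lz - z_margin:
                    d = d.copy()
                    d[2] = -d[2]
                    p = positions[shared] + d * seg
                if _clear(p, set(chains[host_ci][max(0, k - 1) : k + 2])):
                    placed = True
                    break
            if not placed:
                stall += 1
                continue
            branch_hosts.add(shared)
            daughter = [shared, new_bead(p)]
            chains.append(daughter)
            chain_dirs.append(d)
            branch_records.append((shared, len(chains) - 1))
            arp_budget -= 1
            used += 1
            stall = 0
        else:
            growable = [ci for ci in range(len(chains)) if ci not in blocked]
            if not growable:
                break
            ci = int(rng.integers(len(growable)))
            if grow(growable[ci]):
                stall = 0
            else:
                blocked.add(growable[ci])

    pos = np.asarray(positions)
    n = len(pos)

    # --- topology arrays --------------------------------------------
    bonds, angles, dihedrals = [], [], []
    angle_rest, angle_k = [], []
    chain_arrays = [np.asarray(c, dtype=int) for c in chains]
    chain_bond_idx: List[List[int]] = []
    for c in chain_arrays:
        idxs = []
        for a, b in zip(c[:-1], c[1:]):
            idxs.append(len(bonds))
            bonds.append((a, b))
        chain_bond_idx.append(idxs)
        for i in range(len(c) - 2):
            # rest = as-built angle: the assembled network is the
            # stress-free reference (growth kinks are frozen-in
            # curvature, not elastic strain)
            u = pos[c[i]] - pos[c[i + 1]]
            v = pos[c[i + 2]] - pos[c[i + 1]]
            cth = np.clip(
                (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1
            )
            angles.append((c[i], c[i + 1], c[i + 2]))
            angle_rest.append(float(np.arccos(cth)))
            angle_k.append(params.k_bend)

    daughter_of = {ci: shared for shared, ci in branch_records}
    branch_joints = []
    for shared, ci in branch_records:
        c = chain_arrays[ci]
        # locate the shared bead on its mother chain
        host = None
        for mc, marr in enumerate(chain_arrays):
            if mc == ci:
                continue
            where = np.where(marr == shared)[0]
            if len(where) and where[0] > 0:
                host, k = mc, int(where[0])
                break
        if host is None:
            continue
        marr = chain_arrays[host]
        prev_m = marr[k - 1]
        d2 = c[1]
        angles.append((prev_m, shared, d2))
        angle_rest.append(np.pi - np.deg2rad(params.branch_angle_deg))
        angle_k.append(params.k_branch)
        if k + 1 < len(marr):
            # torsional resistance: restrain the daughter against the
            # distal mother segment at its as-built angle.  Together
            # with the branch-angle spring this pins the daughter's
            # azimuth about the mother axis wherever the mother is
            # bent; for an exactly straight mother the azimuth is
            # physically meaningless.  (A four-point dihedral about a
            # near-straight axis is numerically singular.)
            v = pos[d2] - pos[shared]
            w = pos[marr[k + 1]] - pos[shared]
            rest2 = float(
                np.arccos(
                    np.clip(
                        (w @ v) / (np.linalg.norm(w) * np.linalg.norm(v)), -1, 1
                    )
                )
            )
            angles.append((marr[k + 1], shared, d2))
            angle_rest.append(rest2)
            angle_k.append(params.k_torsion)
        branch_joints.append((shared, ci))

    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    angles = np.asarray(angles, dtype=int).reshape(-1, 3)
    dihedrals = np.asarray(dihedrals, dtype=int).reshape(-1, 4)

    state = SimState(
        params=params,
        pos=pos,
        gamma=np.full(n, params.gamma_bead),
        is_filament=np.ones(n, dtype=bool),
        chains=chain_arrays,
        bonds=bonds,
        bond_rest=np.full(len(bonds), seg),
        bond_k=np.full(len(bonds), params.k_stretch),
        angles=angles,
        angle_rest=np.asarray(angle_rest),
        angle_k=np.asarray(angle_k),
        dihedrals=dihedrals,
        dihedral_rest=np.zeros(len(dihedrals)),
        dihedral_k=np.full(len(dihedrals), params.k_torsion),
        branch_joints=np.asarray(branch_joints, dtype=int).reshape(-1, 2),
        chain_bonds=[np.asarray(ix, dtype=int) for ix in chain_bond_idx],
        rng=rng,
    )
    # rest dihedral = assembled geometry (torsion resists twist away
    # from the as-built azimuth about the mother axis)
    if len(dihedrals):
        from .engine import dihedral_angles

        state.dihedral_rest = dihedral_angles(state.pos, dihedrals)
    state.exclusions = _build_exclusions(bonds, angles)
    # motor arrays start empty
    state.arm_anchor_bond = np.empty((0, 0), dtype=int)
    state.arm_anchor_frac = np.empty((0, 0))
    state.arm_bound_bond = np.empty((0, 0), dtype=int)
    state.arm_bound_frac = np.empty((0, 0))
    state.arm_bound_rest = np.empty((0, 0))
    return state


def _build_exclusions(bonds: np.ndarray, angles: np.ndarray) -> set:
    exc = set()
    for a, b in bonds:
        exc.add((min(a, b), max(a, b)))
    for i, j, k in angles:
        for p, q in ((i, j), (j, k), (i, k)):
            exc.add((min(p, q), max(p, q)))
    return exc


def place_motors(state: SimState, seed: Optional[int] = None) -> SimState:
    """Add motors per the arrangement: near z ~ 0 for 'biased' (where
    the network is densest and barbed ends point away), near the
    domain mid-height for 'random'."""
    params = state.params
    rng = np.random.default_rng(params.seed + 7919 if seed is None else seed)
    lx, ly, lz = params.domain
    seg = params.segment_length
    n_motors = params.motor_count()
    n_bb = max(2, int(round(params.motor_length / seg)) + 1)
    arm_s = np.linspace(0, params.motor_length, params.arms_per_motor)

    pos_list = [state.pos]
    gamma_list = [state.gamma]
    nxt = state.n_beads
    new_bonds, new_angles = [], []
    motor_chains = []
    anchor_bond = np.empty((n_motors, params.arms_per_motor), dtype=int)
    anchor_frac = np.empty((n_motors, params.arms_per_motor))
    bond_offset = len(state.bonds)
    fil_pos = state.pos[state.is_filament]
    from scipy.spatial import cKDTree

    wrapped = fil_pos.copy()
    wrapped[:, 0] %= lx
    wrapped[:, 1] %= ly
    zshift = wrapped[:, 2].min() - 1.0
    wrapped[:, 2] -= zshift
    fil_tree = cKDTree(wrapped, boxsize=[lx, ly, 1e6])
    contact = params.motor_repulsion_radius + params.filament_repulsion_radius

    def overlap_score(p0, d):
        pts = p0[None, :] + d[None, :] * seg * np.arange(n_bb)[:, None]
        q = pts.copy()
        q[:, 0] %= lx
        q[:, 1] %= ly
        q[:, 2] = np.clip(q[:, 2], 0.03, lz - 0.03) - zshift
        score = 0.0
        for hits in fil_tree.query_ball_point(q, contact):
            score += len(hits)
        return score

    for m in range(n_motors):
        # motors assemble in situ: choose the least-overlapping pocket
        # among candidate placements so volume exclusion does not expel
        # them in a startup transient
        best = None
        for _ in range(60):
            if params.arrangement == "biased":
                z0 = rng.uniform(0.05, 0.2)
            else:
                z0 = lz / 2 + rng.uniform(-0.1, 0.1)
            p0c = np.array([rng.uniform(0, lx), rng.uniform(0, ly), z0])
            dc = _random_unit(rng)
            dc[2] *= 0.2  # keep backbones roughly in-plane
            dc = _unit(dc)
            sc = overlap_score(p0c, dc)
            if best is None or sc < best[0]:
                best = (sc, p0c, dc)
            if sc == 0:
                break
        _, p0, d = best
        beads = []
        for k in range(n_bb):
            p = p0 + d * seg * k
            p[2] = np.clip(p[2], 0.03, lz - 0.03)
            pos_list.append(p[None])
            beads.append(nxt)
            nxt += 1
        gamma_list.append(np.full(n_bb, state.params.gamma_motor_bead))
        motor_chains.append(np.asarray(beads, dtype=int))
        first_bond = bond_offset + len(new_bonds)
        for a, b in zip(beads[:-1], beads[1:]):
            new_bonds.append((a, b))
        for i in range(n_bb - 2):
            new_angles.append((beads[i], beads[i + 1], beads[i + 2]))
        bb_len = (n_bb - 1) * seg
        for ai, s in enumerate(arm_s):
            s_eff = min(s, bb_len - 1e-9)
            k = min(int(s_eff / seg), n_bb - 2)
            anchor_bond[m, ai] = first_bond + k
            anchor_frac[m, ai] = s_eff / seg - k

    state.pos = np.vstack(pos_list)
    state.gamma = np.concatenate(gamma_list)
    state.is_filament = np.concatenate(
        [state.is_filament, np.zeros(state.n_beads - len(state.is_filament), bool)]
    )
    if new_bonds:
        nb = np.asarray(new_bonds, dtype=int)
        state.bonds = np.vstack([state.bonds, nb])
        state.bond_rest = np.concatenate(
            [state.bond_rest, np.full(len(nb), seg)]
        )
        state.bond_k = np.concatenate(
            [state.bond_k, np.full(len(nb), params.k_stretch)]
        )
    if new_angles:
        na = np.asarray(new_angles, dtype=int)
        state.angles = np.vstack([state.angles, na])
        state.angle_rest = np.concatenate([state.angle_rest, np.full(len(na), np.pi)])
        state.angle_k = np.concatenate(
            [state.angle_k, np.full(len(na), params.k_bend)]
        )
    state.exclusions = _build_exclusions(state.bonds, state.angles)
    state.motor_chains = motor_chains
    state.arm_anchor_bond = anchor_bond
    state.arm_anchor_frac = anchor_frac
    state.arm_bound_bond = np.full((n_motors, params.arms_per_motor), -1, dtype=int)
    state.arm_bound_frac = np.zeros((n_motors, params.arms_per_motor))
    state.arm_bound_rest = np.zeros((n_motors, params.arms_per_motor))
    return state
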