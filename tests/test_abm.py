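"""Simulator unit behaviour: assembly, forces, determinism, kinetics.

The slower emergent-behaviour checks (confinement orderings, free-motor
diffusion slope) live in the acceptance suite.
"""

import numpy as np
import pytest

from actomech.abm import (
    SimParams,
    SimState,
    StabilityError,
    assemble_network,
    dihedral_angles,
    place_motors,
    potential_energy,
    run,
    run_motors,
    step,
)
from actomech.abm.engine import _NeighborList, _forces


SMALL = dict(c_actin=30.0, domain=(1.0, 1.0, 0.5), n_seeds=6)


class TestAssembly:
    def test_zero_arp_means_linear_filaments(self):
        p = SimParams(r_arp=0.0, seed=2, **SMALL)
        st = assemble_network(p)
        assert len(st.branch_joints) == 0

    def test_deterministic_given_seed(self):
        p = SimParams(seed=5, **SMALL)
        a = assemble_network(p)
        b = assemble_network(p)
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.bonds, b.bonds)

    def test_biased_arrangement_bottom_heavy(self):
        # assayed in a domain tall enough to hold a density gradient at
        # the filament scale (the default slab is only ~5 segments
        # high, and a saturated box is uniform by construction)
        p = SimParams(
            seed=3, arrangement="biased", c_actin=50.0, domain=(1, 1, 2)
        )
        st = assemble_network(p)
        lz = p.domain[2]
        lower = (st.pos[st.is_filament, 2] < lz / 2).sum()
        upper = (st.pos[st.is_filament, 2] >= lz / 2).sum()
        assert lower > upper

    def test_budget_consumed(self):
        p = SimParams(seed=4, **SMALL)
        st = assemble_network(p)
        assert st.is_filament.sum() >= 0.95 * p.segment_budget

    def test_degenerate_budget_rejected(self):
        p = SimParams(c_actin=1e-6, domain=(0.2, 0.2, 0.2), n_seeds=2)
        with pytest.raises(ValueError):
            assemble_network(p)

    def test_branch_count_tracks_ratio(self):
        p = SimParams(r_arp=0.005, seed=6, **SMALL)
        st = assemble_network(p)
        assert len(st.branch_joints) == pytest.approx(p.n_branches, rel=0.05)


class TestForcesAndStepping:
    def test_forces_match_numeric_gradient(self, small_network):
        _, st = small_network
        st = st.copy()
        rng = np.random.default_rng(0)
        st.pos = st.pos + rng.normal(0, 0.01, st.pos.shape)
        nl = _NeighborList()
        nl.rebuild(st)
        f = _forces(st, nl)
        h = 1e-6
        for bead in rng.choice(st.n_beads, 5, replace=False):
            for c in range(3):
                st.pos[bead, c] += h
                ep = potential_energy(st, nl)
                st.pos[bead, c] -= 2 * h
                em = potential_energy(st, nl)
                st.pos[bead, c] += h
                num = -(ep - em) / (2 * h)
                assert f[bead, c] == pytest.approx(num, abs=2e-4)

    def test_dihedral_gradient_consistency(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 1, (4, 3))
        quads = np.array([[0, 1, 2, 3]])
        params = SimParams(**SMALL)
        st = SimState(
            params=params,
            pos=pos,
            gamma=np.ones(4),
            is_filament=np.ones(4, bool),
            bonds=np.empty((0, 2), int),
            bond_rest=np.empty(0),
            bond_k=np.empty(0),
            angles=np.empty((0, 3), int),
            angle_rest=np.empty(0),
            angle_k=np.empty(0),
            dihedrals=quads,
            dihedral_rest=np.array([0.3]),
            dihedral_k=np.array([1.0]),
            branch_joints=np.empty((0, 2), int),
            rng=rng,
        )
        st.arm_bound_bond = np.empty((0, 0), int)
        st.params = SimParams(volume_exclusion=False, **SMALL)
        from actomech.abm.engine import _dihedral_forces

        f = np.zeros_like(pos)
        _dihedral_forces(st, f)
        h = 1e-7
        for bead in range(4):
            for c in range(3):
                st.pos[bead, c] += h
                ep = 0.5 * (
                    np.arctan2(
                        np.sin(dihedral_angles(st.pos, quads)[0] - 0.3),
                        np.cos(dihedral_angles(st.pos, quads)[0] - 0.3),
                    )
                    ** 2
                )
                st.pos[bead, c] -= 2 * h
                em = 0.5 * (
                    np.arctan2(
                        np.sin(dihedral_angles(st.pos, quads)[0] - 0.3),
                        np.cos(dihedral_angles(st.pos, quads)[0] - 0.3),
                    )
                    ** 2
                )
                st.pos[bead, c] += h
                assert f[bead, c] == pytest.approx(-(ep - em) / (2 * h), abs=1e-5)

    def test_energy_non_increasing_without_thermal(self, small_network):
        _, st0 = small_network
        st = st0.copy()
        rng = np.random.default_rng(2)
        st.pos = st.pos + rng.normal(0, 0.01, st.pos.shape)
        nl = _NeighborList()
        energies = []
        for k in range(200):
            step(st, nl, thermal=False)
            if k % 20 == 0:
                energies.append(potential_energy(st, nl))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_stretched_spring_relaxes_monotonically(self):
        p = SimParams(volume_exclusion=False, **SMALL)
        pos = np.array([[0.3, 0.5, 0.25], [0.55, 0.5, 0.25]])
        st = SimState(
            params=p,
            pos=pos,
            gamma=np.full(2, p.gamma_bead),
            is_filament=np.ones(2, bool),
            bonds=np.array([[0, 1]]),
            bond_rest=np.array([0.1]),
            bond_k=np.array([p.k_stretch]),
            angles=np.empty((0, 3), int),
            angle_rest=np.empty(0),
            angle_k=np.empty(0),
            dihedrals=np.empty((0, 4), int),
            dihedral_rest=np.empty(0),
            dihedral_k=np.empty(0),
            branch_joints=np.empty((0, 2), int),
            rng=np.random.default_rng(0),
        )
        st.arm_bound_bond = np.empty((0, 0), int)
        nl = _NeighborList()
        lengths = []
        for _ in range(300):
            step(st, nl, thermal=False)
            lengths.append(np.linalg.norm(st.pos[1] - st.pos[0]))
        assert all(b <= a + 1e-12 for a, b in zip(lengths, lengths[1:]))
        assert lengths[-1] == pytest.approx(0.1, abs=1e-3)

    def test_overlapping_beads_repel(self):
        p = SimParams(volume_exclusion=True, **SMALL)
        pos = np.array([[0.5, 0.5, 0.25], [0.52, 0.5, 0.25]])
        st = SimState(
            params=p,
            pos=pos,
            gamma=np.full(2, p.gamma_bead),
            is_filament=np.ones(2, bool),
            bonds=np.empty((0, 2), int),
            bond_rest=np.empty(0),
            bond_k=np.empty(0),
            angles=np.empty((0, 3), int),
            angle_rest=np.empty(0),
            angle_k=np.empty(0),
            dihedrals=np.empty((0, 4), int),
            dihedral_rest=np.empty(0),
            dihedral_k=np.empty(0),
            branch_joints=np.empty((0, 2), int),
            rng=np.random.default_rng(0),
        )
        st.arm_bound_bond = np.empty((0, 0), int)
        nl = _NeighborList()
        d0 = np.linalg.norm(st.pos[1] - st.pos[0])
        for _ in range(50):
            step(st, nl, thermal=False)
        assert np.linalg.norm(st.pos[1] - st.pos[0]) > d0

    def test_stability_abort_diagnostic(self, small_network):
        p, st0 = small_network
        st = st0.copy()
        import dataclasses

        st.params = dataclasses.replace(p, dt=10.0)  # absurd timestep
        st.pos = st.pos + np.random.default_rng(3).normal(0, 0.05, st.pos.shape)
        with pytest.raises(StabilityError):
            for _ in range(50):
                step(st, _NeighborList())


class TestPeriodicConsistency:
    def test_lattice_translation_commutes_with_dynamics(self, small_network):
        # exact modulo floating point only while the chaotic contact
        # network is excluded (a one-ulp wrap difference flips
        # neighbour pairs); bonded + thermal dynamics must commute
        # with a lattice translation bit-for-bit in distribution
        import dataclasses

        p, st0 = small_network
        lx = p.domain[0]
        a = st0.copy()
        a.params = dataclasses.replace(p, volume_exclusion=False)
        a.rng = np.random.default_rng(77)
        b = st0.copy()
        b.params = a.params
        b.pos = b.pos + np.array([lx, 0.0, 0.0])
        b.rng = np.random.default_rng(77)
        nla, nlb = _NeighborList(), _NeighborList()
        for _ in range(100):
            step(a, nla)
            step(b, nlb)
        err = np.abs(b.pos - a.pos - np.array([lx, 0.0, 0.0])).max()
        assert err < 1e-9


class TestMotors:
    def test_record_interval_must_divide_timestep(self):
        p = SimParams(seed=1, n_motors=2, **SMALL)
        st = place_motors(assemble_network(p))
        with pytest.raises(ValueError):
            run_motors(st, 3, record_interval=p.dt * 2.5)

    def test_counts_conserved_and_arms_reference_filaments(self):
        p = SimParams(seed=1, n_motors=3, **SMALL)
        st = place_motors(assemble_network(p))
        n_chains = len(st.chains)
        n_branch = len(st.branch_joints)
        traj = run_motors(st, 5, record_interval=0.002)
        assert len(st.chains) == n_chains
        assert len(st.branch_joints) == n_branch
        assert len(st.motor_chains) == 3
        n_fil_bonds = sum(len(cb) for cb in st.chain_bonds)
        bound = st.arm_bound_bond[st.arm_bound_bond >= 0]
        assert np.all(bound < n_fil_bonds)
        assert len(traj) == 3
        assert traj.data.groupby("id")["frame"].count().eq(5).all()

    def test_binding_disabled_leaves_arms_free(self):
        p = SimParams(seed=1, n_motors=2, binding=False, **SMALL)
        st = place_motors(assemble_network(p))
        run_motors(st, 4, record_interval=0.002)
        assert (st.arm_bound_bond < 0).all()

    def test_binding_enabled_attaches_arms(self):
        # at the default density every motor pocket has filaments in
        # reach, so most arms find binding sites quickly
        p = SimParams(seed=1, n_motors=3, binding=True, walking=False)
        st = place_motors(assemble_network(p))
        run_motors(st, 10, record_interval=0.005)
        assert (st.arm_bound_bond >= 0).mean() > 0.3
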