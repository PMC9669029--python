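"""Parameters of the coarse-grained branched-actomyosin simulator.

Units: lengths um, forces pN, energies pN*um, times s.  Filaments,
motors and branch junctions are bead-spring chains of cylindrical
segments evolved by overdamped (Brownian) dynamics.  The mechanical
defaults are drawn from the coarse-grained actomyosin modelling
literature, scaled to a desk-size domain, and every value can be
overridden from the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

__all__ = ["SimParams", "KT_ROOM", "MONOMERS_PER_UM", "UM3_PER_UM_MOLAR"]

KT_ROOM = 4.142e-3  # pN*um at 300 K
MONOMERS_PER_UM = 370.0  # actin monomers per um of filament
#: molecules per um^3 at 1 uM concentration
UM3_PER_UM_MOLAR = 602.2


@dataclass
class SimParams:
    # --- composition -------------------------------------------------
    # The actin concentration is kept at the study value: the mesh size
    # relative to the motor size is what controls caging, so the desk
    # scaling shrinks the domain, not the density.
    c_actin: float = 200.0  # uM
    r_arp: float = 0.01  # C_Arp2/3 / C_A (molar ratio)
    r_motor: float = 0.0025  # C_M / C_A (molar ratio)
    n_motors: Optional[int] = None  # explicit override of the motor count
    motor_length: float = 0.5  # um, motor backbone equilibrium length (L_M)
    arms_per_motor: int = 16  # ~30 nm arm spacing along the backbone

    # --- geometry ----------------------------------------------------
    domain: Tuple[float, float, float] = (1.0, 1.0, 0.5)  # um, x/y periodic
    arrangement: str = "biased"  # 'biased' (seeded at z~0) or 'random'
    n_seeds: int = 12
    segment_length: float = 0.1  # um, cylindrical segment rest length
    branch_angle_deg: float = 70.0  # preferred mother-daughter angle

    # --- toggles -----------------------------------------------------
    volume_exclusion: bool = True
    binding: bool = True
    walking: bool = True

    # --- mechanics ---------------------------------------------------
    k_stretch: float = 50.0  # pN/um, extensional stiffness per segment
    k_bend: float = 0.41  # pN*um/rad^2 (actin persistence length ~10 um)
    k_branch: float = 0.3  # pN*um/rad^2, branch-angle spring
    k_torsion: float = 0.05  # pN*um/rad^2, dihedral spring at branches
    k_repulsion: float = 20.0  # pN/um, soft bead-bead overlap stiffness
    # pair repulsion acts below r_i + r_j; the motor radius includes the
    # arm corona of the thick filament, much wider than an actin segment
    filament_repulsion_radius: float = 0.03  # um
    motor_repulsion_radius: float = 0.08  # um
    # self-avoidance clearance during assembly, as a fraction of the
    # filament-filament contact distance; slightly below 1 so growth can
    # thread dense regions (residual contact energies are < 1 kT each)
    assembly_clearance_factor: float = 0.75
    k_wall: float = 50.0  # pN/um, z-boundary repulsion
    persistence_length: float = 10.0  # um, sets growth-direction noise

    # --- drag / thermal ----------------------------------------------
    viscosity: float = 0.05  # pN*s/um^2 (crowded-medium effective value)
    bead_radius: float = 0.05  # um, hydrodynamic radius of a segment bead
    motor_bead_radius: float = 0.08  # um
    temperature_kT: float = KT_ROOM  # pN*um

    # --- motor activity ----------------------------------------------
    k_arm: float = 10.0  # pN/um, arm (crossbridge) spring
    capture_radius: float = 0.1  # um, arm binding reach
    k_on: float = 40.0  # 1/s, binding rate within reach
    k_off0: float = 0.3  # 1/s, unloaded unbinding rate
    f_bell: float = 2.0  # pN, Bell force scale of unbinding
    v_walk: float = 0.5  # um/s, unloaded stepping speed toward barbed ends
    f_stall: float = 4.0  # pN, stall force of an arm

    # --- integration -------------------------------------------------
    dt: float = 1e-4  # s
    react_every: int = 10  # binding/unbinding/walking sub-sampling (steps)
    neighbor_every: int = 10  # neighbour-list rebuild interval (steps)
    neighbor_skin: float = 0.05  # um
    max_step_frac: float = 2.0  # abort threshold: max |dx| per step / segment_length
    limit_step_frac: float = 0.25  # displacement limiter cap / segment_length

    seed: int = 0

    # --- derived -----------------------------------------------------
    @property
    def volume(self) -> float:
        lx, ly, lz = self.domain
        return lx * ly * lz

    @property
    def n_monomers(self) -> float:
        return self.c_actin * UM3_PER_UM_MOLAR * self.volume

    @property
    def total_filament_length(self) -> float:
        return self.n_monomers / MONOMERS_PER_UM

    @property
    def segment_budget(self) -> int:
        return int(round(self.total_filament_length / self.segment_length))

    @property
    def n_branches(self) -> int:
        return int(round(self.r_arp * self.n_monomers))

    def motor_count(self) -> int:
        if self.n_motors is not None:
            return int(self.n_motors)
        return max(1, int(round(self.r_motor * self.n_monomers / self.arms_per_motor)))

    @property
    def gamma_bead(self) -> float:
        import math

        return 6 * math.pi * self.viscosity * self.bead_radius

    @property
    def gamma_motor_bead(self) -> float:
        import math

        return 6 * math.pi * self.viscosity * self.motor_bead_radius

    def validate(self) -> None:
        if self.r_arp < 0 or self.r_motor < 0:
            raise ValueError("molar ratios must be non-negative")
        if min(self.domain) <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.arrangement not in ("biased", "random"):
            raise ValueError("arrangement must be 'biased' or 'random'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
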