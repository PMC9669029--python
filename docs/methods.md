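# Methods

`actomech` quantifies how the architecture of a reconstituted F-actin
network — branched (Arp2/3-nucleated) versus linear (formin-nucleated)
— constrains the motion of embedded myosin-II thick filaments and the
contractility of the network. It implements the image-, trajectory-
and simulation-level machinery of that analysis, together with
synthetic-data generators that supply every input class with known
ground truth, so the whole pipeline is testable without microscopy
data.

Units are physical throughout: lengths in µm, times in s, forces in
pN, energies in pN·µm; filament-axis angles are nematic (θ and θ+π
identified, stored in [−π/2, π/2)).

## Trajectory statistics

The translational ensemble MSD is defined through
4 D_T τ^α = ⟨Δr²(τ)⟩ and the rotational one through
2 D_θ τ^α = ⟨Δθ²(τ)⟩. We time-average over all overlapping windows
within each trajectory and then ensemble-average (the alternative,
non-overlapping windows, discards most of the data at no bias
benefit). α and the coefficient come from a linear fit of log MSD vs
log τ; by default only the first two thirds of available lags enter
any curve, because long lags average too few windows. Angular steps
are unwrapped nematically — successive differences are mapped into
(−π/2, π/2] before accumulation — so replacing θ by θ+π anywhere
leaves MSD_θ unchanged.

The van Hove distribution collects translational step magnitudes (or
signed angular steps) at a lag; simple diffusion gives the expected
Gaussian statistics, caged motion an excess central spike, persistent
motion heavy tails. The non-Gaussian parameter is evaluated exactly
as NGP(τ) = 3⟨r⁴⟩/(5⟨r²⟩²) − 1. Note that the 3/5 coefficient is the
*three*-dimensional Gaussian normalisation: isotropic 3-D Gaussian
steps give 0, while the 2-D tracking geometry used here gives 0.2 for
Gaussian steps and fixed-magnitude steps give −0.4. We keep the
printed form for fidelity and document the 2-D offset so curves are
not misread.

Per-trajectory kinematics report v_max (maximum instantaneous speed),
v_EE (end-to-end distance over total time), the filament length
L_myo, and v_EE/L_myo; trajectories whose consecutive displacements
never exceed the 0.1 µm pixel resolution are flagged immobile. The
speed–length relation is summarised by the least-squares slope of
v_EE against L_myo and its absolute value.

## Two-point correlation

For every ordered pair (i≠j) coexisting at start time t with lag τ,
both displacement vectors are projected on the unit separation vector
at t, and the product is accumulated into the radial bin of the
start-time separation (40 bins over 3–20 µm by default). The
normalised variant divides each pair product by the product of the
two displacement magnitudes (pairs with a near-zero magnitude are
excluded by a configurable floor), and the reported C_rr(r) averages
the 10 smallest lags. All start times are used. A power-law fit of
log C_rr vs log r over 3–20 µm returns the decay exponent together
with R² and the fraction of positive bins, so cases where a 1/r form
cannot be assigned are detectable. Both accumulators agree with a
naive O(N²·T) enumeration to 1e−10 relative tolerance on small
instances (tested).

## Correlated-displacement generator

The generator that validates the two-point pipeline places tracers in
the mid-height plane of a box and draws per-epoch displacements from
a multivariate Gaussian whose inter-particle covariance is the
unit-viscosity Stokeslet (Oseen) tensor, amplitude·(I + n̂n̂ᵀ)/(8πr):
the thermal two-point correlation of a viscous continuum, with an
exactly 1/r longitudinal decay. The self-variance is the smallest
diagonal keeping the covariance positive definite (a factor 1.05
above the magnitude of the most negative interaction eigenvalue),
i.e. the strongest admissible pair correlation; the amplitude is
small (1e−4) so tracers do not wander across radial bins over the
movie. Epochs are i.i.d. (temporally white forcing).

Two alternative constructions are retained for cross-checks: explicit
superposition of point-force *dipoles* (net-force-free forcing), and
an independent-displacement null mode. Superposing unbalanced
monopole Stokeslets does **not** produce a 1/r covariance in a finite
box — the far field leaves a nearly constant common mode — and the
heavy tails of any source superposition bias the *normalised*
correlation shallow; both findings drove the Gaussian default. The
brute-force pair-averaged covariance oracle
(`FieldRealization.longitudinal_covariance`) is computed and gated on
before the generator is used in the acceptance path.

## Imaging metrics

*Preprocessing*: Gaussian smoothing at 0.1 µm, rolling-background
subtraction (morphological opening with a 0.5 µm disk), simple-ratio
bleach correction (each frame scaled so its mean matches frame 0),
and translation-only registration to frame 0 by phase
cross-correlation.

*Local orientation*: windows of 3.5 µm at 80% overlap; each window is
mean-subtracted, Hann-apodised (unapodised square windows leak
spectral power along the array axes and bias orientations by several
degrees), Fourier-transformed, and the axis of least second moment of
the power spectrum is rotated by 90° to give the texture axis.
Margins that do not fit a complete window are dropped; zero-variance
windows are masked.

*Nematic order*: n = 2⟨cos²θ_d − 1/2⟩ over the angle differences θ_d
between each interior window and its 8 neighbours in a 3×3 kernel;
masked neighbours are excluded. Perfect alignment gives exactly 1.
The −1 limit requires *every* neighbour to differ by 90°, which no
two-orientation checkerboard can realise (diagonal neighbours share
the orientation); the formula's lower limit is therefore exercised on
a synthetic orientation field directly, and a 0°/90° striped
arrangement sits at −1/2.

*Pore sizes*: threshold at the mean intensity; 8-connected dark
regions that do not touch the image border are pores (closed-pore
semantics), with areas in µm².

*Radial distribution*: white-pixel counts in annuli around
(subsampled, default 2000) white-pixel centres, divided by the ring
circumference, fitted with A·e^{−r/λ}. Centres keep a margin of
r_max from the borders so every ring is complete; truncated rings
would bias g(r) downward at large r. Note the measured profile is the
two-point (self-convolved) statistic of the density field: point
clusters scattered with an exponential envelope of scale λ* produce a
pair profile with decay length ≈ 2λ* (the test oracle computes this
numerically).

*Fluctuation autocorrelation*: pixel-wise products of mean-subtracted
frame pairs, averaged over all start frames per lag, normalised at
lag 0, fitted over the first 40% of lags with
a₁e^{−t/τ₁} + (1−a₁)e^{−t/τ₂} + a₄ using bounded least squares.
Fitting starts both from a near-degenerate single-exponential guess
and from a split two-timescale guess, and the split solution is kept
only when it improves the residual meaningfully — otherwise the
double exponential overfits sampling noise on genuinely
single-exponential data by drifting one time constant. Components
with negligible weight are dropped; the larger retained time constant
is the reported network timescale.

## PIV strain and Kelvin–Voigt fits

PIV uses single-pass, overlap-normalised *linear* cross-correlation
of mean-subtracted 32-px windows at 50% overlap (circular FFT
correlation biases peaks toward zero lag for partially overlapping
content), a search radius of a quarter window, 3-point Gaussian
sub-pixel interpolation per axis, and a tie-break toward the smaller
displacement. Windows whose peak correlation coefficient falls below
0.3 are masked. On a well-textured image a 5-px shift is recovered to
better than 0.1 px.

Consecutive-frame fields are accumulated into a cumulative
displacement so that ⟨ε⟩(t) = ⟨∇·x_c⟩ is a strain relative to frame 0
(matching the Kelvin–Voigt step-response convention; a per-frame
option exists). Divergence is taken by central differences on the
window grid, which annihilates constant fields exactly. ⟨ε⟩_max is
the signed extremum, and the strain rate is a linear fit over the
contiguous window where |⟨ε⟩| rises from 10% to 80% of its extremum.
The Kelvin–Voigt model ε(t) = (σ/E_v)(1 − e^{−t/τ_v}), τ_v = η_v/E_v,
is fitted by bounded least squares on the rising branch; series with
no rising phase are flagged degenerate.

## Detection and linking

Detection is threshold-and-label segmentation (Otsu, mean, or
absolute threshold) with intensity-weighted centroids; each object's
axis angle and length come from its minimum-area rotated bounding box
(via the rotating-calipers rectangle of the pixel set). Linking is
greedy nearest-neighbour assignment with global conflict resolution —
candidate track–detection pairs sorted by squared displacement, each
used once — rather than full global optimisation, which is adequate
at the low object densities this data has. An object may go
undetected for up to 3 frames and keep its identity; after that a new
id starts. When two tracks claim one detection (objects merging),
only the cheaper keeps it.

## Passive microrheology

α(τ) is the centred finite difference of ln MSD vs ln τ (one-sided at
the boundaries), and the modulus magnitude follows the algebraic
generalized Stokes–Einstein form
|G*(ω)| = k_BT / (π a ⟨Δr²(1/ω)⟩ Γ[1+α(1/ω)]), assuming purely
thermal fluctuations. Only the first two thirds of lags are used.
The formula is dimension-agnostic as printed; with 2-D tracking MSDs
it carries a constant offset relative to the 3-D convention (4Dτ vs
6Dτ — a factor 3/2 on |G*| for a viscous fluid), so results state the
MSD convention. Lags where α ≤ −1 (the Γ pole) are masked.

## Brownian-dynamics simulator

The simulator is a coarse-grained overdamped (Langevin) model of an
Arp2/3-branched actin network with multi-arm motors. Filaments are
bead–spring chains of 0.1 µm segments with extensional (50 pN/µm) and
angular springs (0.41 pN·µm/rad², i.e. a 10 µm persistence length at
this discretisation); an Arp2/3 junction is a bead shared between
mother and daughter, held at the preferred 70° branch angle by an
angular spring (0.3 pN·µm/rad²). Torsional resistance at a branch is
implemented as a second, weaker angular spring between the daughter
direction and the distal mother segment at its as-built angle: a
four-point dihedral about a near-straight mother axis is numerically
singular (a straight bead chain carries no material frame), whereas
the two angle springs jointly pin the daughter's azimuth wherever the
mother is bent. (Verified dihedral machinery is retained for
explicitly supplied quads.) Volume exclusion is a soft half-harmonic
bead-pair repulsion acting below the sum of per-bead radii — 0.03 µm
for filament beads and 0.08 µm for motor beads, the latter
representing the arm corona of a thick filament. The domain is
periodic in x and y (minimum image on all non-bonded interactions)
with repulsive z walls. Thermal forces satisfy
fluctuation–dissipation per bead drag (Stokes drag at an effective
medium viscosity of 0.05 Pa·s), integrated by Euler–Maruyama at
dt = 1e−4 s. Rare contact-force spikes are handled by a per-bead
displacement limiter (cap 0.25 segment lengths; a diagonal PSD
rescaling, so deterministic relaxation still descends the energy),
with a hard stability abort at 2 segment lengths.

*Assembly.* The actin budget follows from C_A and the domain volume
(370 monomers per µm of filament); seed filaments elongate at their
barbed tips with direction noise set by the persistence length, and
branch events consume the Arp2/3 budget (R_Arp2/3 · monomers), one
daughter per bead at most. Growth is self-avoiding at 75% of the
contact distance (residual contact energies < 1 kT each): assembling
with unconstrained overlaps stores thousands of kT of contact energy
whose slow release masquerades as network motion. Blocked tips
deflect around obstacles by escalating direction noise. The as-built
geometry is the stress-free reference (growth kinks are frozen-in
curvature, not elastic strain); nucleation kinetics are not modelled.
'biased' seeding starts near z = 0 growing outward, emulating
nucleation at a supported bilayer; 'random' seeds uniformly and
isotropically.

*Motors.* A motor is a backbone chain (default L_M = 0.5 µm, 16 arms
at fixed arc positions) placed into the least-overlapping pocket
among candidate positions near z ≈ 0 (biased) or mid-height (random),
so volume exclusion does not expel it in a startup transient. Arms
bind to filament segments within a 0.1 µm capture radius at 40 s⁻¹
as *relaxed* tethers — the spring rest length is set to the
separation at binding. Binding arms as stretched springs would inject
up to ~12 kT per event and act as an artifactual motor. Bound arms
walk toward barbed ends at 0.5 µm/s with a linear force–velocity
relation (stall at 4 pN) and unbind at a Bell rate
k₀·exp(F/2 pN) with k₀ = 0.3 s⁻¹, with force applied at the bound
point and reacted on the backbone (momentum-conserving).

*Desk scale.* The default conditions keep the study's actin
concentration, C_A = 200 µM, and R_Arp2/3 = 0.01, and shrink the
*domain* to 1×1×0.5 µm (~1650 beads) with a proportionally shortened
motor. The alternative — keeping a larger domain and diluting C_A —
was implemented first and abandoned: at reduced density the mesh size
(~0.14 µm vs ~0.055 µm at 200 µM) exceeds every relevant interaction
range, the network flows instead of jamming, and the confinement
phenomenology inverts. The ratios that control the physics
(mesh/motor size, branching ratio) are preserved rather than the
domain volume. At these conditions, across independent network
realizations: motor MSD with volume exclusion lies below the
matched run without it at all recorded lags, and the motor MSD at
fixed lag decreases monotonically across R_Arp2/3 ∈ {0, 0.005, 0.01}
— linear networks provide long coherent tracks for walking while
branched daughters (~0.3 µm) dead-end immediately, and the dense
branched mesh cages the motor corona. Confinement comparisons use
the full 3-D displacement; free-diffusion slope checks use the
unconfined in-plane components (the z extent is half a micron).
The z density gradient of biased assembly is assayed in a 2-µm-tall
domain at half filling: the default slab is only ~5 segments high,
and a budget that saturates box capacity is uniform by construction.

## What the synthetic data do and do not emulate

Generators reproduce the *statistical structure* the pipeline
measures: Gaussian/fractional/ballistic trajectories with exact
increment covariance (fBm via Davies–Harte circulant embedding),
displacement fields with prescribed 1/r pair correlation, striped /
filamentous / porous textures, single-exponential movie correlations,
Kelvin–Voigt strain responses, and advected textures with prescribed
divergence. They do not model microscope PSFs, shot noise beyond
additive Gaussian options, photobleaching chemistry, or filament
turnover; passing tests demonstrate the correctness of the analysis
machinery on data whose truth is known, not the biology of any
particular experiment. Likewise the simulator omits turnover,
severing, hydrodynamic interactions, and nucleation kinetics.

## Numerical choices and degenerate inputs

- Zero-variance orientation windows, empty radial bins, zero-length
  displacements and zero-mean frames are masked or rejected with
  explicit errors rather than propagated.
- MSD fits need ≥ 4 usable lags; power-law fits ≥ 6 positive bins;
  frozen trajectories are flagged degenerate.
- All generators and the simulator are bit-reproducible under a fixed
  seed; the CLI writes the resolved configuration, seed and package
  version with every run, and identical config+seed yields identical
  outputs.
- Configuration is strict: unknown keys raise instead of silently
  falling back to defaults.

## Problem sizes used in the test and acceptance runs

Trajectory cohorts of 300 × 600 steps; correlated fields of 250
tracers × 2000 epochs; images of 200–384 px; simulator runs of
~1650 beads for 1–2 s of model time (10–20k steps), with two network
realizations averaged per condition in the confinement comparisons.
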