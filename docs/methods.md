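# Methods

`dmhs` simulates dispersed solid–liquid flows in 2D by letting several
particle methods act on one shared set of computational particles.  A
*real* particle (a cell, a cube, a grain of solidified melt) is discretized
into several *elemental* particles; the fluid is discretized into SPH
particles; and every pairwise interaction is routed by phase and body
membership:

| pair                              | treatment                               |
|-----------------------------------|-----------------------------------------|
| fluid–fluid (and fluid–wall)      | weakly-compressible SPH                 |
| solid–solid, same body            | harmonic bead-spring network            |
| solid–solid, different bodies     | DEM spring–dashpot contact              |
| solid–fluid                       | repulsive LJ + viscous no-slip coupling |

All particles obey `m_i dv_i/dt = Σ_j F_ij + F_ext`, integrated with
velocity Verlet (kick–drift–kick; symplectic, one force evaluation per
step).  Scalar fields (density, internal energy, water mass) advance by
forward Euler with rates evaluated at the end-of-step configuration; their
error is dominated by the spatial discretization at the step sizes used.

## Fluid model

Weakly-compressible SPH with the 2D cubic-spline kernel (support `2h`,
normalization `10/(7πh²)`).  Density evolves through the continuity
equation `dρ_i/dt = Σ_j m_j (v_i−v_j)·∇_i W_ij`; pressure closes through
the Tait equation of state `P = (c0²ρ0/7)[(ρ/ρ0)⁷ − 1]` (negative
pressure allowed, no clipping).  An optional kernel-sum density
reinitialization is available but off by default.

Two viscous pair terms are implemented: Monaghan's artificial viscosity for
inertial regimes, with `α` mapped from the physical viscosity via the 2D
relation `α = 8ν/(h c0)` and floored at 0.02 so acoustic modes stay damped
near the CFL limit, and the Morris et al. physical-viscosity term for
creeping flows (the default in the cell scenarios).  Each scenario's
numerical sound speed obeys `c0 ≥ 10 × (expected flow speed)` and, where a
body force acts over a height `L`, `c0 ≥ √(200 f L)`; both bounds keep the
observed density deviations below 1 % of `ρ0` in every shipped scenario.

Channel walls are three layers of frozen *dummy* particles that take part
in the full SPH sums (density, pressure, viscosity) with a prescribed
velocity.  A Dirichlet value — wall velocity or wall temperature — is
therefore imposed *at the first wall-particle row*, half a lattice spacing
outside the fluid; the analytic comparisons use the corresponding
effective width `L + ΔL`.  With that convention the shipped resolutions
give: Poiseuille 1.5 %, Couette 0.5 %, transient conduction 0.6 %,
half-space diffusion 0.5 % (L2).

## Solids

A solid body is a bead network with harmonic potentials
`U = k_b(r−r0)²`, `U = k_a(θ−θ0)²` and `U = k_d(φ−φ0)²` (dihedrals are
meaningful only in 3D and are unused by the 2D scenarios, though fully
implemented and oracle-tested).  Printed equilibrium angles such as 172.5
and 157.5 are interior angles of the regular 48- and 16-gon in degrees.
Builders provide closed membrane rings (consecutive bonds + hinges; one
layer, so the membrane has elastic and bending moduli but no shear or
torsional stiffness) and shear-braced rectangular lattices (nearest-
neighbor bonds + 90° corner hinges on every unit square).

Bonds whose length exceeds `r_max` break irreversibly once per step, after
integration; hinges that reference a broken pair are removed with it.  For
the brittle cubes the printed ratio 0.001 is read as the *allowed strain*
`(r_max−r0)/r0`.

## Contacts and the interface

DEM contacts act between elemental particles of different bodies with
overlap `δ = R_i+R_j−|r_ij|`:

* normal: `f_n = k_n δ + m_eff γ_n v_n` with `v_n` the approach rate,
  clamped to `f_n ≥ 0` (a dashpot never produces adhesion at separation);
* tangential: a history spring on the accumulated tangential displacement
  `ξ` (re-projected onto the current tangent each step), Coulomb-limited:
  stick while `|f_t| ≤ μ_s f_n`, otherwise slide at `μ_d f_n` with `ξ`
  rescaled to the sliding value.  Where only `μ_s` is printed,
  `μ_d = μ_s`; the conventional ordering `μ_d ≤ μ_s` is enforced.

The spring–dashpot restitution obeys `e = exp(−γπ/2ω_d)` in the unclamped
model; the non-adhesive clamp raises `e` by an amount that grows with
damping, so the closed-form check is run in the lightly damped regime
(`ζ ≤ 0.07`), where the correction is below the 1 % tolerance.

The solid–liquid interface uses a Lennard-Jones force truncated at the
potential minimum `2^(1/6)σ` (purely repulsive — no-penetration) plus the
Morris viscous pair term computed against solid-surface particles carrying
the solid's velocity (dummy-particle no-slip).  Elemental DEM radii default
to half the body's lattice spacing.

## Heat and phase change

Internal energy per unit mass follows the SPH conduction sum
`de_i/dt = Σ_j m_j (κ_i+κ_j)(T_i−T_j) F_ij/(ρ_iρ_j)` with
`F_ij = W′(r)/r`; the pair exchange is antisymmetric in `m·e`, so closed
conduction conserves total thermal energy to round-off.  Temperature
follows from the caloric equation of state with a latent plateau
(`T = e/c_vS` below the solidus, `T = T*` on the plateau,
`T = (e−e_liq)/c_vL + T*` above), continuous, monotone and invertible off
the plateau; setting `e_sol = e_liq` switches latent heat off.

Free-surface particles (coordination number `< 5.5` within cutoff `h`)
cool against a virtual isothermal air, `dT/dt = −k_T(T−T_air)`, converted
to an energy rate through the local EOS slope; on the plateau the liquid
capacity is used so latent heat keeps draining and solidification proceeds.

Crossing the solidus turns an SPH-carried particle into a DEM particle and
bonds it harmonically to every already-solid particle within the bond
search radius; same-step cohorts bond pairwise, which removes any
processing-order dependence.  An already-solid particle never initiates
new bonds.  Crossing the liquidus melts a solid particle back to the fluid
and deletes every bond that references it.  A consistency audit (no fluid
particle referenced by any bond) runs after every solidify/melt pass.

For sub-scale-solids rheology (the lava scenario) a pair force can be
blended as `λ̄ F_SPH + (1−λ̄) F_DEM`, with `λ` the liquid fraction — either
the caloric-EOS fraction or, for glass-like transitions without latent
heat, a linear ramp in temperature over a configured interval.

## Solute transport, swelling, adhesion

Water mass diffuses through the same pair structure,
`dw_i/dt = m_i Σ_j m_j (D_i+D_j)(c_i−c_j) F_ij/(ρ_iρ_j)`, with the closure
`c = wρ/m` clamped to `[0,1]`; in that form the continuum limit is exactly
`dc/dt = D∇²c`.  Bulk-water particles are a non-depleting reservoir at
`c = 1`; the injected mass is logged.  Soil particles swell — area grows
linearly with absorbed water (default gain: +50 % area at saturation),
radius, mass and density updated accordingly — and their van der Waals
adhesion (full LJ well) decays linearly in the mean pair concentration,
vanishing at `c = 0.5`.  Only the `r⁻⁶` attraction decays; the `r⁻¹²` core
keeps its dry strength so wetted particles remain excluded-volume bodies.

In quiescent-fluid mode (the pin-array sorter) there is no SPH carrier at
all and water resistance enters as classical Stokes drag
`F = −6πμ r_i v_i`.

## Numerical choices

* Neighbor search: one global cutoff per step (the maximum of kernel
  support, contact diameter, LJ cutoff and bond-search radius) via a
  kd-tree with minimum-image handling on periodic axes; rebuilt every step.
* Pair bookkeeping: each pair stored once (`i < j`) and applied equal and
  opposite, which makes momentum conservation structural.
* Time steps respect the acoustic CFL (`dt ≤ 0.25 h/c0`), the viscous
  limit (`dt ≤ 0.125 h²/ν`), the conduction/diffusion limits
  (`dt ≲ 0.1 h²/α`), and contact/bond oscillation periods (`≥ 200` steps
  per contact, `≥ 60` per bond period).
* Degenerate geometry: coincident bonded particles and zero-length hinge
  arms are hard errors; exactly collinear hinges (sin θ below 1e-10)
  contribute no force; LJ forces are capped below `0.5σ` with a warning
  (an over-penetration signals a too-large step).
* Any non-finite state aborts the run with the step and particle index;
  the last valid frame is flushed first.

## Scenarios and reduced variants

The full-scale configurations keep the published parameter sets: the
micron-scale cell-in-channel family (2048 carrier fluid particles at
ΔL = 5 µm, a 48-bead membrane with 61 cytoplasm particles, `k_b = 10` J/m²,
`k_a = 1e−18` J), cubes in Poiseuille flow (7×7 bodies, `k_n = 1e5` J/m²,
neutral/buoyant/heavy variants), casting (`e_sol = 50`, `e_liq = 100` J/kg,
`c_vS = 2`, `c_vL = 1` J/(kg·K), `κ_wall = 100`, `k_T ∈ {0.02, 0.5}` 1/s),
cleaning (soil Ø 47 µm at ρ = 1800 kg/m³, `D = 1e−9` m²/s, well depths
7e−11 / 5e−10 J, moving wall 2e−4 m/s), lava on a 30° incline (solidus
500 °C, liquidus 1000 °C, `k_n = 1e6` J/m²) and the pin-array sorter
(16-bead cells of radius 10 µm, pitch 30 µm, `k_a` 1e−15 vs 1e−16 J,
driving force 100 m/s²).  Values the source setups leave open were fixed
once as scenario defaults: channel cross-sections sized to hold the printed
particle counts at the printed spacing, pin diameter 10 µm, coupling well
depths scaled so the repulsive cap exceeds a particle weight by ~100×,
carrier gravity in the cleaning problem (9.81 m/s², since nothing else
anchors adhesion-free soil), and water-like viscosities where none is
printed.

Published-scale runs take 10⁷–5×10⁷ steps; the shipped `*_reduced`
variants re-scale so each phenomenology measurement fits in minutes on one
CPU while preserving the governing dimensionless ratios:

* **casting_slow_reduced** — an 8×8 melt at rest in the mould, transport
  only (motion frozen), 3000 × 10 ms steps; used for the wall-to-bulk
  solidification-ordering statistic (Spearman ρ ≈ 0.94).
* **casting_fast_reduced** — a 6×6 blob falling ~5 s under reduced gravity
  (1 m/s²), longer than the 2 s surface-cooling time at `k_T = 0.5` but
  far shorter than the 50 s at `k_T = 0.02`, so the crust-before-contact
  contrast is decidable in 45 000 steps.
* **cleaning_reduced** — boosted diffusivity (1e−7 m²/s), faster wall
  (1e−3 m/s), thicker carrier (μ = 1e−2 Pa·s) and scaled gravity (2 m/s²);
  soil counts as washed away once it has advected three dry diameters from
  its site (irreversible).  22 000 × 70 µs steps.
* **plinko_reduced** — scaled units (cell radius = 1, bead mass = 1): a
  6-lane chip, 10 staggered pin rows with surface gap 0.9 cell diameters,
  8+8 cells, 10× bending-stiffness contrast (`k_a` 5 vs 50), drag-dominated
  descent; 25 000 × 5 ms steps.  The flexible stiffness sits in the window
  where a ring can squeeze through a sub-diameter gap but does not drape
  over a pin: far softer membranes wrap around the pins and the sorting
  *inverts*, which is itself a physically sensible regime but not the one
  of interest.

What the reduced variants do *not* emulate: published step counts and
domain sizes, 3D effects, thermal feedback on viscosity, surface tension,
Brownian motion.  Passing the reduced-scale phenomenology shows the model
reproduces the qualitative mechanisms (conduction-ordered solidification,
wetting-gated removal, rigidity-based sorting) at desk scale; it is not a
quantitative validation against experiments.

## Known limitations

* 2D only; no rotational degrees of freedom for grains (bodies are
  multi-particle, so torque emerges from the constituent forces).
* Forward-Euler scalar updates limit the conduction/diffusion step sizes.
* The hard SPH→DEM solidification switch perturbs the neighboring fluid;
  the artificial-viscosity floor keeps this stable but locally smooths the
  velocity field.
* The weakly-compressible contract degrades under strong impacts (the
  printed sound-speed rule is a lower bound; impact scenarios use the
  impact velocity in the rule).
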