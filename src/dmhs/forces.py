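"""Pair-interaction dispatch: one neighbor list, four interaction types.

Every pair of computational particles is routed to the applicable force
families by phase and body id:

* fluid-fluid (and fluid-wall)          -> SPH pressure + viscous forces
* solid-solid, same body                -> bead-spring forces (via topology)
* solid-solid, different bodies         -> DEM contact (or adhesive LJ)
* solid-fluid                           -> LJ no-penetration + viscous no-slip

Partially solidified (TRANSITION) particles are SPH-carried; with blending
enabled their pair forces are mixed, lambda_pair * F_SPH +
(1 - lambda_pair) * F_DEM, with lambda the liquid fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cgmd, dem, sph, thermo, transport
from .core import (
    BoundarySpec,
    NeighborList,
    ParticleSystem,
    Phase,
    apply_external_forces,
    coordination_numbers,
)


@dataclass
class Rates:
    """Scalar-field rate terms evaluated together with the forces."""

    drho: np.ndarray | None = None
    de: np.ndarray | None = None
    dw: np.ndarray | None = None
    surface_flux: float = 0.0  # sum m_i * de_i from Newton cooling (J/s)
    injected_water: float = 0.0  # reservoir water handed to soil (kg/s)


@dataclass
class Model:
    """All material laws and physics toggles of one scenario."""

    boundary: BoundarySpec
    kernel: sph.KernelSpec | None = None
    fluid: sph.FluidLaw | None = None
    contact: dem.ContactLaw | None = None
    coupling: dem.CouplingLaw | None = None
    thermal: thermo.ThermalLaw | None = None
    diffusion: transport.DiffusionLaw | None = None
    body_force: np.ndarray = field(default_factory=lambda: np.zeros(2))
    drag_mu: float = 0.0
    blending: bool = False
    wall_sph: bool = True
    wall_conduction: bool = True
    isothermal_walls: bool = False
    motion: bool = True  # False freezes positions/velocities (pure transport)

    def cutoff(self, system: ParticleSystem) -> float:
        """One global neighbor cutoff covering every interaction range."""
        c = 0.0
        if self.kernel is not None:
            c = max(c, self.kernel.support)
        if self.contact is not None and system.radius.size:
            c = max(c, 2.0 * float(system.radius.max()))
        if self.coupling is not None:
            c = max(c, self.coupling.r_c)
        if self.thermal is not None:
            c = max(c, self.thermal.bond_search_radius)
        if self.diffusion is not None and self.diffusion.r_c_adh:
            c = max(c, self.diffusion.r_c_adh)
        if c <= 0.0:
            raise ValueError("model defines no interaction range")
        return c


def compute_forces(
    system: ParticleSystem,
    nlist: NeighborList,
    topology: cgmd.BondTopology,
    ledger: dem.ContactLedger,
    model: Model,
    dt: float,
) -> Rates:
    """Zero the accumulators, route every pair, return the scalar rates."""
    phase = system.phase
    if np.any((phase < 0) | (phase > 3)):
        bad = int(np.argwhere((phase < 0) | (phase > 3))[0][0])
        raise ValueError(f"particle {bad} has unknown phase {int(phase[bad])}")
    system.force[:] = 0.0
    rates = Rates()

    is_wall = phase == int(Phase.WALL)
    is_solid = phase == int(Phase.SOLID)
    is_fluidish = np.isin(phase, (int(Phase.FLUID), int(Phase.TRANSITION)))

    lam = None
    if model.blending and model.thermal is not None:
        lam = thermo.blend_weights(system, model.thermal)

    ph_i = phase[nlist.i]
    ph_j = phase[nlist.j]
    wall_i = ph_i == int(Phase.WALL)
    wall_j = ph_j == int(Phase.WALL)
    fluidish_i = is_fluidish[nlist.i]
    fluidish_j = is_fluidish[nlist.j]
    solid_i = is_solid[nlist.i]
    solid_j = is_solid[nlist.j]

    # ---------------- fluid-fluid: SPH family ----------------
    if model.kernel is not None and model.fluid is not None:
        spec, law = model.kernel, model.fluid
        sph_i = fluidish_i | (wall_i & model.wall_sph)
        sph_j = fluidish_j | (wall_j & model.wall_sph)
        m = sph_i & sph_j & ~(wall_i & wall_j) & (nlist.dist < spec.support)
        m &= nlist.dist > 0.0
        pairs_s = nlist.subset(m)

        sph_active = is_fluidish | (is_wall & model.wall_sph)
        system.pressure[sph_active] = sph.tait_pressure(
            system.density[sph_active], law
        )

        rates.drho = sph.continuity_rhs(system, pairs_s, spec)
        rates.drho[~sph_active] = 0.0

        weight = 1.0
        if lam is not None:
            weight = 0.5 * (lam[pairs_s.i] + lam[pairs_s.j])
        sph.sph_momentum_forces(system, pairs_s, spec, law, weight=weight)

        # ------------- solid-fluid interface coupling -------------
        if model.coupling is not None:
            mc = (solid_i & fluidish_j) | (solid_j & fluidish_i)
            pairs_c = nlist.subset(mc & (nlist.dist > 0.0))
            dem.lj_coupling_forces(system, pairs_c, model.coupling)
            if model.coupling.no_slip:
                mv = pairs_c.dist < spec.support
                sph.morris_viscous_forces(
                    system, pairs_c.subset(mv), spec, law.mu
                )

    # ---------------- same-body solids: bead springs ----------------
    if topology is not None and (topology.n_bonds or topology.n_angles):
        cgmd.cgmd_forces(system.position, topology, out=system.force)

    # ---------------- inter-body solids: DEM contacts ----------------
    if model.contact is not None:
        dem_i = solid_i | wall_i
        dem_j = solid_j | wall_j
        if lam is not None:
            # blending: SPH-carried particles with a solid fraction also
            # collide; their DEM force is scaled by (1 - lambda_pair)
            dem_i = dem_i | fluidish_i
            dem_j = dem_j | fluidish_j
        m = dem_i & dem_j & ~(wall_i & wall_j)
        bid_i = system.body_id[nlist.i]
        bid_j = system.body_id[nlist.j]
        m &= (bid_i != bid_j) | (bid_i < 0)
        if topology is not None and topology.n_bonds:
            keys = cgmd.bond_pair_keys(
                np.stack([nlist.i, nlist.j], axis=1), system.n
            )
            bonded = np.isin(keys, cgmd.bond_pair_keys(topology.bonds, system.n))
            m &= ~bonded
        pairs_d = nlist.subset(m)
        weight = 1.0
        if lam is not None:
            weight = 1.0 - 0.5 * (lam[pairs_d.i] + lam[pairs_d.j])
        dem.dem_contact_forces(system, pairs_d, model.contact, ledger, dt, weight)

    # ---------------- van der Waals adhesion (cleaning) ----------------
    if model.diffusion is not None and model.diffusion.sigma_adh > 0.0:
        dl = model.diffusion
        m = (
            ((solid_i & solid_j) | (solid_i & wall_j) | (wall_i & solid_j))
            & (nlist.dist > 0.0)
        )
        pairs_a = nlist.subset(m)
        if pairs_a.n_pairs:
            surface_pair = is_wall[pairs_a.i] | is_wall[pairs_a.j]
            eps_dry = np.where(surface_pair, dl.eps_surface, dl.eps_pair)
            c_pair = 0.5 * (
                system.concentration[pairs_a.i] + system.concentration[pairs_a.j]
            )
            eps_eff = transport.scale_adhesion(c_pair, eps_dry, dl)
            dem.adhesive_lj_forces(
                system,
                pairs_a,
                eps_eff,
                dl.sigma_adh,
                dl.r_c_adh,
                epsilon_core=eps_dry,
            )

    # ---------------- heat transfer ----------------
    if model.thermal is not None and model.kernel is not None:
        law = model.thermal
        conducts = ~is_wall | (is_wall & model.wall_conduction)
        m = (
            conducts[nlist.i]
            & conducts[nlist.j]
            & ~(wall_i & wall_j)
            & (nlist.dist < model.kernel.support)
            & (nlist.dist > 0.0)
        )
        kappa = law.kappa_of(system)
        rates.de = thermo.heat_conduction_rhs(
            system, nlist.subset(m), model.kernel, kappa
        )
        if law.k_T > 0.0:
            coord = coordination_numbers(nlist, system.n, model.kernel.h)
            de_cool = thermo.surface_cooling_rhs(system, coord, law)
            rates.de += de_cool
            rates.surface_flux = float(np.sum(system.mass * de_cool))
        if model.isothermal_walls:
            rates.de[is_wall] = 0.0

    # ---------------- water diffusion ----------------
    if model.diffusion is not None and model.kernel is not None:
        dl = model.diffusion
        participates = ~is_wall
        m = (
            participates[nlist.i]
            & participates[nlist.j]
            & (nlist.dist < model.kernel.support)
            & (nlist.dist > 0.0)
        )
        D = np.where(participates, dl.D, 0.0)
        rates.dw = transport.mass_diffusion_rhs(
            system, nlist.subset(m), model.kernel, D
        )
        if dl.reservoir_fluid:
            reservoir = is_fluidish
            rates.injected_water = -float(np.sum(rates.dw[reservoir]))
            rates.dw[reservoir] = 0.0

    # ---------------- external forcing ----------------
    if np.any(model.body_force != 0.0):
        apply_external_forces(system, model.body_force)
    if model.drag_mu > 0.0:
        transport.stokes_drag(system, model.drag_mu)

    return rates
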