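"""Heat transfer, the caloric equation of state and the phase state machine.

Internal energy e (J/kg) is carried per particle and evolved by the SPH
conduction sum; temperature follows from the caloric equation of state with
a latent-heat plateau

    T = e / c_vS                    e <  e_sol
    T = T*                          e_sol <= e <= e_liq
    T = (e - e_liq)/c_vL + T*       e >  e_liq

Free-surface particles (coordination number below a threshold, cutoff h)
additionally exchange heat with a virtual isothermal air via Newton's law of
cooling.  Crossing e_sol solidifies a particle: it leaves the SPH fluid
family, joins the DEM family and bonds harmonically to every already-solid
neighbor within a search radius.  Crossing e_liq melts it back: all its
bonds are destroyed and it rejoins the fluid.  Partially solidified
("transition") particles may blend SPH and DEM pair forces by their liquid
fraction (sub-scale solids rheology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgmd import BondTopology
from .core import NeighborList, ParticleSystem, Phase
from .sph import KernelSpec, kernel_grad_over_r


@dataclass
class ThermalLaw:
    """Thermal and phase-change constants for one scenario.

    ``e_sol``/``e_liq`` bound the latent plateau (set them equal to switch
    latent heat off; the plateau collapses).  ``bond_*`` describe the
    harmonic bonds created on solidification.  ``blend_T_range`` optionally
    defines a temperature interval over which SPH and DEM forces are mixed
    (fully solid at the lower end, fully liquid at the upper end).
    """

    kappa: float
    c_v_solid: float
    c_v_liquid: float
    T_star: float
    e_sol: float
    e_liq: float
    k_T: float = 0.0
    T_air: float = 0.0
    kappa_wall: float | None = None
    coordination_threshold: float = 5.5
    bond_search_radius: float = 0.0
    bond_k: float = 0.0
    bond_r0: float = 0.0
    bond_rmax: float = np.inf
    blend_T_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.c_v_solid <= 0 or self.c_v_liquid <= 0:
            raise ValueError("kappa >= 0 and heat capacities > 0 required")
        if self.e_sol > self.e_liq:
            raise ValueError("e_sol must not exceed e_liq")
        # continuity of the caloric EOS at the solidus
        if abs(self.e_sol - self.c_v_solid * self.T_star) > 1e-9 * max(
            1.0, abs(self.e_sol)
        ):
            raise ValueError(
                "caloric EOS discontinuous at the solidus: need e_sol = c_vS * T*"
            )

    def kappa_of(self, system: ParticleSystem) -> np.ndarray:
        kap = np.full(system.n, self.kappa)
        if self.kappa_wall is not None:
            kap[system.phase == int(Phase.WALL)] = self.kappa_wall
        return kap


def energy_to_temperature(
    e: np.ndarray | float, law: ThermalLaw
) -> tuple[np.ndarray, np.ndarray]:
    """Temperature (deg C) and liquid fraction from internal energy.

    Continuous and monotone non-decreasing in e; exactly invertible off the
    plateau.  With a collapsed plateau (e_sol = e_liq) the liquid fraction is
    a step at the transition energy.
    """
    e = np.asarray(e, dtype=float)
    T = np.empty_like(e)
    lam = np.empty_like(e)
    below = e < law.e_sol
    above = e > law.e_liq
    mid = ~(below | above)
    T[below] = e[below] / law.c_v_solid
    T[mid] = law.T_star
    T[above] = (e[above] - law.e_liq) / law.c_v_liquid + law.T_star
    lam[below] = 0.0
    lam[above] = 1.0
    width = law.e_liq - law.e_sol
    if width > 0.0:
        lam[mid] = (e[mid] - law.e_sol) / width
    else:
        lam[mid] = 1.0
    return T, lam


def temperature_to_energy(
    T: np.ndarray | float, law: ThermalLaw, liquid_fraction: float = 1.0
) -> np.ndarray:
    """Inverse caloric EOS; on the plateau (T = T*) the liquid fraction
    selects the point inside [e_sol, e_liq]."""
    T = np.asarray(T, dtype=float)
    e = np.where(
        T < law.T_star,
        T * law.c_v_solid,
        law.e_liq + (T - law.T_star) * law.c_v_liquid,
    )
    on_star = T == law.T_star
    e = np.where(on_star, law.e_sol + liquid_fraction * (law.e_liq - law.e_sol), e)
    return e


def local_heat_capacity(e: np.ndarray, law: ThermalLaw) -> np.ndarray:
    """Slope de/dT of the caloric EOS branch at e; on the plateau the liquid
    capacity is used so surface cooling keeps draining latent heat there."""
    return np.where(e < law.e_sol, law.c_v_solid, law.c_v_liquid)


def heat_conduction_rhs(
    system: ParticleSystem,
    pairs: NeighborList,
    spec: KernelSpec,
    kappa: np.ndarray,
) -> np.ndarray:
    """de_i/dt (J/kg/s) from the SPH conduction sum.

    de_i/dt = sum_j m_j (kappa_i + kappa_j)(T_i - T_j) F_ij / (rho_i rho_j)
    with F_ij = W'(r)/r <= 0: heat flows from hot to cold and the pair
    exchange conserves total thermal energy sum(m_i e_i) exactly.
    """
    out = np.zeros(system.n)
    if pairs.n_pairs == 0:
        return out
    i, j = pairs.i, pairs.j
    fij = kernel_grad_over_r(pairs.dist, spec)
    flux = (
        (kappa[i] + kappa[j])
        * (system.temperature[i] - system.temperature[j])
        * fij
        / (system.density[i] * system.density[j])
    )
    np.add.at(out, i, system.mass[j] * flux)
    np.add.at(out, j, -system.mass[i] * flux)
    return out


def surface_cooling_rhs(
    system: ParticleSystem,
    coordination: np.ndarray,
    law: ThermalLaw,
) -> np.ndarray:
    """Newton cooling de/dt for free-surface particles.

    dT/dt = -k_T (T - T_air) converted through the local EOS slope; interior
    particles (coordination >= threshold) and walls are untouched.
    """
    if law.k_T == 0.0:
        return np.zeros(system.n)
    surface = (coordination < law.coordination_threshold) & (
        system.phase != int(Phase.WALL)
    )
    c_loc = local_heat_capacity(system.internal_energy, law)
    de = np.where(
        surface, -law.k_T * (system.temperature - law.T_air) * c_loc, 0.0
    )
    return de


def update_phases_from_energy(system: ParticleSystem, law: ThermalLaw) -> None:
    """Label FLUID particles on the latent plateau as TRANSITION and back.

    The hard solid/fluid switches live in :func:`solidify` and :func:`melt`;
    this only maintains the intermediate label used for blending and
    observables.  Walls are never touched.
    """
    e = system.internal_energy
    fluidish = np.isin(system.phase, (int(Phase.FLUID), int(Phase.TRANSITION)))
    on_plateau = (e >= law.e_sol) & (e <= law.e_liq) & (law.e_liq > law.e_sol)
    system.phase[fluidish & on_plateau] = int(Phase.TRANSITION)
    system.phase[fluidish & (e > law.e_liq)] = int(Phase.FLUID)


def solidify(
    system: ParticleSystem,
    nlist: NeighborList,
    topology: BondTopology,
    law: ThermalLaw,
    next_body_id: int,
) -> tuple[BondTopology, list[tuple[int, int]], int]:
    """Freeze every SPH-carried particle whose energy dropped below e_sol.

    Each newly solid particle bonds (harmonic, law.bond_k / bond_r0) to every
    already-solid particle within the bond search radius; pairs of particles
    solidifying in the same step bond to each other as well, which makes the
    outcome independent of processing order.  A particle that solidified
    earlier never initiates new bonds.  Returns the new topology, the list of
    bonds formed and the next free body id.
    """
    e = system.internal_energy
    sph_carried = np.isin(system.phase, (int(Phase.FLUID), int(Phase.TRANSITION)))
    cohort = np.nonzero(sph_carried & (e < law.e_sol))[0]
    if cohort.size == 0:
        return topology, [], next_body_id
    already_solid = system.phase == int(Phase.SOLID)
    system.phase[cohort] = int(Phase.SOLID)
    for p in cohort:
        system.body_id[p] = next_body_id
        next_body_id += 1

    cohort_set = set(int(p) for p in cohort)
    # tiny tolerance so exact-lattice separations are not lost to rounding
    in_range = nlist.dist <= law.bond_search_radius * (1.0 + 1e-9)
    new_bonds: list[tuple[int, int]] = []
    for i, j in zip(nlist.i[in_range], nlist.j[in_range]):
        i, j = int(i), int(j)
        i_new, j_new = i in cohort_set, j in cohort_set
        if not (i_new or j_new):
            continue
        if (i_new and (already_solid[j] or j_new)) or (j_new and already_solid[i]):
            new_bonds.append((min(i, j), max(i, j)))
    if new_bonds:
        topology = topology.copy()
        topology.add_bonds(
            np.array(sorted(set(new_bonds)), dtype=np.int64),
            law.bond_k,
            law.bond_r0,
            law.bond_rmax,
        )
    return topology, sorted(set(new_bonds)), next_body_id


def melt(
    system: ParticleSystem, topology: BondTopology, law: ThermalLaw
) -> tuple[BondTopology, list[int]]:
    """Re-melt every SOLID particle whose energy rose above e_liq.

    The particle is relabelled FLUID, every bond referencing it is deleted
    and it re-enters the SPH family.
    """
    molten = np.nonzero(
        (system.phase == int(Phase.SOLID)) & (system.internal_energy > law.e_liq)
    )[0]
    if molten.size == 0:
        return topology, []
    system.phase[molten] = int(Phase.FLUID)
    system.body_id[molten] = -1
    topology = topology.copy()
    topology.remove_particles_bonds(molten)
    return topology, [int(p) for p in molten]


def blend_weights(
    system: ParticleSystem, law: ThermalLaw
) -> np.ndarray:
    """Per-particle liquid fraction lambda used to mix SPH and DEM forces.

    A pair force becomes lambda_pair * F_SPH + (1 - lambda_pair) * F_DEM with
    lambda_pair the mean of the two particles' fractions.  With
    ``blend_T_range`` set, lambda ramps linearly in temperature over that
    interval (glass-transition style, no latent plateau); otherwise it is the
    caloric-EOS liquid fraction.
    """
    if law.blend_T_range is not None:
        lo, hi = law.blend_T_range
        lam = np.clip((system.temperature - lo) / (hi - lo), 0.0, 1.0)
    else:
        _, lam = energy_to_temperature(system.internal_energy, law)
    lam = np.where(system.phase == int(Phase.SOLID), 0.0, lam)
    lam = np.where(system.phase == int(Phase.FLUID), np.maximum(lam, 0.0), lam)
    lam = np.where(system.phase == int(Phase.WALL), 1.0, lam)
    return lam


def check_phase_topology_consistency(
    system: ParticleSystem, topology: BondTopology
) -> None:
    """No FLUID particle may appear in any bond (asserted after every
    solidify/melt pass)."""
    if topology.n_bonds == 0:
        return
    bonded = np.unique(topology.bonds)
    fluid = bonded[system.phase[bonded] == int(Phase.FLUID)]
    if fluid.size:
        raise AssertionError(
            f"fluid particle {int(fluid[0])} still referenced by a bond"
        )
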