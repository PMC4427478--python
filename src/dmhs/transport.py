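"""Solute (water) transport, swelling, adhesion decay and Stokes drag.

Water mass w (kg) is carried per particle and diffuses down the
concentration gradient through the same SPH pair structure as heat:

    dw_i/dt = m_i sum_j m_j (D_i + D_j)(c_i - c_j) F_ij / (rho_i rho_j)

with the closure c_i = w_i rho_i / m_i (clamped to [0, 1]).  Bulk-water
particles act as a non-depleting reservoir at c = 1 (the injected mass is
logged).  Soil particles swell - their 2D volume (area) grows in proportion
to the absorbed water - and their van der Waals adhesion decays linearly
with concentration, vanishing at the release threshold, after which the
shear flow washes them away.

The quiescent-fluid mode replaces the SPH fluid entirely by classical
Stokes drag F = -6 pi mu r v on every bead (pin-array cell sorter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeighborList, ParticleSystem, Phase
from .sph import KernelSpec, kernel_grad_over_r


@dataclass
class DiffusionLaw:
    """Transport and adhesion constants for the cleaning problem.

    ``D`` is the water diffusivity (m^2/s), ``c_release`` the concentration
    at which adhesion is fully lost, ``eps_pair``/``eps_surface`` the dry
    Lennard-Jones well depths for soil-soil and soil-surface contacts, and
    ``swelling_gain`` the area added per unit absorbed water (m^2/kg).
    """

    D: float
    c_release: float = 0.5
    eps_pair: float = 0.0
    eps_surface: float = 0.0
    sigma_adh: float = 0.0
    r_c_adh: float | None = None
    swelling_gain: float = 0.0
    reservoir_fluid: bool = True

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusivity must be non-negative")
        if not 0.0 < self.c_release <= 1.0:
            raise ValueError("release threshold must lie in (0, 1]")
        if self.r_c_adh is None and self.sigma_adh > 0.0:
            self.r_c_adh = 2.5 * self.sigma_adh


def mass_diffusion_rhs(
    system: ParticleSystem,
    pairs: NeighborList,
    spec: KernelSpec,
    D: np.ndarray,
) -> np.ndarray:
    """dw_i/dt (kg/s); the pair exchange is antisymmetric, so total water is
    conserved in closed systems (reservoir handling happens in the caller)."""
    out = np.zeros(system.n)
    if pairs.n_pairs == 0:
        return out
    i, j = pairs.i, pairs.j
    fij = kernel_grad_over_r(pairs.dist, spec)
    flux = (
        (D[i] + D[j])
        * (system.concentration[i] - system.concentration[j])
        * fij
        / (system.density[i] * system.density[j])
    )
    np.add.at(out, i, system.mass[i] * system.mass[j] * flux)
    np.add.at(out, j, -system.mass[i] * system.mass[j] * flux)
    return out


def update_concentration(
    system: ParticleSystem, reservoir: np.ndarray | None = None
) -> None:
    """Closure c = w rho / m, clamped to [0, 1]; reservoir particles stay at 1."""
    c = system.water_mass * system.density / system.mass
    np.clip(c, 0.0, 1.0, out=c)
    if reservoir is not None:
        c[reservoir] = 1.0
        system.water_mass[reservoir] = system.mass[reservoir] / system.density[
            reservoir
        ]
    system.concentration[:] = c


def apply_swelling(
    system: ParticleSystem,
    mask: np.ndarray,
    dry_radius: np.ndarray,
    dry_mass: np.ndarray,
    law: DiffusionLaw,
) -> None:
    """Grow each soil particle's area in proportion to its absorbed water.

    area = dry area + gain * w; the radius follows (doubling the area scales
    the radius by sqrt(2)), the mass gains the water mass, and the density is
    recomputed from the new mass over the new area.
    """
    if law.swelling_gain <= 0.0 or not mask.any():
        return
    w = system.water_mass[mask]
    area = np.pi * dry_radius[mask] ** 2 + law.swelling_gain * w
    system.radius[mask] = np.sqrt(area / np.pi)
    system.mass[mask] = dry_mass[mask] + w
    system.density[mask] = system.mass[mask] / area


def scale_adhesion(
    c_pair: np.ndarray, epsilon: np.ndarray | float, law: DiffusionLaw
) -> np.ndarray:
    """Linear adhesion decay: eps_eff = eps * max(0, 1 - c_pair/c_release).

    ``c_pair`` is the mean concentration of the two particles; at the release
    threshold the attractive well vanishes entirely.
    """
    return epsilon * np.maximum(0.0, 1.0 - np.asarray(c_pair) / law.c_release)


def stokes_drag(system: ParticleSystem, mu: float) -> None:
    """Quiescent-fluid water resistance F = -6 pi mu r v per bead.

    Opposes motion, vanishes at rest and recovers ballistic motion at mu = 0.
    """
    if mu == 0.0:
        return
    mob = system.mobile
    system.force[mob] -= (
        6.0 * np.pi * mu * system.radius[mob, None] * system.velocity[mob]
    )
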