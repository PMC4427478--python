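"""Weakly-compressible SPH: kernel, continuity, Tait closure, momentum forces.

The fluid is discretized on moving particles; every field is approximated by
kernel-weighted sums over neighbors,

    f(r_i) ~= sum_j (m_j / rho_j) f(r_j) W(|r_i - r_j|, h).

Density evolves through the SPH continuity equation, pressure follows from
the stiff Tait equation of state (weak compressibility: density deviations
stay ~1% when the numerical sound speed exceeds ten times the flow speed),
and the momentum equation combines the symmetrized pressure gradient with
either Monaghan's artificial viscosity (inertial regimes) or Morris'
physical-viscosity pair term (creeping regimes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeighborList, ParticleSystem


@dataclass(frozen=True)
class KernelSpec:
    """Cubic-spline smoothing kernel in 2D, support radius 2h.

    W(q) = sigma * (1 - 1.5 q^2 + 0.75 q^3)        0 <= q <= 1
         = sigma * 0.25 (2 - q)^3                  1 <  q <= 2
    with q = r/h and sigma = 10 / (7 pi h^2) so that the kernel integrates
    to one over the plane.
    """

    h: float
    family: str = "cubic-spline"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("smoothing length h must be positive")

    @property
    def support(self) -> float:
        return 2.0 * self.h

    @property
    def sigma(self) -> float:
        return 10.0 / (7.0 * np.pi * self.h**2)


@dataclass
class FluidLaw:
    """Per-species fluid constants.

    ``c0`` is the numerical sound speed of the Tait closure; ``viscosity``
    selects the pair term: "monaghan" (artificial viscosity, alpha mapped
    from the physical viscosity via alpha = 8 nu / (h c0) in 2D) or "morris"
    (the physical-viscosity inter-particle form, preferred at Re < 1).
    """

    rho0: float
    c0: float
    mu: float
    viscosity: str = "morris"

    def __post_init__(self) -> None:
        if min(self.rho0, self.c0, self.mu) <= 0:
            raise ValueError("rho0, c0 and mu must be positive")
        if self.viscosity not in ("monaghan", "morris"):
            raise ValueError(f"unknown viscosity formulation {self.viscosity!r}")

    def monaghan_alpha(self, h: float) -> float:
        # mapped from the physical viscosity (2D relation), floored at the
        # customary minimum that keeps acoustic modes damped near the CFL
        # limit — the artificial viscosity's stabilising role
        return max(8.0 * (self.mu / self.rho0) / (h * self.c0), 0.02)


def kernel_value(r: np.ndarray | float, spec: KernelSpec) -> np.ndarray:
    q = np.asarray(r, dtype=float) / spec.h
    w = np.zeros_like(q)
    inner = q <= 1.0
    outer = (q > 1.0) & (q < 2.0)
    w[inner] = 1.0 - 1.5 * q[inner] ** 2 + 0.75 * q[inner] ** 3
    w[outer] = 0.25 * (2.0 - q[outer]) ** 3
    return spec.sigma * w


def kernel_grad_over_r(r: np.ndarray | float, spec: KernelSpec) -> np.ndarray:
    """F(r) = W'(r)/r (<= 0), finite at r -> 0.

    The kernel gradient is grad_i W_ij = F(r) * (r_i - r_j); writing it this
    way avoids a 0/0 at coincident points and makes the pair antisymmetry
    explicit.
    """
    q = np.asarray(r, dtype=float) / spec.h
    f = np.zeros_like(q)
    inner = q <= 1.0
    outer = (q > 1.0) & (q < 2.0)
    f[inner] = -3.0 + 2.25 * q[inner]
    qo = q[outer]
    f[outer] = -0.75 * (2.0 - qo) ** 2 / qo
    return spec.sigma * f / spec.h**2


def tait_pressure(rho: np.ndarray | float, law: FluidLaw) -> np.ndarray:
    """Stiff water-like equation of state, P(rho0) = 0.

    P = (c0^2 rho0 / 7) [ (rho/rho0)^7 - 1 ].  Negative pressure (tension)
    is permitted; no clipping is applied.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive in the equation of state")
    b = law.c0**2 * law.rho0 / 7.0
    return b * ((rho / law.rho0) ** 7 - 1.0)


def continuity_rhs(
    system: ParticleSystem, pairs: NeighborList, spec: KernelSpec
) -> np.ndarray:
    """d(rho_i)/dt = sum_j m_j (v_i - v_j) . grad_i W_ij for the given pairs.

    Compression (converging relative velocity) raises density.  Returns a
    full-length array; only particles appearing in ``pairs`` receive
    contributions.
    """
    out = np.zeros(system.n)
    if pairs.n_pairs == 0:
        return out
    i, j = pairs.i, pairs.j
    fij = kernel_grad_over_r(pairs.dist, spec)
    vij = system.velocity[i] - system.velocity[j]
    vdotr = (vij * pairs.rij).sum(axis=1)
    term = fij * vdotr
    np.add.at(out, i, system.mass[j] * term)
    np.add.at(out, j, system.mass[i] * term)
    return out


def summation_density(
    system: ParticleSystem, pairs: NeighborList, spec: KernelSpec, mask: np.ndarray
) -> np.ndarray:
    """Direct kernel-sum density (optional reinitialization), self term included."""
    rho = system.mass * kernel_value(0.0, spec)
    w = kernel_value(pairs.dist, spec)
    np.add.at(rho, pairs.i, system.mass[pairs.j] * w)
    np.add.at(rho, pairs.j, system.mass[pairs.i] * w)
    return np.where(mask, rho, system.density)


def sph_momentum_forces(
    system: ParticleSystem,
    pairs: NeighborList,
    spec: KernelSpec,
    law: FluidLaw,
    weight: np.ndarray | float = 1.0,
) -> None:
    """Symmetrized pressure-gradient force plus the selected viscous term.

    F_i += -m_i sum_j m_j (P_i/rho_i^2 + P_j/rho_j^2 + Pi_ij) grad_i W_ij
    with Pi_ij the Monaghan artificial-viscosity tensor when selected; the
    Morris physical-viscosity term is accumulated separately (it is not a
    scalar times the kernel gradient).  ``weight`` scales the pair force
    (used by the SPH<->DEM blending of partially solidified material).
    """
    if pairs.n_pairs == 0:
        return
    i, j = pairs.i, pairs.j
    rho_i, rho_j = system.density[i], system.density[j]
    if np.any(rho_i <= 0) or np.any(rho_j <= 0):
        raise ValueError("zero or negative density in an SPH pair")
    fij = kernel_grad_over_r(pairs.dist, spec)
    bracket = system.pressure[i] / rho_i**2 + system.pressure[j] / rho_j**2

    if law.viscosity == "monaghan":
        vij = system.velocity[i] - system.velocity[j]
        vdotr = (vij * pairs.rij).sum(axis=1)
        approaching = vdotr < 0.0
        mu_ij = spec.h * vdotr / (pairs.dist**2 + 0.01 * spec.h**2)
        alpha = law.monaghan_alpha(spec.h)
        pi_ij = np.where(
            approaching, -alpha * law.c0 * mu_ij / (0.5 * (rho_i + rho_j)), 0.0
        )
        bracket = bracket + pi_ij

    scale = weight if np.isscalar(weight) else weight
    fpair = (
        -(system.mass[i] * system.mass[j] * bracket * fij * scale)[:, None]
        * pairs.rij
    )
    np.add.at(system.force, i, fpair)
    np.add.at(system.force, j, -fpair)

    if law.viscosity == "morris":
        morris_viscous_forces(system, pairs, spec, law.mu, weight=weight)


def morris_viscous_forces(
    system: ParticleSystem,
    pairs: NeighborList,
    spec: KernelSpec,
    mu: np.ndarray | float,
    weight: np.ndarray | float = 1.0,
) -> None:
    """Morris et al. physical-viscosity pair term.

    F_i += m_i sum_j m_j (mu_i + mu_j) (r_ij . grad_i W_ij) /
           (rho_i rho_j (r_ij^2 + 0.01 h^2)) * (v_i - v_j)

    which damps relative motion while conserving momentum exactly.  ``mu``
    may be per-particle (used for the no-slip coupling where solid-surface
    particles carry the fluid viscosity).
    """
    if pairs.n_pairs == 0:
        return
    i, j = pairs.i, pairs.j
    if np.isscalar(mu):
        mu_sum = 2.0 * float(mu)
    else:
        mu_sum = mu[i] + mu[j]
    fij = kernel_grad_over_r(pairs.dist, spec)
    rdotgrad = fij * pairs.dist**2
    coeff = (
        system.mass[i]
        * system.mass[j]
        * mu_sum
        * rdotgrad
        / (system.density[i] * system.density[j] * (pairs.dist**2 + 0.01 * spec.h**2))
    )
    coeff = coeff * weight
    vij = system.velocity[i] - system.velocity[j]
    fpair = coeff[:, None] * vij
    np.add.at(system.force, i, fpair)
    np.add.at(system.force, j, -fpair)
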