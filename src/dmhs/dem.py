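"""Inter-body granular contacts and the solid-liquid interface coupling.

Normal contact is a linear spring-dashpot acting on the overlap
delta = (R_i + R_j) - |r_ij|:

    f_n = k_n delta + m_eff gamma_n v_n ,   m_eff = m_i m_j / (m_i + m_j)

with v_n the normal approach rate, clamped to f_n >= 0 so the dashpot never
produces adhesion at separation.  The tangential force is a history spring
on the accumulated tangential displacement xi, limited by the Coulomb cone:
below |f_t| <= mu_s f_n the contact sticks, above it slides with mu_d f_n
and xi is rescaled to the sliding value.

The solid-liquid interface carries a truncated, purely repulsive
Lennard-Jones force (no-penetration); no-slip is realized by letting
solid-surface particles take part in the fluid's viscous pair sums with the
solid's local velocity (dummy-particle treatment, validated against the
analytic Couette profile).  The cleaning scenario uses the full attractive
Lennard-Jones well with a concentration-scaled depth for van der Waals
adhesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import NeighborList, ParticleSystem

LJ_MIN_R_FACTOR = 0.5  # below 0.5 sigma the force is capped (over-penetration)


@dataclass
class ContactLaw:
    """Linear spring-dashpot constants and friction coefficients."""

    k_n: float
    gamma_n: float = 0.0
    k_t: float = 0.0
    gamma_t: float = 0.0
    mu_s: float = 0.0
    mu_d: float | None = None

    def __post_init__(self) -> None:
        if self.k_n <= 0:
            raise ValueError("k_n must be positive")
        if self.gamma_n < 0 or self.gamma_t < 0:
            raise ValueError("damping coefficients must be non-negative")
        if self.mu_d is None:
            self.mu_d = self.mu_s
        if self.mu_d < 0.0 or self.mu_d > self.mu_s + 1e-15:
            raise ValueError("need 0 <= mu_d <= mu_s")


@dataclass
class CouplingLaw:
    """Truncated Lennard-Jones no-penetration coupling at the interface.

    r_c defaults to the potential minimum 2^(1/6) sigma, keeping only the
    repulsive branch.  ``no_slip`` additionally couples fluid and solid
    through the viscous pair term.
    """

    epsilon: float
    sigma: float
    r_c: float | None = None
    no_slip: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.r_c is None:
            self.r_c = 2.0 ** (1.0 / 6.0) * self.sigma
        if self.r_c > 2.0 ** (1.0 / 6.0) * self.sigma * (1.0 + 1e-12):
            raise ValueError("r_c beyond the potential minimum is attractive")


class ContactLedger:
    """Per-pair contact history: accumulated tangential displacement and age.

    An entry exists iff the pair currently overlaps; xi is re-projected onto
    the contact tangent each step and reset when a contact begins.
    """

    def __init__(self) -> None:
        self._xi: dict[tuple[int, int], np.ndarray] = {}
        self._age: dict[tuple[int, int], int] = {}

    def __len__(self) -> int:
        return len(self._xi)

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._xi

    def xi(self, key: tuple[int, int]) -> np.ndarray:
        return self._xi[key]

    def age(self, key: tuple[int, int]) -> int:
        return self._age[key]

    def open(self, key: tuple[int, int]) -> np.ndarray:
        if key not in self._xi:
            self._xi[key] = np.zeros(2)
            self._age[key] = 0
        return self._xi[key]

    def store(self, key: tuple[int, int], xi: np.ndarray) -> None:
        self._xi[key] = xi
        self._age[key] = self._age.get(key, 0) + 1

    def sync(self, active: set[tuple[int, int]]) -> None:
        """Close every entry whose contact has ended."""
        for key in list(self._xi):
            if key not in active:
                del self._xi[key]
                del self._age[key]

    def keys(self):
        return self._xi.keys()


def lj_force_magnitude(
    r: np.ndarray, epsilon: float | np.ndarray, sigma: float, r_c: float
) -> np.ndarray:
    """-dU/dr of 4 eps [(sigma/r)^12 - (sigma/r)^6], zero beyond r_c.

    Positive values push the pair apart.  Inside 0.5 sigma the magnitude is
    capped at its 0.5 sigma value with a warning: such an over-penetration
    signals a too-large time step.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ force undefined at zero separation")
    too_close = r < LJ_MIN_R_FACTOR * sigma
    if too_close.any():
        warnings.warn(
            "LJ over-penetration: capping repulsive force (time step too large?)",
            RuntimeWarning,
            stacklevel=2,
        )
    r_eff = np.maximum(r, LJ_MIN_R_FACTOR * sigma)
    s6 = (sigma / r_eff) ** 6
    f = 24.0 * epsilon / r_eff * (2.0 * s6**2 - s6)
    return np.where(r < r_c, f, 0.0)


def lj_coupling_forces(
    system: ParticleSystem, pairs: NeighborList, law: CouplingLaw
) -> None:
    """Repulsive-branch LJ between solid and fluid particles (no-penetration)."""
    if pairs.n_pairs == 0:
        return
    close = pairs.dist < law.r_c
    if not close.any():
        return
    sub = pairs.subset(close)
    fmag = lj_force_magnitude(sub.dist, law.epsilon, law.sigma, law.r_c)
    fvec = (fmag / sub.dist)[:, None] * sub.rij
    np.add.at(system.force, sub.i, fvec)
    np.add.at(system.force, sub.j, -fvec)


def adhesive_lj_forces(
    system: ParticleSystem,
    pairs: NeighborList,
    epsilon_eff: np.ndarray | float,
    sigma: float,
    r_c: float,
    epsilon_core: np.ndarray | float | None = None,
) -> None:
    """Full LJ with a concentration-scaled attractive well, cut at r_c.

    Models van der Waals adhesion between soil particles and between soil and
    the cleaned surface.  Only the r^-6 attraction carries the (decaying)
    well depth ``epsilon_eff``; the r^-12 core keeps the dry depth
    ``epsilon_core`` so that fully wetted particles remain excluded-volume
    bodies ("only repulsive contact remains") while their adhesion vanishes.
    """
    if pairs.n_pairs == 0:
        return
    if epsilon_core is None:
        epsilon_core = epsilon_eff
    close = pairs.dist < r_c
    if not close.any():
        return
    sub = pairs.subset(close)
    eps_att = np.broadcast_to(np.asarray(epsilon_eff, dtype=float), pairs.dist.shape)[
        close
    ]
    eps_core = np.broadcast_to(
        np.asarray(epsilon_core, dtype=float), pairs.dist.shape
    )[close]
    r = np.maximum(sub.dist, LJ_MIN_R_FACTOR * sigma)
    s6 = (sigma / r) ** 6
    fmag = 24.0 / r * (2.0 * eps_core * s6**2 - eps_att * s6)
    fvec = (fmag / sub.dist)[:, None] * sub.rij
    np.add.at(system.force, sub.i, fvec)
    np.add.at(system.force, sub.j, -fvec)


def dem_normal_force(
    delta: float, v_n: float, m_eff: float, law: ContactLaw
) -> float:
    """Spring-dashpot normal force magnitude, clamped to be non-adhesive.

    ``v_n`` is the normal approach rate (positive while the particles move
    toward each other), so the dashpot always dissipates.
    """
    if delta < 0:
        return 0.0
    return max(law.k_n * delta + m_eff * law.gamma_n * v_n, 0.0)


def dem_contact_forces(
    system: ParticleSystem,
    pairs: NeighborList,
    law: ContactLaw,
    ledger: ContactLedger,
    dt: float,
    weight: np.ndarray | float = 1.0,
) -> None:
    """Normal + history-dependent tangential forces for every overlapping pair.

    ``pairs`` must already be restricted to DEM-eligible pairs (different
    bodies, not bonded).  The ledger is updated in place: entries open when a
    contact begins and close when it ends; after every update the applied
    tangential force satisfies |f_t| <= mu_s f_n (Coulomb cone).
    """
    active: set[tuple[int, int]] = set()
    if pairs.n_pairs:
        overlap = system.radius[pairs.i] + system.radius[pairs.j] - pairs.dist
        touching = np.nonzero(overlap > 0.0)[0]
        w_arr = None if np.isscalar(weight) else np.asarray(weight)
        for idx in touching:
            i = int(pairs.i[idx])
            j = int(pairs.j[idx])
            key = (i, j)
            active.add(key)
            d = pairs.dist[idx]
            if d == 0.0:
                raise ValueError(f"coincident DEM particles {i}, {j}")
            nhat = pairs.rij[idx] / d
            m_eff = system.mass[i] * system.mass[j] / (system.mass[i] + system.mass[j])
            vrel = system.velocity[i] - system.velocity[j]
            v_n = -float(vrel @ nhat)  # approach rate
            f_n = dem_normal_force(float(overlap[idx]), v_n, m_eff, law)

            f_t_vec = np.zeros(2)
            if law.k_t > 0.0 or law.gamma_t > 0.0:
                xi = ledger.open(key)
                v_t_vec = vrel - (vrel @ nhat) * nhat
                xi = xi - (xi @ nhat) * nhat  # re-project onto tangent plane
                xi = xi + v_t_vec * dt
                cand = -law.k_t * xi - m_eff * law.gamma_t * v_t_vec
                cmag = float(np.hypot(cand[0], cand[1]))
                if cmag <= law.mu_s * f_n or cmag == 0.0:
                    f_t_vec = cand  # static branch (stick)
                else:
                    uhat = cand / cmag
                    f_t_vec = law.mu_d * f_n * uhat  # dynamic branch (slip)
                    if law.k_t > 0.0:
                        xi = -(law.mu_d * f_n / law.k_t) * uhat
                ledger.store(key, xi)

            w = 1.0 if w_arr is None else float(w_arr[idx])
            f = (f_n * nhat + f_t_vec) * w
            system.force[i] += f
            system.force[j] -= f
    ledger.sync(active)
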