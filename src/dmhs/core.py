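"""Shared chassis of the simulator.

Every physics family (SPH fluid forces, bead-spring solid forces, DEM
contacts, heat and mass transfer) acts on one common set of computational
particles.  This module owns that state, the neighbor search that feeds the
compact-support pair interactions, the domain boundaries, and the
velocity-Verlet time integration of Newton's equations of motion

    m_i dv_i/dt = sum_j F_ij + F_ext .

Everything is 2D: positions, velocities and forces are (N, 2) arrays.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class Phase(enum.IntEnum):
    """Physical state of a computational particle.

    FLUID particles belong to the SPH family, SOLID particles to the
    DEM/bead-spring families, TRANSITION particles are partially solidified
    material carried by SPH until full solidification, and WALL particles are
    frozen boundary particles (their velocity is prescribed, never
    integrated).
    """

    FLUID = 0
    SOLID = 1
    TRANSITION = 2
    WALL = 3


class SimulationBlowUp(RuntimeError):
    """Raised when any particle state becomes non-finite."""


_VECTOR_FIELDS = ("position", "velocity", "force")
_SCALAR_FIELDS = (
    "mass",
    "density",
    "pressure",
    "internal_energy",
    "temperature",
    "water_mass",
    "concentration",
    "radius",
)
_INT_FIELDS = ("phase", "body_id")


@dataclass
class ParticleSystem:
    """Flat per-particle state shared by every force family.

    Units are SI throughout; temperature is in degrees Celsius (only
    temperature differences enter the equations).  ``body_id`` is -1 for bulk
    fluid and a shared non-negative integer for the elemental particles of one
    dispersed body or wall.
    """

    position: np.ndarray
    velocity: np.ndarray
    mass: np.ndarray
    density: np.ndarray
    pressure: np.ndarray
    internal_energy: np.ndarray
    temperature: np.ndarray
    water_mass: np.ndarray
    concentration: np.ndarray
    phase: np.ndarray
    body_id: np.ndarray
    radius: np.ndarray
    force: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "ParticleSystem":
        return cls(
            position=np.zeros((n, 2)),
            velocity=np.zeros((n, 2)),
            mass=np.ones(n),
            density=np.ones(n),
            pressure=np.zeros(n),
            internal_energy=np.zeros(n),
            temperature=np.zeros(n),
            water_mass=np.zeros(n),
            concentration=np.zeros(n),
            phase=np.full(n, int(Phase.FLUID), dtype=np.int64),
            body_id=np.full(n, -1, dtype=np.int64),
            radius=np.zeros(n),
            force=np.zeros((n, 2)),
        )

    @property
    def n(self) -> int:
        return self.position.shape[0]

    @property
    def mobile(self) -> np.ndarray:
        """Particles whose velocity is integrated (everything but walls)."""
        return self.phase != int(Phase.WALL)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            **{
                name: getattr(self, name).copy()
                for name in _VECTOR_FIELDS + _SCALAR_FIELDS + _INT_FIELDS
            }
        )

    @classmethod
    def concatenate(cls, blocks: list["ParticleSystem"]) -> "ParticleSystem":
        return cls(
            **{
                name: np.concatenate([getattr(b, name) for b in blocks])
                for name in _VECTOR_FIELDS + _SCALAR_FIELDS + _INT_FIELDS
            }
        )

    def validate(self) -> None:
        if np.any(self.mass <= 0):
            raise ValueError("particle mass must be positive")
        if np.any(self.density <= 0):
            raise ValueError("particle density must be positive")
        wall_or_solid = np.isin(
            self.phase, (int(Phase.WALL), int(Phase.SOLID))
        )
        if np.any(self.body_id[wall_or_solid] < 0):
            raise ValueError("WALL/SOLID particles need a non-negative body_id")
        self.check_finite()

    def check_finite(self, step: int | None = None) -> None:
        for name in _VECTOR_FIELDS + _SCALAR_FIELDS:
            arr = getattr(self, name)
            bad = ~np.isfinite(arr)
            if bad.any():
                idx = int(np.argwhere(bad)[0][0])
                where = f" at step {step}" if step is not None else ""
                raise SimulationBlowUp(
                    f"non-finite {name} for particle {idx}{where} (blow-up)"
                )


@dataclass
class BoundarySpec:
    """Domain bounds and per-axis boundary condition.

    ``periodic[k]`` selects a periodic axis (minimum-image convention); on
    non-periodic axes the boundary is realized by layers of frozen WALL
    particles, so nothing is done here beyond bookkeeping.
    """

    lo: np.ndarray
    hi: np.ndarray
    periodic: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise ValueError("domain bounds must satisfy hi > lo")

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    def wrap(self, system: ParticleSystem) -> None:
        """Wrap positions on periodic axes (walls included; a frozen wall
        never crosses a periodic boundary in practice)."""
        for k in range(2):
            if self.periodic[k]:
                span = self.hi[k] - self.lo[k]
                system.position[:, k] = (
                    np.mod(system.position[:, k] - self.lo[k], span) + self.lo[k]
                )


@dataclass
class NeighborList:
    """Symmetric pair list within one global cutoff.

    Each pair is stored once with i < j; ``rij = position[i] - position[j]``
    already honours the minimum-image convention on periodic axes.  Force
    families filter by their own interaction range via :meth:`subset`.
    """

    i: np.ndarray
    j: np.ndarray
    rij: np.ndarray
    dist: np.ndarray
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return self.i.shape[0]

    def subset(self, mask: np.ndarray) -> "NeighborList":
        return NeighborList(
            self.i[mask], self.j[mask], self.rij[mask], self.dist[mask], self.cutoff
        )


def build_neighbor_list(
    system: ParticleSystem,
    cutoff: float,
    boundary: BoundarySpec | None = None,
) -> NeighborList:
    """All pairs with separation <= cutoff, via a kd-tree.

    Periodic axes use the tree's box topology; mixed periodic/wall domains are
    handled by padding the non-periodic axis period beyond any reachable
    coordinate so that no spurious wrap can occur.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = system.position
    bad = ~np.isfinite(pos).all(axis=1)
    if bad.any():
        idx = int(np.argwhere(bad)[0][0])
        raise SimulationBlowUp(f"non-finite position for particle {idx}")

    if boundary is not None and any(boundary.periodic):
        period = np.empty(2)
        base = np.empty(2)
        for k in range(2):
            if boundary.periodic[k]:
                period[k] = boundary.extent[k]
                base[k] = boundary.lo[k]
            else:
                base[k] = pos[:, k].min() - 2.0 * cutoff
                period[k] = pos[:, k].max() - base[k] + 2.0 * cutoff
        shifted = np.mod(pos - base, period)
        tree = cKDTree(shifted, boxsize=period)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        i, j = pairs[:, 0], pairs[:, 1]
        rij = pos[i] - pos[j]
        for k in range(2):
            if boundary.periodic[k]:
                span = boundary.extent[k]
                rij[:, k] -= span * np.round(rij[:, k] / span)
    else:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        i, j = pairs[:, 0], pairs[:, 1]
        rij = pos[i] - pos[j]

    dist = np.sqrt((rij * rij).sum(axis=1))
    keep = dist <= cutoff
    return NeighborList(i[keep], j[keep], rij[keep], dist[keep], cutoff)


def brute_force_pairs(
    system: ParticleSystem,
    cutoff: float,
    boundary: BoundarySpec | None = None,
) -> set[tuple[int, int]]:
    """O(N^2) reference pair scan (oracle for the kd-tree search)."""
    pos = system.position
    n = pos.shape[0]
    out: set[tuple[int, int]] = set()
    for a in range(n):
        d = pos[a] - pos[a + 1 :]
        if boundary is not None:
            for k in range(2):
                if boundary.periodic[k]:
                    span = boundary.extent[k]
                    d[:, k] -= span * np.round(d[:, k] / span)
        r = np.sqrt((d * d).sum(axis=1))
        for off in np.nonzero(r <= cutoff)[0]:
            out.add((a, a + 1 + int(off)))
    return out


def coordination_numbers(
    nlist: NeighborList, n: int, rmax: float
) -> np.ndarray:
    """Neighbor count within rmax per particle (free-surface detection)."""
    mask = nlist.dist <= rmax
    counts = np.bincount(nlist.i[mask], minlength=n)
    counts += np.bincount(nlist.j[mask], minlength=n)
    return counts


# ----------------------------------------------------------------------------
# time integration (velocity Verlet)
# ----------------------------------------------------------------------------


def apply_external_forces(system: ParticleSystem, body_force: np.ndarray) -> None:
    """Volumetric, gravity-like forcing: force += m * f_g on mobile particles."""
    f = np.asarray(body_force, dtype=float)
    mob = system.mobile
    system.force[mob] += system.mass[mob, None] * f


def kick(system: ParticleSystem, dt: float) -> None:
    mob = system.mobile
    system.velocity[mob] += dt * system.force[mob] / system.mass[mob, None]


def drift(system: ParticleSystem, dt: float) -> None:
    # walls drift too, with their prescribed (never-kicked) velocity
    system.position += dt * system.velocity


def velocity_verlet_step(system: ParticleSystem, dt: float, evaluate) -> object:
    """One symplectic step.

    ``evaluate(system)`` must refill ``system.force`` for the current
    positions/velocities and may return auxiliary rate terms; ``system.force``
    is assumed current on entry (call ``evaluate`` once before the first
    step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    kick(system, 0.5 * dt)
    drift(system, dt)
    rates = evaluate(system)
    kick(system, 0.5 * dt)
    return rates
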