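"""Coarse-grained bead-spring solid mechanics.

A dispersed solid body (cell membrane, cube, solidified melt) is a set of
elemental particles tied together by harmonic potentials:

    U_bond     = k_b (r - r0)^2
    U_angle    = k_a (theta - theta0)^2
    U_dihedral = k_d (phi - phi0)^2

The analytic forces are the negative gradients of these potentials; bonds
whose length exceeds r_max break irreversibly (brittle fracture), taking any
hinge that references the broken pair with them.  Topology builders for
closed membranes (elastic + bending modulus only) and shear-braced
rectangular lattices are provided.

Bond and angle forces work in 2D or 3D; the dihedral angle degenerates in
the plane, so dihedral forces require 3D coordinates (unused by the shipped
2D scenarios but fully supported and tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SIN_FLOOR = 1e-10


@dataclass
class BondTopology:
    """Connectivity of the bead-spring solids.

    ``bonds`` is (nb, 2) int; per-bond stiffness k_b (J/m^2), rest length r0
    (m) and breaking length r_max (m; +inf for unbreakable).  ``angles`` is
    (na, 3) with the hinge vertex as the middle index; ``dihedrals`` is
    (nd, 4) in chain order 1-2-3-4.
    """

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_rmax: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 4), dtype=np.int64)
    )
    dihedral_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.dihedrals.shape[0]

    def validate(self) -> None:
        if self.n_bonds:
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise ValueError("bond joins a particle to itself")
            keys = bond_pair_keys(self.bonds)
            if len(np.unique(keys)) != self.n_bonds:
                raise ValueError("duplicate bond")
            if np.any(self.bond_rmax < self.bond_r0):
                raise ValueError("r_max must be >= r0 for breakable bonds")

    def copy(self) -> "BondTopology":
        return BondTopology(
            self.bonds.copy(), self.bond_k.copy(), self.bond_r0.copy(),
            self.bond_rmax.copy(), self.angles.copy(), self.angle_k.copy(),
            self.angle_theta0.copy(), self.dihedrals.copy(),
            self.dihedral_k.copy(), self.dihedral_phi0.copy(),
        )

    def add_bonds(
        self,
        pairs: np.ndarray,
        k: float | np.ndarray,
        r0: float | np.ndarray,
        rmax: float | np.ndarray = np.inf,
    ) -> None:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        m = pairs.shape[0]
        self.bonds = np.concatenate([self.bonds, pairs])
        self.bond_k = np.concatenate([self.bond_k, np.broadcast_to(k, m).astype(float)])
        self.bond_r0 = np.concatenate(
            [self.bond_r0, np.broadcast_to(r0, m).astype(float)]
        )
        self.bond_rmax = np.concatenate(
            [self.bond_rmax, np.broadcast_to(rmax, m).astype(float)]
        )

    def add_angles(
        self, triplets: np.ndarray, k: float | np.ndarray, theta0: float | np.ndarray
    ) -> None:
        triplets = np.atleast_2d(np.asarray(triplets, dtype=np.int64))
        m = triplets.shape[0]
        self.angles = np.concatenate([self.angles, triplets])
        self.angle_k = np.concatenate(
            [self.angle_k, np.broadcast_to(k, m).astype(float)]
        )
        self.angle_theta0 = np.concatenate(
            [self.angle_theta0, np.broadcast_to(theta0, m).astype(float)]
        )

    def remove_particles_bonds(self, particles: np.ndarray) -> int:
        """Delete every bond/angle/dihedral referencing any given particle."""
        particles = np.asarray(particles)
        removed = 0
        if self.n_bonds:
            keep = ~np.isin(self.bonds, particles).any(axis=1)
            removed += int((~keep).sum())
            self._filter_bonds(keep)
        if self.n_angles:
            keep = ~np.isin(self.angles, particles).any(axis=1)
            self._filter_angles(keep)
        if self.n_dihedrals:
            keep = ~np.isin(self.dihedrals, particles).any(axis=1)
            self._filter_dihedrals(keep)
        return removed

    def _filter_bonds(self, keep: np.ndarray) -> None:
        self.bonds = self.bonds[keep]
        self.bond_k = self.bond_k[keep]
        self.bond_r0 = self.bond_r0[keep]
        self.bond_rmax = self.bond_rmax[keep]

    def _filter_angles(self, keep: np.ndarray) -> None:
        self.angles = self.angles[keep]
        self.angle_k = self.angle_k[keep]
        self.angle_theta0 = self.angle_theta0[keep]

    def _filter_dihedrals(self, keep: np.ndarray) -> None:
        self.dihedrals = self.dihedrals[keep]
        self.dihedral_k = self.dihedral_k[keep]
        self.dihedral_phi0 = self.dihedral_phi0[keep]

    @classmethod
    def merge(cls, parts: list["BondTopology"], offsets: list[int]) -> "BondTopology":
        """Concatenate topologies whose particle indices shift by offsets."""
        out = cls()
        for topo, off in zip(parts, offsets):
            if topo.n_bonds:
                out.add_bonds(topo.bonds + off, topo.bond_k, topo.bond_r0, topo.bond_rmax)
            if topo.n_angles:
                out.add_angles(topo.angles + off, topo.angle_k, topo.angle_theta0)
            if topo.n_dihedrals:
                out.dihedrals = np.concatenate([out.dihedrals, topo.dihedrals + off])
                out.dihedral_k = np.concatenate([out.dihedral_k, topo.dihedral_k])
                out.dihedral_phi0 = np.concatenate(
                    [out.dihedral_phi0, topo.dihedral_phi0]
                )
        return out


def bond_pair_keys(pairs: np.ndarray, n: int | None = None) -> np.ndarray:
    """Canonical unordered-pair keys (for duplicate and bonded-pair checks)."""
    if pairs.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    a = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    b = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    width = np.int64(n if n is not None else max(int(b.max()) + 1, 1))
    return a * width + b


def bond_forces(
    positions: np.ndarray, topology: BondTopology, out: np.ndarray | None = None
) -> np.ndarray:
    """Restoring force 2 k_b (r - r0) along each bond axis, equal and opposite."""
    if out is None:
        out = np.zeros_like(positions)
    if topology.n_bonds == 0:
        return out
    i, j = topology.bonds[:, 0], topology.bonds[:, 1]
    d = positions[i] - positions[j]
    r = np.sqrt((d * d).sum(axis=1))
    if np.any(r == 0.0):
        k = int(np.nonzero(r == 0.0)[0][0])
        raise ValueError(
            f"coincident bonded particles {i[k]} and {j[k]}: force direction undefined"
        )
    fmag = -2.0 * topology.bond_k * (r - topology.bond_r0)
    fvec = (fmag / r)[:, None] * d
    np.add.at(out, i, fvec)
    np.add.at(out, j, -fvec)
    return out


def bond_energy(positions: np.ndarray, topology: BondTopology) -> float:
    if topology.n_bonds == 0:
        return 0.0
    d = positions[topology.bonds[:, 0]] - positions[topology.bonds[:, 1]]
    r = np.sqrt((d * d).sum(axis=1))
    return float(np.sum(topology.bond_k * (r - topology.bond_r0) ** 2))


def angle_forces(
    positions: np.ndarray, topology: BondTopology, out: np.ndarray | None = None
) -> np.ndarray:
    """Hinge forces -dU/dr for U = k_a (theta - theta0)^2.

    theta in [0, pi] is the angle at the middle particle.  The net force and
    net torque of each triplet vanish (the potential is invariant under rigid
    motions).  Exactly collinear hinges with theta0 != pi have an undefined
    bending direction; their contribution is dropped (measure-zero event).
    """
    if out is None:
        out = np.zeros_like(positions)
    if topology.n_angles == 0:
        return out
    ia, ij, ic = topology.angles.T
    u = positions[ia] - positions[ij]
    v = positions[ic] - positions[ij]
    lu = np.sqrt((u * u).sum(axis=1))
    lv = np.sqrt((v * v).sum(axis=1))
    if np.any(lu == 0.0) or np.any(lv == 0.0):
        raise ValueError("zero-length angle arm: theta undefined")
    uh = u / lu[:, None]
    vh = v / lv[:, None]
    cos_t = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    theta = np.arccos(cos_t)
    dudtheta = 2.0 * topology.angle_k * (theta - topology.angle_theta0)
    ok = sin_t > _SIN_FLOOR
    coeff = np.where(ok, -dudtheta / np.where(ok, sin_t, 1.0), 0.0)
    # dtheta/dr_a = (cos t * uh - vh) / (|u| sin t); F_a = -dU/dtheta * that
    fa = (coeff / lu)[:, None] * (cos_t[:, None] * uh - vh)
    fc = (coeff / lv)[:, None] * (cos_t[:, None] * vh - uh)
    np.add.at(out, ia, fa)
    np.add.at(out, ic, fc)
    np.add.at(out, ij, -(fa + fc))
    return out


def angle_energy(positions: np.ndarray, topology: BondTopology) -> float:
    if topology.n_angles == 0:
        return 0.0
    ia, ij, ic = topology.angles.T
    u = positions[ia] - positions[ij]
    v = positions[ic] - positions[ij]
    lu = np.sqrt((u * u).sum(axis=1))
    lv = np.sqrt((v * v).sum(axis=1))
    cos_t = np.clip((u * v).sum(axis=1) / (lu * lv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    return float(np.sum(topology.angle_k * (theta - topology.angle_theta0) ** 2))


def dihedral_forces(
    positions: np.ndarray, topology: BondTopology, out: np.ndarray | None = None
) -> np.ndarray:
    """Torsional forces for U = k_d (phi - phi0)^2 (3D coordinates required).

    phi is the signed angle between the planes (1,2,3) and (2,3,4).
    """
    if out is None:
        out = np.zeros_like(positions)
    if topology.n_dihedrals == 0:
        return out
    if positions.shape[1] != 3:
        raise ValueError("dihedral angles are undefined in 2D; supply 3D coordinates")
    i1, i2, i3, i4 = topology.dihedrals.T
    b1 = positions[i2] - positions[i1]
    b2 = positions[i3] - positions[i2]
    b3 = positions[i4] - positions[i3]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = (n1 * n1).sum(axis=1)
    n2sq = (n2 * n2).sum(axis=1)
    lb2 = np.sqrt((b2 * b2).sum(axis=1))
    if np.any(n1sq == 0.0) or np.any(n2sq == 0.0) or np.any(lb2 == 0.0):
        raise ValueError("degenerate dihedral: collinear backbone atoms")
    phi = np.arctan2((np.cross(n1, n2) * b2).sum(axis=1) / lb2, (n1 * n2).sum(axis=1))
    dudphi = 2.0 * topology.dihedral_k * (phi - topology.dihedral_phi0)
    g1 = -(lb2 / n1sq)[:, None] * n1
    g4 = (lb2 / n2sq)[:, None] * n2
    c12 = ((b1 * b2).sum(axis=1) / lb2**2)[:, None]
    c32 = ((b3 * b2).sum(axis=1) / lb2**2)[:, None]
    g2 = -(1.0 + c12) * g1 + c32 * g4
    g3 = c12 * g1 - (1.0 + c32) * g4
    s = -dudphi[:, None]
    np.add.at(out, i1, s * g1)
    np.add.at(out, i2, s * g2)
    np.add.at(out, i3, s * g3)
    np.add.at(out, i4, s * g4)
    return out


def dihedral_energy(positions: np.ndarray, topology: BondTopology) -> float:
    if topology.n_dihedrals == 0:
        return 0.0
    i1, i2, i3, i4 = topology.dihedrals.T
    b1 = positions[i2] - positions[i1]
    b2 = positions[i3] - positions[i2]
    b3 = positions[i4] - positions[i3]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.sqrt((b2 * b2).sum(axis=1))
    phi = np.arctan2((np.cross(n1, n2) * b2).sum(axis=1) / lb2, (n1 * n2).sum(axis=1))
    return float(np.sum(topology.dihedral_k * (phi - topology.dihedral_phi0) ** 2))


def total_energy(positions: np.ndarray, topology: BondTopology) -> float:
    e = bond_energy(positions, topology) + angle_energy(positions, topology)
    if topology.n_dihedrals:
        e += dihedral_energy(positions, topology)
    return e


def cgmd_forces(
    positions: np.ndarray, topology: BondTopology, out: np.ndarray | None = None
) -> np.ndarray:
    if out is None:
        out = np.zeros_like(positions)
    bond_forces(positions, topology, out)
    angle_forces(positions, topology, out)
    if topology.n_dihedrals:
        dihedral_forces(positions, topology, out)
    return out


def break_bonds(
    positions: np.ndarray, topology: BondTopology
) -> tuple[BondTopology, list[tuple[int, int]]]:
    """Remove every pair bond stretched beyond its r_max.

    Angle and dihedral bonds that reference a broken pair (as consecutive
    members) go with it: a hinge with a missing arm is undefined.  Breakage
    is irreversible; re-bonding happens only through solidification.
    """
    if topology.n_bonds == 0:
        return topology, []
    d = positions[topology.bonds[:, 0]] - positions[topology.bonds[:, 1]]
    r = np.sqrt((d * d).sum(axis=1))
    broken = r > topology.bond_rmax
    if not broken.any():
        return topology, []
    events = [tuple(int(x) for x in pair) for pair in topology.bonds[broken]]
    n_guess = int(topology.bonds.max()) + 1
    broken_keys = bond_pair_keys(topology.bonds[broken], n_guess)

    new = topology.copy()
    new._filter_bonds(~broken)
    if new.n_angles:
        p1 = bond_pair_keys(new.angles[:, [0, 1]], n_guess)
        p2 = bond_pair_keys(new.angles[:, [1, 2]], n_guess)
        hit = np.isin(p1, broken_keys) | np.isin(p2, broken_keys)
        new._filter_angles(~hit)
    if new.n_dihedrals:
        hit = np.zeros(new.n_dihedrals, dtype=bool)
        for cols in ([0, 1], [1, 2], [2, 3]):
            hit |= np.isin(bond_pair_keys(new.dihedrals[:, cols], n_guess), broken_keys)
        new._filter_dihedrals(~hit)
    return new, events


# ----------------------------------------------------------------------------
# topology builders
# ----------------------------------------------------------------------------


def build_membrane(
    n_beads: int,
    radius: float,
    k_b: float,
    r_0: float,
    r_max: float = np.inf,
    k_a: float = 0.0,
    theta0_deg: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, BondTopology]:
    """Closed ring of beads: consecutive pair bonds + consecutive-triplet hinges.

    A single particle layer gives the membrane an elastic and a bending
    modulus while leaving Poisson's ratio, shear and torsional moduli out.
    ``theta0_deg`` defaults to the regular-polygon interior angle, which makes
    the resting ring force-free.
    """
    if n_beads < 3:
        raise ValueError("a closed membrane needs at least 3 beads")
    ang = 2.0 * np.pi * np.arange(n_beads) / n_beads
    pos = np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1
    )
    topo = BondTopology()
    nxt = (np.arange(n_beads) + 1) % n_beads
    topo.add_bonds(np.stack([np.arange(n_beads), nxt], axis=1), k_b, r_0, r_max)
    if k_a > 0.0:
        if theta0_deg is None:
            theta0 = np.pi * (n_beads - 2) / n_beads
        else:
            theta0 = np.deg2rad(theta0_deg)
        prv = (np.arange(n_beads) - 1) % n_beads
        topo.add_angles(np.stack([prv, np.arange(n_beads), nxt], axis=1), k_a, theta0)
    return pos, topo


def build_braced_lattice(
    nx: int,
    ny: int,
    spacing: float,
    k_b: float,
    r_0: float | None = None,
    r_max: float = np.inf,
    k_a: float = 0.0,
    theta0_deg: float = 90.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, BondTopology]:
    """Rectangular block with nearest-neighbor bonds and right-angle braces.

    The corner hinges of every unit square resist shear; with theta0 = 90 deg
    the resting lattice is force-free.  Suitable for rigid/brittle cubes and
    solidified bodies.
    """
    if nx < 2 or ny < 2:
        raise ValueError("lattice needs nx, ny >= 2")
    if r_0 is None:
        r_0 = spacing
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pos = np.stack(
        [origin[0] + ix.ravel() * spacing, origin[1] + iy.ravel() * spacing], axis=1
    )

    def idx(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * ny + j

    topo = BondTopology()
    bonds = []
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny), indexing="ij")
    bonds.append(np.stack([idx(i, j).ravel(), idx(i + 1, j).ravel()], axis=1))
    i, j = np.meshgrid(np.arange(nx), np.arange(ny - 1), indexing="ij")
    bonds.append(np.stack([idx(i, j).ravel(), idx(i, j + 1).ravel()], axis=1))
    topo.add_bonds(np.concatenate(bonds), k_b, r_0, r_max)

    if k_a > 0.0:
        theta0 = np.deg2rad(theta0_deg)
        i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
        a = idx(i, j).ravel()        # bottom-left of each unit square
        b = idx(i + 1, j).ravel()    # bottom-right
        c = idx(i + 1, j + 1).ravel()  # top-right
        d = idx(i, j + 1).ravel()    # top-left
        tris = np.concatenate(
            [
                np.stack([b, a, d], axis=1),
                np.stack([a, b, c], axis=1),
                np.stack([b, c, d], axis=1),
                np.stack([c, d, a], axis=1),
            ]
        )
        topo.add_angles(tris, k_a, theta0)
    return pos, topo
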