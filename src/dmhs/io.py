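"""Trajectory and observable writers (plain-text formats only).

Frames go out as extended-XYZ (full-precision, round-trippable), legacy
ASCII VTK polydata (loads in standard visualization tools) or CSV; bond
topology is written as a sidecar text table so breakage/formation history is
reconstructible.  All headers are self-describing (units, seed, time).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .cgmd import BondTopology
from .core import ParticleSystem, Phase

_XYZ_SCALARS = (
    "mass",
    "density",
    "pressure",
    "internal_energy",
    "temperature",
    "water_mass",
    "concentration",
    "radius",
)


def write_frame(
    system: ParticleSystem,
    topology: BondTopology | None,
    path: str | Path,
    fmt: str = "xyz",
    time: float = 0.0,
    seed: int = 0,
) -> Path:
    path = Path(path)
    if fmt == "xyz":
        _write_xyz(system, path, time, seed)
    elif fmt == "vtk":
        _write_vtk(system, path, time, seed)
    elif fmt == "csv":
        _write_csv(system, path, time, seed)
    else:
        raise ValueError(f"unknown frame format {fmt!r}")
    if topology is not None and fmt == "xyz":
        write_bond_table(path.with_suffix(".bonds.txt"), topology)
    return path


def _write_xyz(system: ParticleSystem, path: Path, time: float, seed: int) -> None:
    props = "species:S:1:pos:R:3:velo:R:3"
    for name in _XYZ_SCALARS:
        props += f":{name}:R:1"
    props += ":phase:I:1:body:I:1"
    with open(path, "w") as fh:
        fh.write(f"{system.n}\n")
        fh.write(f'Properties={props} time={time:.17g} seed={seed} units=SI\n')
        for k in range(system.n):
            fields = [
                Phase(int(system.phase[k])).name,
                f"{system.position[k, 0]:.17g}",
                f"{system.position[k, 1]:.17g}",
                "0",
                f"{system.velocity[k, 0]:.17g}",
                f"{system.velocity[k, 1]:.17g}",
                "0",
            ]
            fields += [f"{getattr(system, n)[k]:.17g}" for n in _XYZ_SCALARS]
            fields += [str(int(system.phase[k])), str(int(system.body_id[k]))]
            fh.write(" ".join(fields) + "\n")


def read_xyz(path: str | Path) -> ParticleSystem:
    """Read back a frame written by :func:`write_frame` (full precision)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()  # header
        system = ParticleSystem.empty(n)
        for k in range(n):
            parts = fh.readline().split()
            system.position[k] = [float(parts[1]), float(parts[2])]
            system.velocity[k] = [float(parts[4]), float(parts[5])]
            for off, name in enumerate(_XYZ_SCALARS):
                getattr(system, name)[k] = float(parts[7 + off])
            system.phase[k] = int(parts[7 + len(_XYZ_SCALARS)])
            system.body_id[k] = int(parts[8 + len(_XYZ_SCALARS)])
    return system


def _write_vtk(system: ParticleSystem, path: Path, time: float, seed: int) -> None:
    n = system.n
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"particle frame time={time:.9g} seed={seed} units=SI\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for k in range(n):
            fh.write(
                f"{system.position[k, 0]:.9g} {system.position[k, 1]:.9g} 0\n"
            )
        fh.write(f"VERTICES {n} {2 * n}\n")
        for k in range(n):
            fh.write(f"1 {k}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name in ("temperature", "concentration", "density", "pressure"):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            arr = getattr(system, name)
            fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
        fh.write("SCALARS phase int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in system.phase) + "\n")
        fh.write("SCALARS body int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in system.body_id) + "\n")
        fh.write("VECTORS velocity double\n")
        for k in range(n):
            fh.write(
                f"{system.velocity[k, 0]:.9g} {system.velocity[k, 1]:.9g} 0\n"
            )


def _write_csv(system: ParticleSystem, path: Path, time: float, seed: int) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# time={time:.17g} seed={seed} units=SI\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["x", "y", "vx", "vy"] + list(_XYZ_SCALARS) + ["phase", "body_id"]
        )
        for k in range(system.n):
            writer.writerow(
                [system.position[k, 0], system.position[k, 1],
                 system.velocity[k, 0], system.velocity[k, 1]]
                + [getattr(system, n)[k] for n in _XYZ_SCALARS]
                + [int(system.phase[k]), int(system.body_id[k])]
            )


def write_bond_table(path: str | Path, topology: BondTopology) -> Path:
    """One record per bond: type, indices, parameters (plain text)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# type indices... parameters (k, rest geometry, r_max)\n")
        for b in range(topology.n_bonds):
            i, j = topology.bonds[b]
            fh.write(
                f"bond {i} {j} {topology.bond_k[b]:.9g} "
                f"{topology.bond_r0[b]:.9g} {topology.bond_rmax[b]:.9g}\n"
            )
        for a in range(topology.n_angles):
            i, j, k = topology.angles[a]
            fh.write(
                f"angle {i} {j} {k} {topology.angle_k[a]:.9g} "
                f"{topology.angle_theta0[a]:.9g}\n"
            )
        for d in range(topology.n_dihedrals):
            i, j, k, l = topology.dihedrals[d]
            fh.write(
                f"dihedral {i} {j} {k} {l} {topology.dihedral_k[d]:.9g} "
                f"{topology.dihedral_phi0[d]:.9g}\n"
            )
    return path


def write_observables(path: str | Path, records: list[dict]) -> Path:
    path = Path(path)
    if not records:
        path.write_text("")
        return path
    keys: list[str] = []
    for rec in records:
        for k in rec:
            if k not in keys:
                keys.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(records)
    return path


def write_events(path: str | Path, events: dict[str, list]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["event", "step", "a", "b"])
        for kind, rows in events.items():
            for row in rows:
                padded = list(row) + [""] * (2 - (len(row) - 1))
                writer.writerow([kind] + padded[:3])
    return path
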