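"""Scenario builders: the worked examples, their reduced desk-scale variants
and small deterministic test fixtures.

Each builder assembles the initial particle state, bond topology and
material model of one study case programmatically (there are no external
data files) and returns a :class:`Scenario` ready to hand to
:class:`~dmhs.runner.Simulation`.  Full-scale configurations keep the
published parameter sets (channel cell flows, cubes in Poiseuille flow,
casting, cleaning, lava on an incline, the pin-array cell sorter); the
``*_reduced`` and ``*_test`` variants are cut down in particle count and
step count so the same physics runs in seconds, with the governing
dimensionless ratios preserved (see docs/methods.md).

All randomness flows through ``numpy.random.default_rng(seed)``: two builds
with the same name, overrides and seed are bit-for-bit identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgmd import BondTopology, build_braced_lattice, build_membrane
from .core import BoundarySpec, ParticleSystem, Phase
from .dem import ContactLaw, CouplingLaw
from .forces import Model
from .runner import ScenarioConfig, Simulation
from .sph import FluidLaw, KernelSpec
from .thermo import ThermalLaw, temperature_to_energy
from .transport import DiffusionLaw


@dataclass
class Scenario:
    config: ScenarioConfig
    system: ParticleSystem
    topology: BondTopology
    model: Model

    def simulation(self) -> Simulation:
        return Simulation(self.config, self.system, self.topology, self.model)


# ----------------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------------


def _lattice(nx: int, ny: int, dl: float, origin=(0.0, 0.0)) -> np.ndarray:
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.stack(
        [origin[0] + (ix.ravel() + 0.5) * dl, origin[1] + (iy.ravel() + 0.5) * dl],
        axis=1,
    )


def particle_block(
    pos: np.ndarray,
    mass: float | np.ndarray,
    density: float | np.ndarray,
    phase: Phase,
    body_id: int = -1,
    radius: float = 0.0,
    velocity=(0.0, 0.0),
    temperature: float = 0.0,
    energy: float | None = None,
    concentration: float = 0.0,
) -> ParticleSystem:
    n = pos.shape[0]
    block = ParticleSystem.empty(n)
    block.position[:] = pos
    block.velocity[:] = np.asarray(velocity, dtype=float)
    block.mass[:] = mass
    block.density[:] = density
    block.phase[:] = int(phase)
    block.body_id[:] = body_id
    block.radius[:] = radius
    block.temperature[:] = temperature
    if energy is not None:
        block.internal_energy[:] = energy
    block.concentration[:] = concentration
    return block


def _wall_rows(
    nx: int, dl: float, y0: float, layers: int, body_id: int, mass, rho,
    velocity=(0.0, 0.0), radius: float = 0.0, x0: float = 0.0,
    temperature: float = 0.0, energy: float = 0.0,
) -> ParticleSystem:
    pos = _lattice(nx, layers, dl, origin=(x0, y0))
    return particle_block(
        pos, mass, rho, Phase.WALL, body_id, radius, velocity,
        temperature=temperature, energy=energy,
    )


def _wall_cols(
    ny: int, dl: float, x0: float, layers: int, body_id: int, mass, rho,
    y0: float = 0.0, radius: float = 0.0, temperature: float = 0.0,
    energy: float = 0.0,
) -> ParticleSystem:
    pos = _lattice(layers, ny, dl, origin=(x0, y0))
    return particle_block(
        pos, mass, rho, Phase.WALL, body_id, radius,
        temperature=temperature, energy=energy,
    )


# ----------------------------------------------------------------------------
# cell in a channel (and its variants)
# ----------------------------------------------------------------------------

CELL_DEFAULTS = dict(
    dl=5e-6, fluid_mass=2.5e-8, rho0=1000.0, mu=0.1, h=1.18e-5,
    n_membrane=48, r_0=3.3e-6, r_max=3.6e-6, k_b=10.0, theta0_deg=172.5,
    k_a=1e-18, n_cytoplasm=61, lj_eps=1e-12, dt=1e-7, n_steps=10_000_000,
)


def _build_cell_channel_family(
    seed: int,
    name: str,
    nx: int = 128,
    ny: int = 16,
    fg=(1.0, 0.0),
    v_wall: float = 0.0,
    breakable: bool = False,
    extra_walls: ParticleSystem | None = None,
    with_cell: bool = True,
    **over,
) -> Scenario:
    p = dict(CELL_DEFAULTS)
    p.update(over)
    dl, m, rho0 = p["dl"], p["fluid_mass"], p["rho0"]
    width = ny * dl

    radius_cell = p["n_membrane"] * p["r_0"] / (2.0 * np.pi)
    center = (0.25 * nx * dl, 0.5 * width)
    if with_cell:
        # carve the cell hole as whole columns' worth of the nearest lattice
        # sites and extend the channel by as many columns, so the carrier
        # keeps exactly nx*ny fluid particles
        probe = _lattice(nx, ny, dl)
        d = np.hypot(probe[:, 0] - center[0], probe[:, 1] - center[1])
        n_in = int(np.sum(d <= radius_cell + 0.4 * dl))
        extra = int(np.ceil(n_in / ny))
        nx_total = nx + extra
        pos = _lattice(nx_total, ny, dl)
        d = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1])
        drop_idx = np.argsort(d, kind="stable")[: extra * ny]
        keep = np.ones(pos.shape[0], dtype=bool)
        keep[drop_idx] = False
        pos = pos[keep]
    else:
        nx_total = nx
        pos = _lattice(nx, ny, dl)
    length = nx_total * dl

    fluid = particle_block(pos, m, rho0, Phase.FLUID, -1, 0.5 * dl)
    layers = 3
    bottom = _wall_rows(nx_total, dl, -layers * dl, layers, 0, m, rho0,
                        radius=0.5 * dl)
    top = _wall_rows(
        nx_total, dl, width, layers, 1, m, rho0, velocity=(v_wall, 0.0),
        radius=0.5 * dl,
    )
    blocks = [fluid, bottom, top]
    if extra_walls is not None:
        blocks.append(extra_walls)

    topology = BondTopology()
    species: dict = {}
    if with_cell:
        mem_pos, topology = build_membrane(
            p["n_membrane"], radius_cell, p["k_b"], p["r_0"],
            p["r_max"] if breakable else np.inf, p["k_a"], p["theta0_deg"],
            center=center,
        )
        offset = sum(b.n for b in blocks)
        topology = BondTopology.merge([topology], [offset])
        membrane = particle_block(
            mem_pos, m, rho0, Phase.SOLID, 2, 0.5 * p["r_0"]
        )
        # cytoplasm: concentric rings 1+6+12+18+24 = 61 particles, SPH fluid
        # with the same properties as the carrier liquid
        rings = [(0, 1)] + [(k, 6 * k) for k in range(1, 5)]
        r_in = radius_cell - 0.75 * dl
        pts = []
        for k, cnt in rings:
            rr = r_in * k / 4.0
            ang = 2.0 * np.pi * np.arange(cnt) / max(cnt, 1)
            pts.append(
                np.stack(
                    [center[0] + rr * np.cos(ang), center[1] + rr * np.sin(ang)],
                    axis=1,
                )
            )
        cyt_pos = np.concatenate(pts)
        m_cyt = rho0 * np.pi * r_in**2 / p["n_cytoplasm"]
        cytoplasm = particle_block(cyt_pos, m_cyt, rho0, Phase.FLUID, -1, 0.5 * dl)
        blocks += [membrane, cytoplasm]
        species = {"cell": [2]}

    system = ParticleSystem.concatenate(blocks)
    vmax_est = max(abs(fg[0]) * width**2 / (8.0 * p["mu"] / rho0), v_wall, 1e-9)
    c0 = max(10.0 * vmax_est, np.sqrt(200.0 * max(abs(fg[0]), abs(fg[1]), 1e-12) * width))
    boundary = BoundarySpec(
        lo=(0.0, -layers * dl), hi=(length, width + layers * dl),
        periodic=(True, False),
    )
    model = Model(
        boundary=boundary,
        kernel=KernelSpec(p["h"]),
        fluid=FluidLaw(rho0, c0, p["mu"], viscosity="morris"),
        coupling=CouplingLaw(p["lj_eps"], dl),
        body_force=np.asarray(fg, dtype=float),
    )
    config = ScenarioConfig(
        name=name, dt=p["dt"], n_steps=p["n_steps"], seed=seed,
        species=species, params={**p, "c0": c0, "fg": fg, "v_wall": v_wall},
    )
    return Scenario(config, system, topology, model)


def _mask_block(block: ParticleSystem, keep: np.ndarray) -> ParticleSystem:
    out = ParticleSystem.empty(int(keep.sum()))
    for name in (
        "position", "velocity", "mass", "density", "pressure",
        "internal_energy", "temperature", "water_mass", "concentration",
        "phase", "body_id", "radius", "force",
    ):
        getattr(out, name)[:] = getattr(block, name)[keep]
    return out


def build_cell_channel(seed: int = 0, **over) -> Scenario:
    return _build_cell_channel_family(seed, "cell_channel", **over)


def build_cell_obstacle(seed: int = 0, gap: float = 3.2e-5, **over) -> Scenario:
    p = dict(CELL_DEFAULTS)
    p.update(over)
    dl = p["dl"]
    nx = over.get("nx", 128)
    ny = over.get("ny", 16)
    width = ny * dl
    x_obs = 0.55 * nx * dl
    rows_low = int(np.floor((0.5 * (width - gap)) / dl))
    low = _lattice(2, rows_low, dl, origin=(x_obs, 0.0))
    high = _lattice(2, rows_low, dl, origin=(x_obs, width - rows_low * dl))
    walls = particle_block(
        np.concatenate([low, high]), p["fluid_mass"], p["rho0"], Phase.WALL, 3,
        0.5 * dl,
    )
    return _build_cell_channel_family(
        seed, "cell_obstacle", extra_walls=walls, **over
    )


def build_cell_aspiration(seed: int = 0, gap: float = 2.0e-5, **over) -> Scenario:
    over.setdefault("fg", (10.0, 0.0))
    p = dict(CELL_DEFAULTS)
    p.update({k: v for k, v in over.items() if k in p})
    dl = p["dl"]
    nx = over.get("nx", 128)
    ny = over.get("ny", 16)
    width = ny * dl
    x0 = 0.8 * nx * dl
    x1 = nx * dl
    pts = []
    for t in np.arange(0.0, 1.0 + 1e-9, dl / (x1 - x0)):
        x = x0 + t * (x1 - x0)
        y_low = t * 0.5 * (width - gap)
        for layer in range(2):
            pts.append((x, y_low - layer * dl))
            pts.append((x, width - y_low + layer * dl))
    walls = particle_block(
        np.asarray(pts), p["fluid_mass"], p["rho0"], Phase.WALL, 3, 0.5 * dl
    )
    return _build_cell_channel_family(
        seed, "cell_aspiration", extra_walls=walls, **over
    )


def build_cell_shear(seed: int = 0, **over) -> Scenario:
    over.setdefault("fg", (0.0, 0.0))
    return _build_cell_channel_family(
        seed, "cell_shear", v_wall=over.pop("v_wall", 2e-3), breakable=True, **over
    )


def build_cell_piercing(seed: int = 0, **over) -> Scenario:
    over.setdefault("fg", (10.0, 0.0))
    p = dict(CELL_DEFAULTS)
    p.update({k: v for k, v in over.items() if k in p})
    dl = p["dl"]
    nx = over.get("nx", 128)
    ny = over.get("ny", 16)
    width = ny * dl
    xs = np.arange(0.85 * nx * dl, nx * dl, dl)
    pts = np.stack([xs, np.full_like(xs, 0.5 * width)], axis=1)
    walls = particle_block(
        pts, p["fluid_mass"], p["rho0"], Phase.WALL, 3, 0.5 * dl
    )
    return _build_cell_channel_family(
        seed, "cell_piercing", extra_walls=walls, breakable=True, **over
    )


# ----------------------------------------------------------------------------
# cubes in Poiseuille flow
# ----------------------------------------------------------------------------

CUBES_DEFAULTS = dict(
    fluid_mass=5.7e-3, rho0=1000.0, mu=0.1, h=5.6e-3, r_0=2.3e-3,
    k_b=10.0, theta0_deg=90.0, k_a=1e-4,
    k_n=1e5, gamma_n=0.3, k_t=1e3, gamma_t=0.2, mu_s=0.5,
    dt=0.5e-4, n_steps=10_000_000, lj_eps=1e-7,
)


def build_cubes_poiseuille(
    seed: int = 0,
    variant: str = "neutral",
    nx: int = 80,
    ny: int = 24,
    n_cubes: int = 4,
    cube_side: int = 7,
    fg: float = 0.1,
    **over,
) -> Scenario:
    """Cubic dispersed bodies in a body-force-driven channel.

    ``variant``: "neutral" (density-matched), "buoyant" (990 kg/m^3, channel
    partially filled, free surface) or "heavy" (1500 kg/m^3, brittle bonds
    with 0.1% allowed strain, vertical gravity).
    """
    if variant not in ("neutral", "buoyant", "heavy"):
        raise ValueError(f"unknown cubes variant {variant!r}")
    p = dict(CUBES_DEFAULTS)
    p.update(over)
    dl = np.sqrt(p["fluid_mass"] / p["rho0"])
    rho_s = {"neutral": 1000.0, "buoyant": 990.0, "heavy": 1500.0}[variant]
    gravity = 0.0 if variant == "neutral" else -9.81
    fill = int(ny * 2 / 3) if variant == "buoyant" else ny
    width = ny * dl
    length = nx * dl

    fluid = particle_block(
        _lattice(nx, fill, dl), p["fluid_mass"], p["rho0"], Phase.FLUID, -1,
        0.5 * dl,
    )
    layers = 3
    bottom = _wall_rows(nx, dl, -layers * dl, layers, 0, p["fluid_mass"],
                        p["rho0"], radius=0.5 * dl)
    top = _wall_rows(nx, dl, width, layers, 1, p["fluid_mass"], p["rho0"],
                     radius=0.5 * dl)
    blocks = [fluid, bottom, top]

    rng = np.random.default_rng(seed)
    side = (cube_side - 1) * p["r_0"]
    topo_parts, offsets = [], []
    r_max = (
        p["r_0"] * (1.0 + 1e-3) if variant == "heavy" else np.inf
    )  # brittle: 0.1% allowed strain
    bead_mass = rho_s * p["r_0"] ** 2
    xs = np.linspace(0.15 * length, 0.85 * length, n_cubes)
    margin = 2.0 ** (1.0 / 6.0) * dl  # carve fluid out to the LJ rest distance
    keep = np.ones(fluid.n, dtype=bool)
    for c in range(n_cubes):
        y0 = (0.15 + 0.3 * rng.random()) * fill * dl
        x0 = xs[c] - 0.5 * side
        pos, topo = build_braced_lattice(
            cube_side, cube_side, p["r_0"], p["k_b"], p["r_0"], r_max,
            p["k_a"], p["theta0_deg"], origin=(x0, y0),
        )
        keep &= ~(
            (fluid.position[:, 0] > x0 - margin)
            & (fluid.position[:, 0] < x0 + side + margin)
            & (fluid.position[:, 1] > y0 - margin)
            & (fluid.position[:, 1] < y0 + side + margin)
        )
        offsets.append(sum(b.n for b in blocks))
        topo_parts.append(topo)
        blocks.append(
            particle_block(pos, bead_mass, rho_s, Phase.SOLID, 2 + c,
                           0.5 * p["r_0"])
        )
    topology = BondTopology.merge(topo_parts, offsets)
    n_removed = int((~keep).sum())
    blocks[0] = _mask_block(fluid, keep)
    # index bookkeeping: cube blocks were appended after the fluid block,
    # so removing fluid particles shifts every cube index down uniformly
    topology = BondTopology.merge([topology], [-n_removed])
    system = ParticleSystem.concatenate(blocks)

    nu = p["mu"] / p["rho0"]
    vmax = fg * width**2 / (8.0 * nu)
    c0 = max(10.0 * vmax, np.sqrt(200.0 * max(fg, abs(gravity)) * width))
    boundary = BoundarySpec(
        lo=(0.0, -layers * dl), hi=(length, width + layers * dl),
        periodic=(True, False),
    )
    model = Model(
        boundary=boundary,
        kernel=KernelSpec(p["h"]),
        fluid=FluidLaw(p["rho0"], c0, p["mu"], viscosity="monaghan"),
        contact=ContactLaw(p["k_n"], p["gamma_n"], p["k_t"], p["gamma_t"],
                           p["mu_s"]),
        coupling=CouplingLaw(p["lj_eps"], dl),
        body_force=np.array([fg, gravity]),
    )
    config = ScenarioConfig(
        name=f"cubes_poiseuille_{variant}", dt=p["dt"], n_steps=p["n_steps"],
        seed=seed, species={"cubes": list(range(2, 2 + n_cubes))},
        params={**p, "variant": variant, "rho_solid": rho_s, "c0": c0,
                "fg": fg, "dl": dl},
    )
    return Scenario(config, system, topology, model)


# ----------------------------------------------------------------------------
# casting (solidification / melting)
# ----------------------------------------------------------------------------

CASTING_DEFAULTS = dict(
    rho0=1000.0, fluid_mass=0.62, h=4e-2, kappa=1.0, kappa_wall=100.0,
    c_v_solid=2.0, c_v_liquid=1.0, T_star=25.0, e_sol=50.0, e_liq=100.0,
    k_T=0.02, T_air=0.0, T_init=100.0, T_wall=0.0,
    bond_radius=2.5e-2, bond_k=1e5, bond_r0=2.5e-2,
    k_n=1e4, gamma_n=0.3, k_t=1e3, gamma_t=0.2, mu_s=0.5,
    mu=0.1, lj_eps=1e-5, dt=1e-3, n_steps=100_000,
)


def _casting(
    seed: int,
    name: str,
    fill_w: int,
    fill_h: int,
    drop: float,
    gravity: float,
    motion: bool,
    latent: bool,
    k_T: float,
    n_steps: int,
    dt: float,
    c0: float,
    bond_rmax: float = np.inf,
    mould_w: int | None = None,
    side_h: int | None = None,
    **over,
) -> Scenario:
    p = dict(CASTING_DEFAULTS)
    p.update(over)
    p["k_T"] = k_T
    dl = np.sqrt(p["fluid_mass"] / p["rho0"])
    law = ThermalLaw(
        kappa=p["kappa"], c_v_solid=p["c_v_solid"], c_v_liquid=p["c_v_liquid"],
        T_star=p["T_star"],
        e_sol=p["c_v_solid"] * p["T_star"],
        e_liq=(p["e_liq"] if latent else p["c_v_solid"] * p["T_star"]),
        k_T=k_T, T_air=p["T_air"], kappa_wall=p["kappa_wall"],
        bond_search_radius=p["bond_radius"], bond_k=p["bond_k"],
        bond_r0=p["bond_r0"], bond_rmax=bond_rmax,
    )
    e_init = float(temperature_to_energy(p["T_init"], law))
    e_wall = float(temperature_to_energy(p["T_wall"], law, liquid_fraction=0.0))

    mould_w = fill_w + 4 if mould_w is None else mould_w
    side_h = fill_h + 6 if side_h is None else side_h
    layers = 3
    floor = _wall_rows((mould_w + 2 * layers), dl, -layers * dl, layers, 0,
                       p["fluid_mass"], p["rho0"], radius=0.5 * dl,
                       x0=-layers * dl, temperature=p["T_wall"], energy=e_wall)
    left = _wall_cols(side_h, dl, -layers * dl, layers, 0, p["fluid_mass"],
                      p["rho0"], radius=0.5 * dl, temperature=p["T_wall"],
                      energy=e_wall)
    right = _wall_cols(side_h, dl, mould_w * dl, layers, 0, p["fluid_mass"],
                       p["rho0"], radius=0.5 * dl, temperature=p["T_wall"],
                       energy=e_wall)
    x_fill = 0.5 * (mould_w - fill_w) * dl
    liquid = particle_block(
        _lattice(fill_w, fill_h, dl, origin=(x_fill, drop)),
        p["fluid_mass"], p["rho0"], Phase.FLUID, -1, 0.5 * dl,
        temperature=p["T_init"], energy=e_init,
    )
    system = ParticleSystem.concatenate([floor, left, right, liquid])
    top = max(side_h * dl, drop + (fill_h + 2) * dl)
    boundary = BoundarySpec(
        lo=(-(layers + 1) * dl, -(layers + 1) * dl),
        hi=((mould_w + layers + 1) * dl, top + 5 * dl),
        periodic=(False, False),
    )
    model = Model(
        boundary=boundary,
        kernel=KernelSpec(p["h"]),
        fluid=FluidLaw(p["rho0"], c0, p["mu"], viscosity="monaghan"),
        contact=ContactLaw(p["k_n"], p["gamma_n"], p["k_t"], p["gamma_t"],
                           p["mu_s"]),
        coupling=CouplingLaw(p["lj_eps"], dl),
        thermal=law,
        body_force=np.array([0.0, gravity]),
        isothermal_walls=True,
        motion=motion,
    )
    config = ScenarioConfig(
        name=name, dt=dt, n_steps=n_steps, seed=seed,
        params={**p, "dl": dl, "gravity": gravity, "latent": latent, "c0": c0},
    )
    return Scenario(config, system, BondTopology(), model)


def build_casting_slow(seed: int = 0, **over) -> Scenario:
    """Pouring into a cold mould with latent heat and slow surface cooling."""
    return _casting(
        seed, "casting_slow", fill_w=10, fill_h=8, drop=0.5, gravity=-9.81,
        motion=True, latent=True, k_T=over.pop("k_T", 0.02),
        n_steps=over.pop("n_steps", 100_000), dt=over.pop("dt", 3e-4),
        c0=35.0, **over,
    )


def build_casting_slow_reduced(seed: int = 0, **over) -> Scenario:
    """Liquid already at rest in the mould; pure conduction + solidification.

    Motion is frozen so the wall-to-bulk solidification ordering can be
    observed on a static lattice in a few thousand steps.
    """
    fill_w = over.pop("fill_w", 8)
    return _casting(
        seed, "casting_slow_reduced", fill_w=fill_w,
        fill_h=over.pop("fill_h", 8), drop=0.0, gravity=0.0, motion=False,
        latent=True, k_T=over.pop("k_T", 0.02),
        n_steps=over.pop("n_steps", 3000), dt=over.pop("dt", 1e-2), c0=10.0,
        mould_w=fill_w,
        **over,
    )


def build_casting_fast(seed: int = 0, **over) -> Scenario:
    """Ultrafast surface cooling: a crust forms before the melt lands.

    Latent heat is neglected (e_sol = e_liq) and crust fragments are brittle
    (r_max = 4e-2 m).
    """
    return _casting(
        seed, "casting_fast", fill_w=10, fill_h=8, drop=0.5, gravity=-9.81,
        motion=True, latent=False, k_T=over.pop("k_T", 0.5),
        n_steps=over.pop("n_steps", 100_000), dt=over.pop("dt", 3e-4),
        c0=35.0, bond_rmax=4e-2, **over,
    )


def build_casting_fast_reduced(seed: int = 0, k_T: float = 0.5, **over) -> Scenario:
    """Small hot blob falling slowly toward a cold floor.

    The fall lasts ~5 s (reduced gravity), longer than the 1/k_T = 2 s
    surface-cooling time at k_T = 0.5 but far shorter than the 50 s at
    k_T = 0.02, so the crust-before-contact contrast is observable in a few
    thousand steps.
    """
    return _casting(
        seed, "casting_fast_reduced", fill_w=over.pop("fill_w", 6),
        fill_h=over.pop("fill_h", 6), drop=over.pop("drop", 12.0),
        gravity=over.pop("gravity", -1.0), motion=True, latent=False, k_T=k_T,
        n_steps=over.pop("n_steps", 45_000), dt=over.pop("dt", 1.2e-4),
        c0=50.0, bond_rmax=4e-2, side_h=4, **over,
    )


# ----------------------------------------------------------------------------
# cleaning (soil swelling and removal)
# ----------------------------------------------------------------------------

CLEANING_DEFAULTS = dict(
    rho0=1000.0, fluid_mass=2.3e-6, h=1.1e-4, mu=1e-3,
    soil_rho=1800.0, soil_diameter=4.7e-5, D=1e-9,
    sigma_adh=5e-5, eps_pair=7e-11, eps_surface=5e-10, c_release=0.5,
    lj_eps=1e-13, v_wall=2e-4, gravity=-9.81, dt=1e-6, n_steps=50_000_000,
)


def build_cleaning(
    seed: int = 0,
    nx: int = 16,
    ny: int = 8,
    n_soil: int = 6,
    **over,
) -> Scenario:
    """Protein soil on a surface under shear flow: swelling, adhesion decay,
    removal once the water concentration reaches the release threshold."""
    p = dict(CLEANING_DEFAULTS)
    p.update(over)
    dl = np.sqrt(p["fluid_mass"] / p["rho0"])
    width = ny * dl
    length = nx * dl
    layers = 3

    fluid = particle_block(
        _lattice(nx, ny, dl), p["fluid_mass"], p["rho0"], Phase.FLUID, -1,
        0.5 * dl, concentration=1.0,
    )
    fluid.water_mass[:] = fluid.mass / fluid.density  # saturated reservoir
    bottom = _wall_rows(nx, dl, -layers * dl, layers, 0, p["fluid_mass"],
                        p["rho0"], radius=0.5 * dl)
    top = _wall_rows(nx, dl, width, layers, 1, p["fluid_mass"], p["rho0"],
                     velocity=(p["v_wall"], 0.0), radius=0.5 * dl)

    r_soil = 0.5 * p["soil_diameter"]
    m_soil = p["soil_rho"] * np.pi * r_soil**2
    y_soil = 2.0 ** (1.0 / 6.0) * p["sigma_adh"] - 0.5 * dl  # LJ rest height
    xs = (np.arange(n_soil) + 0.5) * length / n_soil
    soil = particle_block(
        np.stack([xs, np.full(n_soil, y_soil)], axis=1), m_soil, p["soil_rho"],
        Phase.SOLID, 2, r_soil,
    )
    soil.body_id[:] = 2 + np.arange(n_soil)
    keep = np.ones(fluid.n, dtype=bool)
    for x in xs:
        keep &= (
            np.hypot(fluid.position[:, 0] - x, fluid.position[:, 1] - y_soil)
            > 2.0 ** (1.0 / 6.0) * dl  # carve out to the LJ rest distance
        )
    fluid = _mask_block(fluid, keep)
    system = ParticleSystem.concatenate([fluid, bottom, top, soil])

    w_sat = m_soil / p["soil_rho"]  # water content at c = 1
    diffusion = DiffusionLaw(
        D=p["D"], c_release=p["c_release"], eps_pair=p["eps_pair"],
        eps_surface=p["eps_surface"], sigma_adh=p["sigma_adh"],
        swelling_gain=0.5 * np.pi * r_soil**2 / w_sat,
    )
    c0 = max(
        20.0 * p["v_wall"], np.sqrt(200.0 * abs(p["gravity"]) * width), 1e-3
    )
    boundary = BoundarySpec(
        lo=(0.0, -layers * dl), hi=(length, width + layers * dl),
        periodic=(True, False),
    )
    model = Model(
        boundary=boundary,
        kernel=KernelSpec(p["h"]),
        fluid=FluidLaw(p["rho0"], c0, p["mu"], viscosity="morris"),
        coupling=CouplingLaw(p["lj_eps"], dl),
        diffusion=diffusion,
        body_force=np.array([0.0, p["gravity"]]),
    )
    config = ScenarioConfig(
        name="cleaning", dt=p["dt"], n_steps=p["n_steps"], seed=seed,
        species={"soil": list(range(2, 2 + n_soil))},
        params={**p, "dl": dl, "c0": c0, "n_soil": n_soil},
    )
    return Scenario(config, system, BondTopology(), model)


def build_cleaning_reduced(seed: int = 0, moving_wall: bool = True, **over) -> Scenario:
    """Desk-scale cleaning: faster wall, boosted diffusivity, larger step."""
    over.setdefault("v_wall", 1e-3 if moving_wall else 0.0)
    over.setdefault("D", 1e-7)
    over.setdefault("mu", 1e-2)  # thicker carrier so washed soil advects fast
    over.setdefault("gravity", -2.0)  # scaled anchoring gravity
    over.setdefault("dt", 7e-5)
    over.setdefault("n_steps", 22_000)
    sc = build_cleaning(seed, nx=over.pop("nx", 14), ny=over.pop("ny", 7),
                        n_soil=over.pop("n_soil", 5), **over)
    sc.config.name = "cleaning_reduced"
    return sc


# ----------------------------------------------------------------------------
# lava on an inclined plane
# ----------------------------------------------------------------------------

LAVA_DEFAULTS = dict(
    rho0=2000.0, fluid_mass=1.25, h=4e-2, mu=1.0, kappa=1.0, c_v=1.0,
    T_init=1000.0, T_star=500.0, k_T=0.02, T_air=0.0,
    bond_radius=2.5e-2, bond_k=1e5, bond_r0=2.5e-2, bond_rmax=4e-2,
    k_n=1e6, gamma_n=0.3, k_t=1e4, gamma_t=0.1, mu_s=0.5,
    incline_deg=30.0, lj_eps=1e-5, dt=1e-4, n_steps=10_000_000,
)


def build_lava_incline(
    seed: int = 0, nx: int = 24, ny: int = 6, floor_nx: int = 60, **over
) -> Scenario:
    """Hot blob flowing down an incline, cooling at the surface, blending
    SPH and DEM forces as sub-scale solids form (no latent heat)."""
    p = dict(LAVA_DEFAULTS)
    p.update(over)
    dl = np.sqrt(p["fluid_mass"] / p["rho0"])
    theta = np.deg2rad(p["incline_deg"])
    g = 9.81
    law = ThermalLaw(
        kappa=p["kappa"], c_v_solid=p["c_v"], c_v_liquid=p["c_v"],
        T_star=p["T_star"], e_sol=p["c_v"] * p["T_star"],
        e_liq=p["c_v"] * p["T_star"], k_T=p["k_T"], T_air=p["T_air"],
        bond_search_radius=p["bond_radius"], bond_k=p["bond_k"],
        bond_r0=p["bond_r0"], bond_rmax=p["bond_rmax"],
        blend_T_range=(p["T_star"], p["T_init"]),
    )
    e_init = float(temperature_to_energy(p["T_init"], law))
    layers = 3
    floor = _wall_rows(floor_nx, dl, -layers * dl, layers, 0, p["fluid_mass"],
                       p["rho0"], radius=0.5 * dl)
    blob = particle_block(
        _lattice(nx, ny, dl, origin=(dl, 0.0)), p["fluid_mass"], p["rho0"],
        Phase.FLUID, -1, 0.5 * dl, temperature=p["T_init"], energy=e_init,
    )
    system = ParticleSystem.concatenate([floor, blob])
    c0 = 30.0
    boundary = BoundarySpec(
        lo=(0.0, -(layers + 1) * dl),
        hi=(floor_nx * dl, (ny + 30) * dl),
        periodic=(True, False),
    )
    model = Model(
        boundary=boundary,
        kernel=KernelSpec(p["h"]),
        fluid=FluidLaw(p["rho0"], c0, p["mu"], viscosity="monaghan"),
        contact=ContactLaw(p["k_n"], p["gamma_n"], p["k_t"], p["gamma_t"],
                           p["mu_s"]),
        coupling=CouplingLaw(p["lj_eps"], dl),
        thermal=law,
        body_force=g * np.array([np.sin(theta), -np.cos(theta)]),
        blending=True,
        wall_conduction=False,  # the incline exchanges no heat
    )
    config = ScenarioConfig(
        name="lava_incline", dt=p["dt"], n_steps=p["n_steps"], seed=seed,
        params={**p, "dl": dl, "c0": c0},
    )
    return Scenario(config, system, BondTopology(), model)


# ----------------------------------------------------------------------------
# pin-array ("Plinko") cell sorter
# ----------------------------------------------------------------------------

PLINKO_DEFAULTS = dict(
    x0=0.45e-3, y0=1.5e-3, pitch=30e-6, pin_radius=5e-6,
    cell_radius=10e-6, n_beads=16, r_0=3.9e-6, k_b=1e-2,
    theta0_deg=157.5, k_a_rigid=1e-15, k_a_flexible=1e-16,
    k_n=10.0, gamma_n=0.3, k_t=10.0, gamma_t=0.3, mu_s=0.5,
    mu_water=1e-3, f=100.0, rho_cell=1000.0, dt=1e-7, n_steps=10_000_000,
)


def _assemble_plinko(
    seed: int,
    name: str,
    p: dict,
    n_cells_each: int,
    dt: float,
    n_steps: int,
) -> Scenario:
    rng = np.random.default_rng(seed)
    pitch, pin_r = p["pitch"], p["pin_radius"]
    R = p["cell_radius"]
    bead_r = p["bead_radius"]
    bead_m = p["bead_mass"]
    width, length = p["x0"], p["y0"]

    wall_sp = 1.5 * bead_r
    ys = np.arange(0.0, length + wall_sp, wall_sp)
    left = particle_block(
        np.stack([np.zeros_like(ys), ys], axis=1), bead_m, p["rho_cell"],
        Phase.WALL, 0, bead_r,
    )
    right = particle_block(
        np.stack([np.full_like(ys, width), ys], axis=1), bead_m,
        p["rho_cell"], Phase.WALL, 0, bead_r,
    )
    xs_f = np.arange(0.0, width + wall_sp, wall_sp)
    floor = particle_block(
        np.stack([xs_f, np.zeros_like(xs_f)], axis=1), bead_m, p["rho_cell"],
        Phase.WALL, 0, bead_r,
    )

    pin_rows = np.arange(p["pins_y_lo"], p["pins_y_hi"], pitch)
    pin_pts = []
    for r_idx, y in enumerate(pin_rows):
        off = 0.5 * pitch if r_idx % 2 else 0.0
        xs = np.arange(off + 0.5 * pitch, width - 0.25 * pitch, pitch)
        pin_pts += [(x, y) for x in xs]
    pins = particle_block(
        np.asarray(pin_pts), bead_m, p["rho_cell"], Phase.WALL, 1, pin_r
    )

    blocks = [left, right, floor, pins]
    topo_parts, offsets = [], []
    species = {"flexible": [], "rigid": []}
    centers: list[np.ndarray] = []
    y_lo, y_hi = p["cells_y_lo"], p["cells_y_hi"]
    labels = ["flexible"] * n_cells_each + ["rigid"] * n_cells_each
    rng.shuffle(labels)
    body = 2
    for label in labels:
        for _ in range(10_000):
            c = np.array(
                [
                    rng.uniform(1.6 * R, width - 1.6 * R),
                    rng.uniform(y_lo, y_hi),
                ]
            )
            if all(np.linalg.norm(c - o) > 2.3 * R for o in centers):
                break
        else:  # pragma: no cover - placement region is generously sized
            raise RuntimeError("could not place all cells without overlap")
        centers.append(c)
        k_a = p["k_a_flexible"] if label == "flexible" else p["k_a_rigid"]
        pos, topo = build_membrane(
            p["n_beads"], R, p["k_b"], p["r_0"], np.inf, k_a,
            p["theta0_deg"], center=tuple(c),
        )
        offsets.append(sum(b.n for b in blocks))
        topo_parts.append(topo)
        blocks.append(
            particle_block(pos, bead_m, p["rho_cell"], Phase.SOLID, body,
                           bead_r)
        )
        species[label].append(body)
        body += 1

    topology = BondTopology.merge(topo_parts, offsets)
    system = ParticleSystem.concatenate(blocks)
    boundary = BoundarySpec(
        lo=(-2.0 * R, -2.0 * R), hi=(width + 2.0 * R, length + 2.0 * R),
        periodic=(False, False),
    )
    model = Model(
        boundary=boundary,
        contact=ContactLaw(p["k_n"], p["gamma_n"], p["k_t"], p["gamma_t"],
                           p["mu_s"]),
        body_force=np.array([0.0, -p["f"]]),
        drag_mu=p["mu_water"],
    )
    config = ScenarioConfig(
        name=name, dt=dt, n_steps=n_steps, seed=seed, species=species,
        params=dict(p),
    )
    return Scenario(config, system, topology, model)


def build_plinko(seed: int = 0, n_cells_each: int = 10, **over) -> Scenario:
    """Published-scale pin-array sorter (micron scale, aqueous drag)."""
    p = dict(PLINKO_DEFAULTS)
    p.update(over)
    p["bead_radius"] = 0.5 * p["r_0"]
    p["bead_mass"] = p["rho_cell"] * np.pi * p["bead_radius"] ** 2
    p["pins_y_lo"] = 0.15 * p["y0"]
    p["pins_y_hi"] = 0.75 * p["y0"]
    p["cells_y_lo"] = 0.8 * p["y0"]
    p["cells_y_hi"] = 0.95 * p["y0"]
    return _assemble_plinko(
        seed, "plinko", p, n_cells_each, p["dt"], p["n_steps"]
    )


def build_plinko_reduced(seed: int = 0, n_cells_each: int = 8, **over) -> Scenario:
    """Scaled pin-array sorter (cell radius = 1, bead mass = 1).

    Preserves the governing ratios of the full chip: pin gap below the cell
    diameter, a 10x bending-stiffness contrast between the two species, and
    drag-dominated descent, at ~10^4 instead of ~10^8 steps.  The flexible
    bending stiffness is chosen soft enough to squeeze through the
    sub-diameter gaps yet stiff enough that the ring keeps its round shape
    instead of draping over a pin.
    """
    p = dict(
        x0=18.0, y0=47.0, pitch=3.0, pin_radius=0.35,
        cell_radius=1.0, n_beads=16, r_0=2.0 * np.sin(np.pi / 16),
        k_b=100.0, theta0_deg=157.5, k_a_rigid=50.0, k_a_flexible=5.0,
        k_n=50.0, gamma_n=5.0, k_t=50.0, gamma_t=5.0, mu_s=0.5,
        mu_water=0.13, f=1.0, rho_cell=1.0,
        bead_radius=0.25, bead_mass=1.0,
        pins_y_lo=6.0, pins_y_hi=33.0, cells_y_lo=34.0, cells_y_hi=44.0,
    )
    p.update(over)
    return _assemble_plinko(
        seed, "plinko_reduced", p, n_cells_each,
        over.get("dt", 5e-3), over.get("n_steps", 25_000),
    )


# ----------------------------------------------------------------------------
# analytic-oracle test channels (continuum-limit checks)
# ----------------------------------------------------------------------------


def build_poiseuille_test(
    seed: int = 0, nx: int = 12, ny: int = 16, fg: float = 1.0, **over
) -> Scenario:
    """Body-force-driven planar channel whose steady profile is parabolic."""
    p = dict(dl=5e-6, rho0=1000.0, mu=0.1)
    p.update(over)
    dl = p["dl"]
    m = p["rho0"] * dl**2
    sc = _build_cell_channel_family(
        seed, "poiseuille_test", nx=nx, ny=ny, fg=(fg, 0.0), with_cell=False,
        dl=dl, fluid_mass=m, rho0=p["rho0"], mu=p["mu"], h=1.3 * dl,
        dt=over.get("dt", 5e-8), n_steps=over.get("n_steps", 800),
    )
    return sc


def build_couette_test(
    seed: int = 0, nx: int = 12, ny: int = 16, v_wall: float = 2e-3, **over
) -> Scenario:
    """Moving-top-wall channel whose steady profile is linear."""
    p = dict(dl=5e-6, rho0=1000.0, mu=0.1)
    p.update(over)
    dl = p["dl"]
    m = p["rho0"] * dl**2
    return _build_cell_channel_family(
        seed, "couette_test", nx=nx, ny=ny, fg=(0.0, 0.0), v_wall=v_wall,
        with_cell=False, dl=dl, fluid_mass=m, rho0=p["rho0"], mu=p["mu"],
        h=1.3 * dl, dt=over.get("dt", 5e-8), n_steps=over.get("n_steps", 800),
    )


def build_conduction_test(
    seed: int = 0, nx: int = 40, ny: int = 4, T0: float = 100.0, **over
) -> Scenario:
    """1D slab, hot interior, cold isothermal walls; transient conduction."""
    p = dict(dl=2.5e-2, rho0=1000.0, kappa=1.0, c_v=1.0)
    p.update(over)
    dl = p["dl"]
    m = p["rho0"] * dl**2
    law = ThermalLaw(
        kappa=p["kappa"], c_v_solid=p["c_v"], c_v_liquid=p["c_v"],
        T_star=1e6, e_sol=p["c_v"] * 1e6, e_liq=p["c_v"] * 1e6,
        kappa_wall=p["kappa"],
    )
    layers = 3
    interior = particle_block(
        _lattice(nx, ny, dl), m, p["rho0"], Phase.FLUID, -1, 0.0,
        temperature=T0, energy=p["c_v"] * T0,
    )
    left = _wall_cols(ny, dl, -layers * dl, layers, 0, m, p["rho0"],
                      temperature=0.0, energy=0.0)
    right = _wall_cols(ny, dl, nx * dl, layers, 0, m, p["rho0"],
                       temperature=0.0, energy=0.0)
    system = ParticleSystem.concatenate([interior, left, right])
    boundary = BoundarySpec(
        lo=(-layers * dl, 0.0), hi=((nx + layers) * dl, ny * dl),
        periodic=(False, True),
    )
    model = Model(
        boundary=boundary, kernel=KernelSpec(1.3 * dl),
        thermal=law, isothermal_walls=True, motion=False,
    )
    config = ScenarioConfig(
        name="conduction_test", dt=over.get("dt", 0.05),
        n_steps=over.get("n_steps", 400), seed=seed,
        params={**p, "T0": T0, "L": nx * dl},
    )
    return Scenario(config, system, BondTopology(), model)


def build_diffusion_test(
    seed: int = 0, nx: int = 40, ny: int = 4, n_res: int = 8, **over
) -> Scenario:
    """Dry half-space in contact with a saturated reservoir; erf profile."""
    p = dict(dl=1e-3, rho0=1000.0, D=1e-6)
    p.update(over)
    dl = p["dl"]
    m = p["rho0"] * dl**2
    reservoir = particle_block(
        _lattice(n_res, ny, dl, origin=(-n_res * dl, 0.0)), m, p["rho0"],
        Phase.FLUID, -1, 0.0, concentration=1.0,
    )
    reservoir.water_mass[:] = reservoir.mass / reservoir.density
    dry = particle_block(
        _lattice(nx, ny, dl), m, p["rho0"], Phase.SOLID, 2, 0.0
    )
    system = ParticleSystem.concatenate([reservoir, dry])
    boundary = BoundarySpec(
        lo=(-(n_res + 1) * dl, 0.0), hi=((nx + 1) * dl, ny * dl),
        periodic=(False, True),
    )
    model = Model(
        boundary=boundary, kernel=KernelSpec(1.3 * dl),
        diffusion=DiffusionLaw(D=p["D"]), motion=False,
    )
    config = ScenarioConfig(
        name="diffusion_test", dt=over.get("dt", 0.1),
        n_steps=over.get("n_steps", 360), seed=seed,
        params={**p, "L": nx * dl},
    )
    return Scenario(config, system, BondTopology(), model)


# ----------------------------------------------------------------------------
# registry / dispatch
# ----------------------------------------------------------------------------

_BUILDERS = {
    "cell_channel": build_cell_channel,
    "cell_obstacle": build_cell_obstacle,
    "cell_aspiration": build_cell_aspiration,
    "cell_shear": build_cell_shear,
    "cell_piercing": build_cell_piercing,
    "cubes_poiseuille": build_cubes_poiseuille,
    "casting_slow": build_casting_slow,
    "casting_slow_reduced": build_casting_slow_reduced,
    "casting_fast": build_casting_fast,
    "casting_fast_reduced": build_casting_fast_reduced,
    "cleaning": build_cleaning,
    "cleaning_reduced": build_cleaning_reduced,
    "lava_incline": build_lava_incline,
    "plinko": build_plinko,
    "plinko_reduced": build_plinko_reduced,
    "poiseuille_test": build_poiseuille_test,
    "couette_test": build_couette_test,
    "conduction_test": build_conduction_test,
    "diffusion_test": build_diffusion_test,
}


def scenario_names() -> list[str]:
    return sorted(_BUILDERS)


def build_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Build a named scenario; overrides adjust counts, steps and parameters."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {scenario_names()}"
        ) from None
    return builder(seed=seed, **overrides)


# ----------------------------------------------------------------------------
# deterministic test fixtures
# ----------------------------------------------------------------------------


def fixture_generator(kind: str, n: int = 16, seed: int = 0, **kw):
    """Small seeded systems exercising one physics family each.

    Kinds: uniform_lattice, random_gas, two_body_collision, bonded_ring,
    hot_slab, dry_soil_strip.  Returns (system, topology, boundary).
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform_lattice":
        side = max(int(round(np.sqrt(n))), 2)
        dl = kw.get("dl", 1.0)
        sys_ = particle_block(
            _lattice(side, side, dl), kw.get("mass", 1.0),
            kw.get("rho", 1.0), Phase.FLUID, -1, 0.5 * dl,
        )
        bnd = BoundarySpec((0.0, 0.0), (side * dl, side * dl), (True, True))
        return sys_, BondTopology(), bnd
    if kind == "random_gas":
        box = kw.get("box", 1.0)
        sys_ = particle_block(
            rng.uniform(0.0, box, size=(n, 2)), 1.0, 1.0, Phase.FLUID, -1, 0.0
        )
        sys_.velocity[:] = rng.normal(0.0, kw.get("v_scale", 1.0), size=(n, 2))
        bnd = BoundarySpec((0.0, 0.0), (box, box), (True, True))
        return sys_, BondTopology(), bnd
    if kind == "two_body_collision":
        speed = kw.get("speed", 1.0)
        gap = kw.get("gap", 1.0)
        radius = kw.get("radius", 0.5)
        sys_ = particle_block(
            np.array([[-0.5 * gap, 0.0], [0.5 * gap, 0.0]]),
            kw.get("mass", 1.0), 1.0, Phase.SOLID, 0, radius,
        )
        sys_.body_id[:] = [0, 1]
        sys_.velocity[:] = [[0.5 * speed, 0.0], [-0.5 * speed, 0.0]]
        bnd = BoundarySpec((-10.0, -10.0), (10.0, 10.0), (False, False))
        return sys_, BondTopology(), bnd
    if kind == "bonded_ring":
        pos, topo = build_membrane(
            n, kw.get("radius", 1.0), kw.get("k_b", 10.0),
            kw.get("r_0", 2.0 * np.sin(np.pi / n)),
            kw.get("r_max", np.inf), kw.get("k_a", 1.0),
        )
        sys_ = particle_block(pos, kw.get("mass", 1.0), 1.0, Phase.SOLID, 0,
                              kw.get("r_0", 0.1) / 2)
        bnd = BoundarySpec((-10.0, -10.0), (10.0, 10.0), (False, False))
        return sys_, topo, bnd
    if kind == "hot_slab":
        sc = build_conduction_test(seed, nx=max(n, 8), ny=2)
        return sc.system, sc.topology, sc.model.boundary
    if kind == "dry_soil_strip":
        sc = build_diffusion_test(seed, nx=max(n, 8), ny=2)
        return sc.system, sc.topology, sc.model.boundary
    raise ValueError(f"unknown fixture kind {kind!r}")
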