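"""Time-stepping driver: integration loop, state machine, observables.

One :class:`Simulation` owns the particle state, bond topology, contact
ledger and material model of a scenario and advances them with velocity
Verlet.  After each step the state machine runs in flowchart order: bond
breakage, phase relabelling, solidification (bond formation), melting,
swelling and the phase/topology consistency audit.  Observables (momentum,
energies, bond counts, per-species centres of mass, density extrema) are
recorded on a fixed cadence; bond and melt events are logged with their step
number so the history is reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dmhs_io
from .cgmd import BondTopology, break_bonds
from .core import (
    ParticleSystem,
    Phase,
    SimulationBlowUp,
    build_neighbor_list,
    velocity_verlet_step,
)
from .dem import ContactLedger
from .forces import Model, Rates, compute_forces
from .thermo import (
    check_phase_topology_consistency,
    energy_to_temperature,
    melt,
    solidify,
    update_phases_from_energy,
)
from .transport import apply_swelling, update_concentration


@dataclass
class ScenarioConfig:
    """Declarative run control for one scenario (physics lives in Model)."""

    name: str
    dt: float
    n_steps: int
    output_every: int = 100
    seed: int = 0
    species: dict = field(default_factory=dict)  # label -> list of body ids
    params: dict = field(default_factory=dict)  # printed physical parameters

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")


class Simulation:
    """Drives one scenario; deterministic given (config, seed)."""

    def __init__(
        self,
        config: ScenarioConfig,
        system: ParticleSystem,
        topology: BondTopology,
        model: Model,
    ) -> None:
        system.validate()
        topology.validate()
        self.config = config
        self.system = system
        self.topology = topology
        self.model = model
        self.ledger = ContactLedger()
        self.step_index = 0
        self.time = 0.0
        self.observables: list[dict] = []
        self.events: dict[str, list] = {
            "bond_break": [],
            "bond_form": [],
            "melt": [],
        }
        n = system.n
        self.solidified_step = np.full(n, -1, dtype=np.int64)
        self.solidified_step[system.phase == int(Phase.SOLID)] = 0
        self.next_body_id = int(system.body_id.max()) + 1 if n else 0
        self.cumulative_surface_heat = 0.0
        self.cumulative_injected_water = 0.0
        # swelling reference state
        self._soil_mask = (system.phase == int(Phase.SOLID)) & (system.radius > 0)
        self._dry_radius = system.radius.copy()
        self._dry_mass = system.mass.copy()
        self._nlist = None
        self._rates: Rates = Rates()
        if model.thermal is not None:
            T, _ = energy_to_temperature(system.internal_energy, model.thermal)
            system.temperature[:] = T
        self._rates = self._evaluate(system)
        self.record()

    # ------------------------------------------------------------------
    def _evaluate(self, system: ParticleSystem) -> Rates:
        self.model.boundary.wrap(system)
        self._nlist = build_neighbor_list(
            system, self.model.cutoff(system), self.model.boundary
        )
        return compute_forces(
            system,
            self._nlist,
            self.topology,
            self.ledger,
            self.model,
            self.config.dt,
        )

    # ------------------------------------------------------------------
    def step(self) -> None:
        system = self.system
        dt = self.config.dt
        if self.model.motion:
            self._rates = velocity_verlet_step(system, dt, self._evaluate)
        else:
            self._rates = self._evaluate(system)

        r = self._rates
        if r.drho is not None:
            system.density += dt * r.drho
        if r.de is not None:
            system.internal_energy += dt * r.de
            self.cumulative_surface_heat += dt * r.surface_flux
        if r.dw is not None:
            system.water_mass += dt * r.dw
            self.cumulative_injected_water += dt * r.injected_water

        thermal = self.model.thermal
        if thermal is not None:
            T, _ = energy_to_temperature(system.internal_energy, thermal)
            wall = system.phase == int(Phase.WALL)
            if self.model.isothermal_walls:
                T[wall] = system.temperature[wall]
            system.temperature[:] = T

        if self.model.diffusion is not None:
            reservoir = (
                np.isin(system.phase, (int(Phase.FLUID), int(Phase.TRANSITION)))
                if self.model.diffusion.reservoir_fluid
                else None
            )
            update_concentration(system, reservoir)
            apply_swelling(
                system, self._soil_mask, self._dry_radius, self._dry_mass,
                self.model.diffusion,
            )

        # ---- state machine (flowchart order) ----
        if self.topology.n_bonds and np.isfinite(self.topology.bond_rmax).any():
            self.topology, broken = break_bonds(system.position, self.topology)
            for pair in broken:
                self.events["bond_break"].append((self.step_index, *pair))

        if thermal is not None and thermal.bond_search_radius > 0.0:
            update_phases_from_energy(system, thermal)
            before_solid = system.phase == int(Phase.SOLID)
            self.topology, formed, self.next_body_id = solidify(
                system, self._nlist, self.topology, thermal, self.next_body_id
            )
            newly = (system.phase == int(Phase.SOLID)) & ~before_solid
            self.solidified_step[newly & (self.solidified_step < 0)] = (
                self.step_index + 1
            )
            for pair in formed:
                self.events["bond_form"].append((self.step_index, *pair))
            self.topology, molten = melt(system, self.topology, thermal)
            for p in molten:
                self.events["melt"].append((self.step_index, p))
            if formed or molten:
                check_phase_topology_consistency(system, self.topology)

        self.step_index += 1
        self.time += dt
        system.check_finite(self.step_index)
        if self.step_index % self.config.output_every == 0:
            self.record()

    # ------------------------------------------------------------------
    def record(self) -> None:
        s = self.system
        mob = s.mobile
        mom = (s.mass[mob, None] * s.velocity[mob]).sum(axis=0)
        ke = 0.5 * float(np.sum(s.mass[mob] * (s.velocity[mob] ** 2).sum(axis=1)))
        rec = {
            "step": self.step_index,
            "time": self.time,
            "momentum_x": float(mom[0]),
            "momentum_y": float(mom[1]),
            "kinetic_energy": ke,
            "thermal_energy": float(np.sum(s.mass[mob] * s.internal_energy[mob])),
            "water_total": float(np.sum(s.water_mass[mob])),
            "bond_count": self.topology.n_bonds,
            "solid_count": int(np.sum(s.phase == int(Phase.SOLID))),
            "surface_heat": self.cumulative_surface_heat,
        }
        fluidish = np.isin(s.phase, (int(Phase.FLUID), int(Phase.TRANSITION)))
        if fluidish.any():
            rec["density_min"] = float(s.density[fluidish].min())
            rec["density_max"] = float(s.density[fluidish].max())
        for label, bodies in self.config.species.items():
            mask = np.isin(s.body_id, bodies)
            if mask.any():
                com = np.average(s.position[mask], axis=0, weights=s.mass[mask])
                rec[f"x_com_{label}"] = float(com[0])
                rec[f"y_com_{label}"] = float(com[1])
        self.observables.append(rec)

    # ------------------------------------------------------------------
    def run(
        self,
        n_steps: int | None = None,
        out_dir: str | Path | None = None,
        frame_every: int | None = None,
        frame_format: str = "xyz",
    ) -> dict:
        """Advance n_steps (default: config.n_steps); optionally write frames.

        On blow-up the last valid frame is flushed before the error
        propagates.  Returns a summary of conservation audits and counts.
        """
        n = self.config.n_steps if n_steps is None else n_steps
        out = Path(out_dir) if out_dir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            self._write_frame(out, frame_format)
        try:
            for _ in range(n):
                self.step()
                if (
                    out is not None
                    and frame_every
                    and self.step_index % frame_every == 0
                ):
                    self._write_frame(out, frame_format)
        except SimulationBlowUp:
            if out is not None:
                self._write_frame(out, frame_format, suffix="last_valid")
            raise
        if out is not None:
            self._write_frame(out, frame_format)
            dmhs_io.write_observables(out / "observables.csv", self.observables)
            dmhs_io.write_events(out / "events.csv", self.events)
            dmhs_io.write_bond_table(
                out / f"bonds_{self.step_index:08d}.txt", self.topology
            )
        return self.summary()

    def _write_frame(self, out: Path, fmt: str, suffix: str | None = None) -> None:
        tag = suffix if suffix is not None else f"{self.step_index:08d}"
        ext = {"xyz": "xyz", "vtk": "vtk", "csv": "csv"}[fmt]
        dmhs_io.write_frame(
            self.system,
            self.topology,
            out / f"frame_{tag}.{ext}",
            fmt,
            time=self.time,
            seed=self.config.seed,
        )

    def summary(self) -> dict:
        s = self.system
        return {
            "name": self.config.name,
            "steps": self.step_index,
            "time": self.time,
            "n_particles": s.n,
            "bond_count": self.topology.n_bonds,
            "solid_count": int(np.sum(s.phase == int(Phase.SOLID))),
            "bond_breaks": len(self.events["bond_break"]),
            "bonds_formed": len(self.events["bond_form"]),
            "melt_events": len(self.events["melt"]),
            "surface_heat": self.cumulative_surface_heat,
            "injected_water": self.cumulative_injected_water,
        }
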