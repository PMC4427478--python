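"""Chassis tests: neighbor search, integration, boundaries, dispatch."""

import numpy as np
import pytest

from dmhs.core import (
    BoundarySpec,
    ParticleSystem,
    Phase,
    SimulationBlowUp,
    apply_external_forces,
    brute_force_pairs,
    build_neighbor_list,
    coordination_numbers,
    velocity_verlet_step,
)
from dmhs.forces import Model, compute_forces
from dmhs.cgmd import BondTopology
from dmhs.dem import ContactLaw, ContactLedger
from dmhs.sph import FluidLaw, KernelSpec
from helpers import make_pair


class TestNeighborList:
    @pytest.mark.parametrize("factor,expected", [(0.9, 1), (1.1, 0)])
    def test_cutoff_definition(self, factor, expected):
        system = make_pair(factor * 1.0)
        nl = build_neighbor_list(system, cutoff=1.0)
        assert nl.n_pairs == expected

    def test_matches_brute_force_on_random_configs(self):
        """Tree-based search equals the O(N^2) oracle, with and without
        periodic axes, over 100 random configurations."""
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = int(rng.integers(2, 60))
            box = rng.uniform(1.0, 3.0)
            periodic = (bool(rng.integers(2)), bool(rng.integers(2)))
            boundary = BoundarySpec((0.0, 0.0), (box, box), periodic)
            system = ParticleSystem.empty(n)
            system.position[:] = rng.uniform(0.0, box, size=(n, 2))
            cutoff = rng.uniform(0.1, 0.6) * box / 2.0
            nl = build_neighbor_list(system, cutoff, boundary)
            got = {(int(a), int(b)) for a, b in zip(nl.i, nl.j)}
            want = brute_force_pairs(system, cutoff, boundary)
            assert got == want

    def test_minimum_image_distance(self):
        boundary = BoundarySpec((0.0, 0.0), (10.0, 10.0), (True, False))
        system = make_pair(0.0)
        system.position[:] = [[0.3, 5.0], [9.8, 5.0]]
        nl = build_neighbor_list(system, 1.0, boundary)
        assert nl.n_pairs == 1
        assert nl.dist[0] == pytest.approx(0.5)

    def test_rejects_nonfinite_position(self):
        system = make_pair(1.0)
        system.position[1, 0] = np.nan
        with pytest.raises(SimulationBlowUp, match="particle 1"):
            build_neighbor_list(system, 1.0)

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            build_neighbor_list(make_pair(1.0), 0.0)

    def test_coordination_counts(self):
        system = ParticleSystem.empty(3)
        system.position[:] = [[0.0, 0.0], [0.5, 0.0], [5.0, 0.0]]
        nl = build_neighbor_list(system, 1.0)
        coord = coordination_numbers(nl, 3, 1.0)
        assert list(coord) == [1, 1, 0]


class TestIntegration:
    def test_constant_force_kinematics(self):
        """Velocity Verlet reproduces x = F t^2 / (2m) for constant force."""
        system = ParticleSystem.empty(1)
        system.mass[:] = 2.0
        force = np.array([0.4, -0.2])

        def ev(s):
            s.force[:] = force

        ev(system)
        dt, n = 1e-3, 1000
        for _ in range(n):
            velocity_verlet_step(system, dt, ev)
        t = n * dt
        expected = 0.5 * force / 2.0 * t**2
        np.testing.assert_allclose(system.position[0], expected, rtol=1e-12)

    def test_zero_force_uniform_translation_exact(self):
        system = ParticleSystem.empty(1)
        system.velocity[:] = [1.5, -0.5]

        def ev(s):
            s.force[:] = 0.0

        ev(system)
        for _ in range(100):
            velocity_verlet_step(system, 0.25, ev)
        np.testing.assert_array_equal(system.position[0], [37.5, -12.5])

    def test_wall_particles_keep_prescribed_velocity(self):
        system = ParticleSystem.empty(2)
        system.phase[:] = [int(Phase.WALL), int(Phase.FLUID)]
        system.body_id[0] = 0
        system.velocity[0] = [2.0, 0.0]

        def ev(s):
            s.force[:] = [[5.0, 5.0], [0.0, 0.0]]

        ev(system)
        velocity_verlet_step(system, 0.1, ev)
        np.testing.assert_array_equal(system.velocity[0], [2.0, 0.0])
        np.testing.assert_allclose(system.position[0], [0.2, 0.0])

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            velocity_verlet_step(ParticleSystem.empty(1), 0.0, lambda s: None)

    def test_oscillator_energy_bounded_nonsecular(self):
        """Symplectic contract: bonded-pair energy error stays bounded and
        shows no trend over 1e5 steps at dt = T/1000."""
        from dmhs.cgmd import bond_forces, bond_energy

        topo = BondTopology()
        topo.add_bonds([[0, 1]], 10.0, 1.0)
        system = make_pair(1.1)
        system.mass[:] = 1.0
        T = 2.0 * np.pi * np.sqrt(0.5 / 20.0)
        dt = T / 1000.0

        def ev(s):
            s.force[:] = 0.0
            bond_forces(s.position, topo, s.force)

        def energy(s):
            ke = 0.5 * float(np.sum(s.mass * (s.velocity**2).sum(axis=1)))
            return ke + bond_energy(s.position, topo)

        ev(system)
        e0 = energy(system)
        samples = []
        for step in range(100_000):
            velocity_verlet_step(system, dt, ev)
            if step % 1000 == 0:
                samples.append(energy(system))
        samples = np.array(samples)
        assert np.max(np.abs(samples - e0) / e0) < 5e-4  # bounded
        first, last = samples[:10].mean(), samples[-10:].mean()
        assert abs(last - first) / e0 < 5e-5  # non-secular


class TestExternalForces:
    def test_body_force_adds_mass_times_acceleration(self):
        system = make_pair(1.0)
        system.mass[:] = 2.5e-8
        apply_external_forces(system, np.array([1.0, 0.0]))
        np.testing.assert_allclose(system.force[:, 0], 2.5e-8)

    def test_zero_body_force_noop(self):
        system = make_pair(1.0)
        apply_external_forces(system, np.zeros(2))
        assert np.all(system.force == 0.0)

    def test_net_force_on_bonded_body(self):
        system = ParticleSystem.empty(16)
        system.mass[:] = 3.0
        apply_external_forces(system, np.array([0.0, -100.0]))
        assert system.force[:, 1].sum() == pytest.approx(-16 * 3.0 * 100.0)

    def test_walls_excluded(self):
        system = make_pair(1.0)
        system.phase[0] = int(Phase.WALL)
        system.body_id[0] = 0
        apply_external_forces(system, np.array([1.0, 0.0]))
        assert system.force[0, 0] == 0.0
        assert system.force[1, 0] > 0.0


class TestDispatch:
    def _model(self, boundary, **kw):
        return Model(
            boundary=boundary,
            kernel=KernelSpec(1.3),
            fluid=FluidLaw(1.0, 10.0, 0.1),
            **kw,
        )

    def test_fluid_pair_gets_sph_only(self, open_box):
        """A solid body outside every interaction range does not perturb the
        SPH force on a fluid pair."""
        from dmhs.sph import tait_pressure

        def build(with_solid):
            n = 3 if with_solid else 2
            s = ParticleSystem.empty(n)
            s.position[:2] = [[0.0, 0.0], [1.0, 0.0]]
            s.density[:2] = 1.05
            if with_solid:
                s.position[2] = [0.5, 20.0]
                s.phase[2] = int(Phase.SOLID)
                s.body_id[2] = 5
                s.radius[2] = 0.5
            return s

        law = ContactLaw(10.0)
        forces = []
        for with_solid in (False, True):
            s = build(with_solid)
            nl = build_neighbor_list(s, 3.0, open_box)
            model = self._model(open_box, contact=law)
            compute_forces(s, nl, BondTopology(), ContactLedger(), model, 1e-3)
            forces.append(s.force[:2].copy())
        np.testing.assert_array_equal(forces[0], forces[1])
        assert np.abs(forces[0]).max() > 0.0  # pressure force present

    def test_same_body_solid_pair_gets_no_dem(self, open_box):
        s = make_pair(0.8, radius=0.5)  # overlapping circles
        s.phase[:] = int(Phase.SOLID)
        s.body_id[:] = 3
        nl = build_neighbor_list(s, 3.0, open_box)
        model = Model(boundary=open_box, contact=ContactLaw(100.0))
        compute_forces(s, nl, BondTopology(), ContactLedger(), model, 1e-3)
        assert np.all(s.force == 0.0)

    def test_different_body_solid_pair_gets_dem(self, open_box):
        s = make_pair(0.8, radius=0.5)
        s.phase[:] = int(Phase.SOLID)
        s.body_id[:] = [3, 4]
        nl = build_neighbor_list(s, 3.0, open_box)
        model = Model(boundary=open_box, contact=ContactLaw(100.0))
        compute_forces(s, nl, BondTopology(), ContactLedger(), model, 1e-3)
        assert s.force[0, 0] < 0.0 < s.force[1, 0]  # repulsive pair

    def test_unknown_phase_hard_error(self, open_box):
        s = make_pair(1.0)
        s.phase[0] = 7
        nl = build_neighbor_list(s, 3.0, open_box)
        with pytest.raises(ValueError, match="unknown phase"):
            compute_forces(
                s, nl, BondTopology(), ContactLedger(), self._model(open_box),
                1e-3,
            )

    def test_all_fluid_periodic_box_net_force_zero(self, random_gas):
        system, topology, boundary = random_gas
        system.density[:] = 1.0 + 0.01 * np.sin(system.position[:, 0])
        nl = build_neighbor_list(system, 2.6, boundary)
        model = self._model(boundary)
        compute_forces(system, nl, topology, ContactLedger(), model, 1e-3)
        total = system.force.sum(axis=0)
        scale = np.abs(system.force).sum() + 1e-300
        assert np.abs(total).max() / scale < 1e-12


class TestBoundarySpec:
    def test_wrap_periodic_axis_only(self):
        boundary = BoundarySpec((0.0, 0.0), (4.0, 4.0), (True, False))
        s = make_pair(0.0)
        s.position[:] = [[4.5, 4.5], [-0.5, -0.5]]
        boundary.wrap(s)
        np.testing.assert_allclose(s.position[:, 0], [0.5, 3.5])
        np.testing.assert_allclose(s.position[:, 1], [4.5, -0.5])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            BoundarySpec((0.0, 0.0), (0.0, 1.0))
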