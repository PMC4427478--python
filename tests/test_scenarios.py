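"""Scenario builder, runner, I/O and CLI tests."""

import numpy as np
import pytest
from click.testing import CliRunner

from dmhs import io as dmhs_io
from dmhs import scenarios
from dmhs.cli import main
from dmhs.core import ParticleSystem, Phase, SimulationBlowUp


class TestBuilders:
    def test_cell_channel_published_counts(self):
        """2048 carrier fluid + 48 membrane + 61 cytoplasm particles."""
        sc = scenarios.build_scenario("cell_channel")
        s = sc.system
        carrier = int(np.sum((s.phase == int(Phase.FLUID)) & (s.body_id == -1)))
        membrane = int(np.sum(s.phase == int(Phase.SOLID)))
        assert carrier == 2048 + 61
        assert membrane == 48
        assert sc.topology.n_bonds == 48
        assert sc.topology.n_angles == 48

    def test_cell_channel_membrane_geometry(self):
        sc = scenarios.build_scenario("cell_channel")
        p = sc.config.params
        # ring radius follows from 48 bonds of rest length 3.3e-6
        assert 48 * p["r_0"] / (2 * np.pi) == pytest.approx(2.52e-5, rel=1e-2)
        assert p["theta0_deg"] == 172.5

    def test_cubes_are_49_elemental_particles(self):
        sc = scenarios.build_scenario("cubes_poiseuille", n_cubes=2)
        s = sc.system
        for body in (2, 3):
            assert int(np.sum(s.body_id == body)) == 49

    def test_cubes_variants(self):
        heavy = scenarios.build_scenario("cubes_poiseuille", variant="heavy",
                                         n_cubes=1)
        assert heavy.config.params["rho_solid"] == 1500.0
        assert np.isfinite(heavy.topology.bond_rmax).all()
        # brittle reading: 0.1% allowed strain
        strain = heavy.topology.bond_rmax / heavy.topology.bond_r0 - 1.0
        np.testing.assert_allclose(strain, 1e-3)
        neutral = scenarios.build_scenario("cubes_poiseuille", n_cubes=1)
        assert np.isinf(neutral.topology.bond_rmax).all()
        with pytest.raises(ValueError):
            scenarios.build_scenario("cubes_poiseuille", variant="bogus")

    def test_plinko_species_differ_only_in_bending_stiffness(self):
        sc = scenarios.build_scenario("plinko", n_cells_each=2)
        s = sc.system
        topo = sc.topology
        flex = sc.config.species["flexible"]
        rigid = sc.config.species["rigid"]
        assert len(flex) == len(rigid) == 2
        k_by_body = {}
        for (a, j, c), k in zip(topo.angles, topo.angle_k):
            k_by_body.setdefault(int(s.body_id[j]), set()).add(float(k))
        for b in flex:
            assert k_by_body[b] == {1e-16}
        for b in rigid:
            assert k_by_body[b] == {1e-15}
        # same bond stiffness, mass and radius for both species
        for b in flex + rigid:
            beads = s.body_id == b
            assert np.allclose(s.mass[beads], s.mass[s.body_id == flex[0]][0])

    def test_casting_thermal_constants(self):
        sc = scenarios.build_scenario("casting_slow")
        law = sc.model.thermal
        assert (law.e_sol, law.e_liq) == (50.0, 100.0)
        assert (law.c_v_solid, law.c_v_liquid) == (2.0, 1.0)
        assert law.kappa_wall == 100.0
        assert law.k_T == 0.02
        fast = scenarios.build_scenario("casting_fast")
        assert fast.model.thermal.e_sol == fast.model.thermal.e_liq  # no latent

    def test_lava_blends_over_transition_range(self):
        sc = scenarios.build_scenario("lava_incline")
        assert sc.model.blending
        assert sc.model.thermal.blend_T_range == (500.0, 1000.0)
        assert not sc.model.wall_conduction

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenarios.build_scenario("nope")

    def test_every_scenario_builds_and_validates(self):
        for name in scenarios.scenario_names():
            sc = scenarios.build_scenario(name, seed=3)
            sc.system.validate()
            sc.topology.validate()


class TestDeterminism:
    def test_same_seed_same_build(self):
        a = scenarios.build_scenario("plinko_reduced", seed=5, n_cells_each=2)
        b = scenarios.build_scenario("plinko_reduced", seed=5, n_cells_each=2)
        np.testing.assert_array_equal(a.system.position, b.system.position)

    def test_different_seed_different_placement(self):
        a = scenarios.build_scenario("plinko_reduced", seed=5, n_cells_each=2)
        b = scenarios.build_scenario("plinko_reduced", seed=6, n_cells_each=2)
        assert not np.array_equal(a.system.position, b.system.position)

    def test_same_run_is_bitwise_reproducible(self):
        states = []
        for _ in range(2):
            sc = scenarios.build_scenario("cleaning_reduced", seed=2,
                                          n_steps=50)
            sim = sc.simulation()
            for _ in range(50):
                sim.step()
            states.append(sim.system.position.copy())
        np.testing.assert_array_equal(states[0], states[1])

    def test_fixture_generator_deterministic(self):
        a, _, _ = scenarios.fixture_generator("random_gas", n=20, seed=9)
        b, _, _ = scenarios.fixture_generator("random_gas", n=20, seed=9)
        np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(a.velocity, b.velocity)

    def test_two_body_fixture_closing_speed(self):
        s, _, _ = scenarios.fixture_generator(
            "two_body_collision", speed=2.5, gap=3.0
        )
        assert s.n == 2
        closing = float(s.velocity[0, 0] - s.velocity[1, 0])
        assert closing == pytest.approx(2.5)

    def test_bonded_ring_fixture_delegates_to_membrane(self):
        s, topo, _ = scenarios.fixture_generator("bonded_ring", n=48)
        assert s.n == 48 and topo.n_bonds == 48


class TestSmokeRuns:
    def test_weak_compressibility_contract(self):
        """Max |rho - rho0|/rho0 < 1% during smoke runs of every shipped
        scenario (sound speed from the 10x rule)."""
        devs = benchmark_density()
        for name, dev in devs.items():
            assert dev < 1.0, f"{name}: {dev}%"

    def test_blowup_flushes_and_raises(self, tmp_path):
        sc = scenarios.build_scenario("conduction_test", n_steps=5)
        sim = sc.simulation()
        sim.system.internal_energy[0] = np.nan
        with pytest.raises(SimulationBlowUp):
            sim.run(out_dir=tmp_path)
        assert (tmp_path / "frame_last_valid.xyz").exists()


def benchmark_density():
    from dmhs import benchmarks

    return benchmarks.density_contract(seed=0)


class TestIO:
    def _system(self):
        sc = scenarios.build_scenario("conduction_test", nx=4, ny=2)
        return sc.system, sc.topology

    def test_xyz_round_trip_full_precision(self, tmp_path):
        system, topo = self._system()
        system.velocity[:] = np.random.default_rng(0).normal(
            size=(system.n, 2)
        )
        path = dmhs_io.write_frame(system, topo, tmp_path / "f.xyz", "xyz",
                                   time=1.25, seed=7)
        back = dmhs_io.read_xyz(path)
        for name in ("position", "velocity", "mass", "density", "temperature",
                     "internal_energy", "phase", "body_id"):
            np.testing.assert_array_equal(getattr(back, name),
                                          getattr(system, name))

    def test_vtk_header_conformance(self, tmp_path):
        system, topo = self._system()
        path = dmhs_io.write_frame(system, topo, tmp_path / "f.vtk", "vtk")
        lines = path.read_text().splitlines()
        assert lines[0] == "# vtk DataFile Version 3.0"
        assert lines[2] == "ASCII"
        assert lines[3] == "DATASET POLYDATA"
        assert lines[4] == f"POINTS {system.n} double"
        assert f"POINT_DATA {system.n}" in lines

    def test_empty_system_writes_valid_file(self, tmp_path):
        empty = ParticleSystem.empty(0)
        path = dmhs_io.write_frame(empty, None, tmp_path / "e.xyz", "xyz")
        assert path.read_text().startswith("0\n")
        back = dmhs_io.read_xyz(path)
        assert back.n == 0

    def test_bond_table_records_parameters(self, tmp_path):
        _, topo = self._system()
        from dmhs.cgmd import BondTopology

        topo = BondTopology()
        topo.add_bonds([[0, 1]], 10.0, 1.5, 2.0)
        topo.add_angles([[0, 1, 2]], 3.0, 1.0)
        path = dmhs_io.write_bond_table(tmp_path / "b.txt", topo)
        text = path.read_text()
        assert "bond 0 1 10 1.5 2" in text
        assert "angle 0 1 2 3 1" in text

    def test_observables_csv(self, tmp_path):
        sc = scenarios.build_scenario("conduction_test", n_steps=3)
        sim = sc.simulation()
        summary = sim.run(out_dir=tmp_path)
        text = (tmp_path / "observables.csv").read_text()
        assert "thermal_energy" in text.splitlines()[0]
        assert summary["steps"] == 3


class TestCLI:
    def test_list_names_scenarios(self):
        result = CliRunner().invoke(main, ["list"])
        assert result.exit_code == 0
        assert "cell_channel" in result.output
        assert "plinko" in result.output

    def test_validate_good_scenario(self):
        result = CliRunner().invoke(main, ["validate", "conduction_test"])
        assert result.exit_code == 0
        assert "OK" in result.output

    def test_validate_bad_scenario_exit_code(self):
        result = CliRunner().invoke(main, ["validate", "not_a_scenario"])
        assert result.exit_code == 2

    def test_run_writes_outputs(self, tmp_path):
        result = CliRunner().invoke(
            main,
            ["run", "conduction_test", "--steps", "3", "--out",
             str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "observables.csv").exists()

    def test_fixtures_command(self, tmp_path):
        out = tmp_path / "fix.xyz"
        result = CliRunner().invoke(
            main, ["fixtures", "bonded_ring", "--n", "12", "--out", str(out)]
        )
        assert result.exit_code == 0
        assert out.exists()
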