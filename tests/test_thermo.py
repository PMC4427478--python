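"""Thermal tests: caloric EOS, conduction, Newton cooling, phase machine."""

import numpy as np
import pytest

from dmhs import benchmarks, scenarios
from dmhs.cgmd import BondTopology
from dmhs.core import BoundarySpec, ParticleSystem, Phase, build_neighbor_list
from dmhs.sph import KernelSpec
from dmhs.thermo import (
    ThermalLaw,
    blend_weights,
    check_phase_topology_consistency,
    energy_to_temperature,
    heat_conduction_rhs,
    melt,
    solidify,
    surface_cooling_rhs,
    temperature_to_energy,
    update_phases_from_energy,
)


@pytest.fixture(scope="module")
def casting_law():
    # solid heat capacity 2, liquid 1, transition at 25 C with a latent
    # plateau between e = 50 and e = 100 J/kg
    return ThermalLaw(
        kappa=1.0, c_v_solid=2.0, c_v_liquid=1.0, T_star=25.0,
        e_sol=50.0, e_liq=100.0, k_T=0.02, T_air=0.0,
        bond_search_radius=1.0, bond_k=1e5, bond_r0=1.0,
    )


class TestCaloricEOS:
    @pytest.mark.parametrize(
        "e,T,frac",
        [
            (40.0, 20.0, 0.0),   # solid branch: T = e / c_vS
            (75.0, 25.0, 0.5),   # plateau: T pinned at T*, half molten
            (120.0, 45.0, 1.0),  # liquid branch: T = (e - e_liq)/c_vL + T*
            (50.0, 25.0, 0.0),   # solidus endpoint
            (100.0, 25.0, 1.0),  # liquidus endpoint
        ],
    )
    def test_branches(self, casting_law, e, T, frac):
        temp, lam = energy_to_temperature(e, casting_law)
        assert temp == pytest.approx(T)
        assert lam == pytest.approx(frac)

    def test_continuous_and_monotone(self, casting_law):
        e = np.linspace(-50.0, 300.0, 2000)
        T, lam = energy_to_temperature(e, casting_law)
        assert np.all(np.diff(T) >= 0.0)
        assert np.all(np.diff(lam) >= 0.0)
        assert np.max(np.abs(np.diff(T))) < 0.5  # no jumps

    def test_round_trip_off_plateau(self, casting_law):
        """e -> T -> e is the identity outside [e_sol, e_liq]."""
        e = np.concatenate([np.linspace(-40.0, 49.9, 40),
                            np.linspace(100.1, 400.0, 40)])
        T, _ = energy_to_temperature(e, casting_law)
        np.testing.assert_allclose(temperature_to_energy(T, casting_law), e,
                                   rtol=1e-12)

    def test_collapsed_plateau_degenerates_gracefully(self):
        law = ThermalLaw(
            kappa=1.0, c_v_solid=1.0, c_v_liquid=1.0, T_star=500.0,
            e_sol=500.0, e_liq=500.0,
        )
        T, lam = energy_to_temperature(np.array([400.0, 600.0]), law)
        np.testing.assert_allclose(T, [400.0, 600.0])
        np.testing.assert_allclose(lam, [0.0, 1.0])

    def test_solidus_continuity_enforced(self):
        with pytest.raises(ValueError, match="solidus"):
            ThermalLaw(kappa=1.0, c_v_solid=2.0, c_v_liquid=1.0,
                       T_star=25.0, e_sol=60.0, e_liq=100.0)


class TestConduction:
    def _slab(self):
        sc = scenarios.build_scenario("conduction_test", seed=0)
        return sc

    def test_uniform_temperature_gives_zero_exactly(self):
        sc = self._slab()
        s = sc.system
        s.temperature[:] = 42.0
        nl = build_neighbor_list(s, sc.model.kernel.support, sc.model.boundary)
        de = heat_conduction_rhs(s, nl, sc.model.kernel, np.ones(s.n))
        assert np.all(de == 0.0)

    def test_heat_flows_from_hot_to_cold(self):
        s = ParticleSystem.empty(2)
        s.position[:] = [[0.0, 0.0], [1.0, 0.0]]
        s.temperature[:] = [100.0, 0.0]
        spec = KernelSpec(1.0)
        nl = build_neighbor_list(s, spec.support)
        de = heat_conduction_rhs(s, nl, spec, np.ones(2))
        assert de[0] < 0.0 < de[1]

    def test_closed_system_conserves_thermal_energy(self):
        """Sum m_i e_i drifts only at round-off under pure conduction."""
        assert benchmarks.thermal_energy_drift(n_steps=400) < 1e-12

    def test_transient_slab_matches_fourier_series(self):
        """1D slab with cold isothermal walls vs the analytic series, L2
        error under 2%."""
        assert benchmarks.conduction_error() < 0.02


class TestSurfaceCooling:
    def test_interior_particle_unaffected(self, casting_law):
        s = ParticleSystem.empty(2)
        s.temperature[:] = 100.0
        s.internal_energy[:] = 175.0
        coord = np.array([8, 3])
        de = surface_cooling_rhs(s, coord, casting_law)
        assert de[0] == 0.0
        assert de[1] < 0.0

    def test_at_air_temperature_no_cooling(self, casting_law):
        s = ParticleSystem.empty(1)
        s.temperature[:] = casting_law.T_air
        de = surface_cooling_rhs(s, np.zeros(1), casting_law)
        assert de[0] == 0.0

    def test_exponential_decay_closed_form(self):
        """Isolated particle at T0=100 with k_T=0.02/s: T(50 s) = 100/e,
        within 0.1%."""
        assert benchmarks.newton_cooling_error() < 1e-3

    def test_walls_never_cool(self, casting_law):
        s = ParticleSystem.empty(1)
        s.phase[:] = int(Phase.WALL)
        s.body_id[:] = 0
        s.temperature[:] = 100.0
        de = surface_cooling_rhs(s, np.zeros(1), casting_law)
        assert de[0] == 0.0


class TestPhaseMachine:
    def _pair_system(self, energies, dist=0.9):
        s = ParticleSystem.empty(len(energies))
        s.position[:, 0] = np.arange(len(energies)) * dist
        s.internal_energy[:] = energies
        return s

    def test_no_crossing_no_change(self, casting_law):
        s = self._pair_system([120.0, 130.0])
        nl = build_neighbor_list(s, 1.0)
        topo, formed, nxt = solidify(s, nl, BondTopology(), casting_law, 10)
        assert formed == [] and topo.n_bonds == 0 and nxt == 10

    def test_successive_solidification_forms_exactly_one_bond(self, casting_law):
        """Two adjacent particles crossing e_sol on successive passes bond
        once; the earlier solid cannot initiate, the newcomer can."""
        s = self._pair_system([40.0, 120.0])
        nl = build_neighbor_list(s, 1.0)
        topo, formed, nxt = solidify(s, nl, BondTopology(), casting_law, 10)
        assert formed == [] and s.phase[0] == int(Phase.SOLID)
        s.internal_energy[1] = 45.0  # second particle crosses later
        topo, formed, nxt = solidify(s, nl, topo, casting_law, nxt)
        assert formed == [(0, 1)]
        assert topo.n_bonds == 1
        # re-running never duplicates the bond
        topo, formed, _ = solidify(s, nl, topo, casting_law, nxt)
        assert formed == [] and topo.n_bonds == 1

    def test_same_step_cohort_bonds_pairwise(self, casting_law):
        s = self._pair_system([40.0, 45.0, 42.0])
        nl = build_neighbor_list(s, 1.0)
        topo, formed, _ = solidify(s, nl, BondTopology(), casting_law, 10)
        assert set(formed) == {(0, 1), (1, 2)}  # only pairs within radius

    def test_cold_patch_bond_graph_is_connected(self, casting_law):
        """A 3x3 patch solidifying inward over a scripted schedule (rim
        first, centre last) ends as one connected bonded cluster."""
        s = ParticleSystem.empty(9)
        ix, iy = np.meshgrid(range(3), range(3), indexing="ij")
        s.position[:, 0] = ix.ravel() * 0.9
        s.position[:, 1] = iy.ravel() * 0.9
        s.internal_energy[:] = 120.0
        nl = build_neighbor_list(s, 1.0)
        topo = BondTopology()
        nxt = 10
        center = 4  # index of the middle site
        rim = [k for k in range(9) if k != center]
        for cohort in (rim[:4], rim[4:], [center]):
            s.internal_energy[cohort] = 40.0
            topo, _, nxt = solidify(s, nl, topo, casting_law, nxt)
        assert np.all(s.phase == int(Phase.SOLID))
        # breadth-first search over the bond graph
        adj = {k: set() for k in range(9)}
        for a, b in topo.bonds:
            adj[int(a)].add(int(b))
            adj[int(b)].add(int(a))
        seen, frontier = {0}, [0]
        while frontier:
            nxt_frontier = []
            for node in frontier:
                for other in adj[node] - seen:
                    seen.add(other)
                    nxt_frontier.append(other)
            frontier = nxt_frontier
        assert seen == set(range(9))

    def test_melt_removes_exactly_incident_bonds(self, casting_law):
        s = self._pair_system([40.0, 41.0, 42.0])
        nl = build_neighbor_list(s, 1.0)
        topo, formed, _ = solidify(s, nl, BondTopology(), casting_law, 10)
        assert topo.n_bonds == 2
        s.internal_energy[1] = 150.0  # interior particle re-melts
        topo, molten = melt(s, topo, casting_law)
        assert molten == [1]
        assert topo.n_bonds == 0  # both bonds referenced particle 1
        assert s.phase[1] == int(Phase.FLUID)
        assert s.phase[0] == int(Phase.SOLID) == s.phase[2]
        check_phase_topology_consistency(s, topo)

    def test_full_melt_leaves_no_bonds(self, casting_law):
        s = self._pair_system([40.0, 41.0, 42.0])
        nl = build_neighbor_list(s, 1.0)
        topo, _, _ = solidify(s, nl, BondTopology(), casting_law, 10)
        s.internal_energy[:] = 200.0
        topo, molten = melt(s, topo, casting_law)
        assert topo.n_bonds == 0
        assert np.all(s.phase == int(Phase.FLUID))

    def test_consistency_check_catches_fluid_in_bond(self, casting_law):
        s = self._pair_system([40.0, 41.0])
        nl = build_neighbor_list(s, 1.0)
        topo, _, _ = solidify(s, nl, BondTopology(), casting_law, 10)
        s.phase[0] = int(Phase.FLUID)  # corrupt the state on purpose
        with pytest.raises(AssertionError):
            check_phase_topology_consistency(s, topo)

    def test_transition_label_tracks_plateau(self, casting_law):
        s = self._pair_system([75.0, 120.0])
        update_phases_from_energy(s, casting_law)
        assert s.phase[0] == int(Phase.TRANSITION)
        assert s.phase[1] == int(Phase.FLUID)

    def test_casting_solidifies_wall_first(self):
        """Reduced mould casting: first-solidification time rank-correlates
        with distance from the wall (> 0.8)."""
        assert benchmarks.casting_rank_correlation() > 0.8


class TestBlending:
    def test_endpoint_weights(self, casting_law):
        s = ParticleSystem.empty(3)
        s.internal_energy[:] = [120.0, 75.0, 40.0]
        s.phase[:] = [int(Phase.FLUID), int(Phase.TRANSITION), int(Phase.SOLID)]
        s.body_id[2] = 1
        lam = blend_weights(s, casting_law)
        np.testing.assert_allclose(lam, [1.0, 0.5, 0.0])

    def test_temperature_ramp_range(self):
        law = ThermalLaw(
            kappa=1.0, c_v_solid=1.0, c_v_liquid=1.0, T_star=500.0,
            e_sol=500.0, e_liq=500.0, blend_T_range=(500.0, 1000.0),
        )
        s = ParticleSystem.empty(3)
        s.temperature[:] = [1100.0, 750.0, 400.0]
        s.internal_energy[:] = s.temperature
        lam = blend_weights(s, law)
        np.testing.assert_allclose(lam, [1.0, 0.5, 0.0])

    def test_pair_force_is_convex_mix(self, casting_law):
        """lambda = 1 reproduces the pure SPH pair force, lambda = 0 the
        pure DEM force, lambda = 0.5 their mean."""
        from dmhs.cgmd import BondTopology
        from dmhs.dem import ContactLaw, ContactLedger
        from dmhs.forces import Model, compute_forces
        from dmhs.sph import FluidLaw

        boundary = BoundarySpec((-10.0, -10.0), (10.0, 10.0))

        def force_for(e_pair):
            s = ParticleSystem.empty(2)
            s.position[:] = [[0.0, 0.0], [0.8, 0.0]]
            s.radius[:] = 0.5
            s.density[:] = 1.05
            s.internal_energy[:] = e_pair
            s.temperature[:] = energy_to_temperature(
                np.full(2, e_pair), casting_law
            )[0]
            update_phases_from_energy(s, casting_law)
            if e_pair < casting_law.e_sol:
                s.phase[:] = int(Phase.SOLID)
                s.body_id[:] = [5, 6]
            model = Model(
                boundary=boundary,
                kernel=KernelSpec(1.0),
                fluid=FluidLaw(1.0, 10.0, 0.1, viscosity="monaghan"),
                contact=ContactLaw(100.0),
                thermal=casting_law,
                blending=True,
            )
            nl = build_neighbor_list(s, 3.0, boundary)
            compute_forces(s, nl, BondTopology(), ContactLedger(), model, 1e-3)
            return s.force[0, 0]

        f_liquid = force_for(150.0)   # lambda = 1: pure SPH
        f_solid = force_for(40.0)     # lambda = 0: pure DEM
        f_mid = force_for(75.0)       # lambda = 0.5 on the plateau
        assert f_mid == pytest.approx(0.5 * (f_liquid + f_solid), rel=1e-9)
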