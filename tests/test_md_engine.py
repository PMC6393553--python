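"""Engine mechanics: neighbor search, integration, thermostat, builders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sidm import (ForceField, ParticleSystem, Simulation, Topology,
                  build_cell_list, compute_forces, create_slab_system,
                  insert_copolymers_by_identity_swap, kinetic_temperature,
                  maxwell_velocities, pressure_tensor,
                  surface_tension_kirkwood_buff, thermostat_step,
                  velocity_verlet_step)
from sidm.md import H, O, T, W, density_profile, parse_architecture


def brute_force_pairs(pos, box, cutoff):
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt((d ** 2).sum(-1))
    i, j = np.triu_indices(len(pos), 1)
    sel = r[i, j] <= cutoff
    return set(zip(i[sel].tolist(), j[sel].tolist()))


class TestCellList:
    def test_two_particles_inside_and_outside_cutoff(self):
        box = np.array([12.0, 12.0, 12.0])
        for d, expect in ((2.8, 1), (3.05, 0)):
            s = ParticleSystem(np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]),
                               np.zeros((2, 3)), np.zeros(2, dtype=int), box)
            assert len(build_cell_list(s, 2.9)) == expect

    def test_pair_across_periodic_boundary(self):
        box = np.array([12.0, 12.0, 12.0])
        s = ParticleSystem(np.array([[0.3, 6.0, 6.0], [11.8, 6.0, 6.0]]),
                           np.zeros((2, 3)), np.zeros(2, dtype=int), box)
        assert len(build_cell_list(s, 2.9)) == 1

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        box = np.array([11.0, 13.0, 12.0])
        pos = rng.uniform(0, 1, (n, 3)) * box
        s = ParticleSystem(pos, np.zeros((n, 3)), np.zeros(n, dtype=int), box)
        pairs = set(map(tuple, build_cell_list(s, 2.9)))
        assert pairs == brute_force_pairs(s.positions, box, 2.9)

    def test_box_too_small_rejected(self):
        s = ParticleSystem(np.array([[1.0, 1.0, 1.0]]), np.zeros((1, 3)),
                           np.zeros(1, dtype=int), np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="too small"):
            build_cell_list(s, 2.9)


class TestVelocityVerlet:
    def test_free_particle_uniform_motion(self):
        box = np.array([20.0, 20.0, 20.0])
        s = ParticleSystem(np.array([[1.0, 1.0, 1.0]]),
                           np.array([[0.3, 0.2, 0.1]]),
                           np.zeros(1, dtype=int), box)
        ff = ForceField.liquid_vapor()
        f = np.zeros((1, 3))
        for _ in range(100):
            f = velocity_verlet_step(s, f, lambda sy: compute_forces(sy, ff),
                                     dt=0.01)
        np.testing.assert_allclose(s.positions[0], [1.3, 1.2, 1.1], atol=1e-12)

    def test_harmonic_oscillator_period(self):
        # bonded dimer, reduced mass 1/2: T = 2 pi sqrt(mu / k)
        k = 50.0
        ff = ForceField.liquid_vapor()
        ff.bond_k = k
        ff.pair_epsilon = np.zeros((4, 4))
        topo = Topology(bonds=np.array([[0, 1]]), bond_types=np.array([0]))
        box = np.array([20.0, 20.0, 20.0])
        s = ParticleSystem(np.array([[9.1, 10.0, 10.0], [10.3, 10.0, 10.0]]),
                           np.zeros((2, 3)), np.zeros(2, dtype=int), box)
        sim = Simulation(s, ff, topo, dt=0.002)
        period = 2 * math.pi * math.sqrt(0.5 / k)
        sep_prev, crossings, t_cross = None, [], []
        for i in range(int(10 * period / 0.002) + 2):
            sim.step()
            sep = s.positions[1, 0] - s.positions[0, 0] - 1.0
            if sep_prev is not None and sep_prev < 0 <= sep:
                frac = sep_prev / (sep_prev - sep)
                t_cross.append((i + frac) * 0.002)
            sep_prev = sep
        measured = np.mean(np.diff(t_cross))
        assert measured == pytest.approx(period, rel=1e-3)

    def test_nve_dimer_energy_conservation(self):
        box = np.array([12.0, 12.0, 12.0])
        s = ParticleSystem(np.array([[5.0, 5.0, 5.0], [6.15, 5.0, 5.0]]),
                           np.array([[0.05, 0.02, 0.0], [-0.05, -0.02, 0.0]]),
                           np.zeros(2, dtype=int), box)
        sim = Simulation(s, ForceField.liquid_vapor(), dt=0.006)
        energies = []
        for _ in range(10000):
            sim.step()
            energies.append(sim.total_energy)
        e = np.asarray(energies)
        drift = abs(e[-500:].mean() - e[:500].mean())
        assert drift < 1e-5

    def test_nonfinite_forces_abort(self):
        box = np.array([12.0, 12.0, 12.0])
        s = ParticleSystem(np.zeros((1, 3)), np.zeros((1, 3)),
                           np.zeros(1, dtype=int), box)
        with pytest.raises(FloatingPointError):
            velocity_verlet_step(s, np.array([[np.nan, 0.0, 0.0]]),
                                 lambda sy: compute_forces(
                                     sy, ForceField.liquid_vapor()))


class TestThermostat:
    def test_ideal_gas_temperature(self):
        # no interactions: the OU update is exact, T must match closely
        n = 1000
        box = np.array([20.0, 20.0, 20.0])
        ff = ForceField.liquid_vapor()
        ff.pair_epsilon = np.zeros((4, 4))
        s = ParticleSystem(np.random.default_rng(0).uniform(0, 20, (n, 3)),
                           maxwell_velocities(n, 0.5, seed=1),
                           np.zeros(n, dtype=int), box)
        rng = np.random.default_rng(2)
        temps = []
        for _ in range(8000):
            thermostat_step(s, 0.723, 1.0, rng)
            temps.append(kinetic_temperature(s))
        assert np.mean(temps[1000:]) == pytest.approx(0.723, rel=0.01)

    def test_component_selection(self):
        n = 500
        box = np.array([20.0, 20.0, 20.0])
        s = ParticleSystem(np.random.default_rng(0).uniform(0, 20, (n, 3)),
                           np.zeros((n, 3)), np.zeros(n, dtype=int), box)
        s.velocities[:, 0] = 1.0  # streaming x-velocity must be untouched
        rng = np.random.default_rng(3)
        for _ in range(100):
            thermostat_step(s, 1.0, 1.0, rng, components=(1, 2))
        assert np.all(s.velocities[:, 0] == 1.0)
        assert kinetic_temperature(s, components=(1, 2)) > 0.5

    def test_parameter_validation(self):
        s = ParticleSystem(np.zeros((1, 3)), np.zeros((1, 3)),
                           np.zeros(1, dtype=int), np.ones(3))
        with pytest.raises(ValueError):
            thermostat_step(s, 1.0, 0.0, 0)
        with pytest.raises(ValueError):
            thermostat_step(s, -1.0, 1.0, 0)


class TestPressureAndSurfaceTension:
    def test_ideal_gas_pressure(self):
        n, L, T = 2000, 15.0, 0.9
        rng = np.random.default_rng(4)
        box = np.array([L, L, L])
        s = ParticleSystem(rng.uniform(0, L, (n, 3)),
                           rng.normal(0, math.sqrt(T), (n, 3)),
                           np.zeros(n, dtype=int), box)
        p = pressure_tensor(s, np.zeros((3, 3)))
        rho = n / L ** 3
        t_actual = kinetic_temperature(s)
        np.testing.assert_allclose(np.diag(p), rho * t_actual, rtol=0.1)
        assert abs(p[0, 1]) < 0.05 * rho * t_actual + 0.01

    def test_isotropic_bulk_gives_zero_gamma(self):
        p = np.diag([1.3, 1.3, 1.3])
        assert surface_tension_kirkwood_buff(p, 20.0) == pytest.approx(0.0)

    def test_tension_formula(self):
        p = np.diag([1.0, 1.0, 1.5])
        assert surface_tension_kirkwood_buff(p, 40.0, 2) == pytest.approx(10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            surface_tension_kirkwood_buff(np.ones(3), 10.0)
        with pytest.raises(ValueError):
            surface_tension_kirkwood_buff(np.eye(3), 10.0, 0)


class TestBuilders:
    def test_parse_architecture(self):
        assert parse_architecture("H30T10") == [(H, 30), (T, 10)]
        assert parse_architecture("T5H10T5") == [(T, 5), (H, 10), (T, 5)]
        with pytest.raises(ValueError):
            parse_architecture("X5")

    def test_liquid_liquid_equal_counts(self):
        s = create_slab_system(density=0.7, box=(8.0, 8.0, 16.0),
                               mode="liquid-liquid", temperature=1.0,
                               seed=0, equil_steps=200, post_steps=0)
        assert (s.species == W).sum() == (s.species == O).sum()

    def test_insertion_preserves_density_and_count(self):
        s = create_slab_system(density=0.7, box=(8.0, 8.0, 16.0),
                               mode="liquid-liquid", temperature=1.0,
                               seed=1, equil_steps=500, post_steps=0)
        n0 = s.n
        s2, topo = insert_copolymers_by_identity_swap(s, "H3T3", 4, seed=2,
                                                      bond_type="fene")
        assert s2.n == n0
        assert (s2.species == H).sum() == 12
        assert (s2.species == T).sum() == 12
        assert topo.n_bonds == 4 * 5
        # conversion is identity swap only: positions untouched
        np.testing.assert_array_equal(s2.positions, s.positions)

    def test_insertion_count_zero_noop(self):
        s = create_slab_system(density=0.7, box=(8.0, 8.0, 16.0),
                               mode="liquid-liquid", temperature=1.0,
                               seed=1, equil_steps=200, post_steps=0)
        s2, topo = insert_copolymers_by_identity_swap(s, "H3T3", 0)
        assert topo.n_bonds == 0
        np.testing.assert_array_equal(s2.species, s.species)

    def test_triblock_gets_rigid_middle_block(self):
        s = create_slab_system(density=0.8, box=(9.0, 9.0, 9.0),
                               mode="liquid-vapor", temperature=0.723,
                               seed=3, equil_steps=500, post_steps=500)
        s2, topo = insert_copolymers_by_identity_swap(s, "T2H4T2", 2, seed=4)
        # angles/dihedrals only within the 4-bead middle H block
        assert len(topo.angles) == 2 * 2
        assert len(topo.dihedrals) == 2 * 1
        for trip in topo.angles:
            assert all(s2.species[i] == H for i in trip)

    def test_liquid_vapor_slab_has_two_interfaces(self):
        s = create_slab_system(density=0.8, box=(9.0, 9.0, 9.0),
                               mode="liquid-vapor", temperature=0.723,
                               seed=5, equil_steps=1000, post_steps=1500)
        z, rho = density_profile(s, 24)
        # liquid in the middle, dilute vapor at the edges
        assert rho[8:16].mean() > 0.6
        edge = np.r_[rho[:3], rho[-3:]].mean()
        assert edge < 0.1 * rho[8:16].mean()
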