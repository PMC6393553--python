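import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sidm import (DeformationProtocol, ForceField, ParticleSystem,
                  Simulation, TraceGenerationSpec, fixture_params,
                  generate_trace, maxwell_velocities)
from sidm.md import _lattice_positions


@pytest.fixture
def protocol():
    return DeformationProtocol(equilibration_s=2000.0, step_fraction=0.10,
                               step_duration_s=2.0, hold_s=1200.0,
                               sample_interval_s=1.0)


@pytest.fixture
def nanosphere_trace(protocol):
    """Noise-free trace with the nanosphere-expansion truth (beta=0.55,
    tau1=19.5 s) and the standard fixture constants."""
    spec = TraceGenerationSpec(relax_params=fixture_params(beta=0.55, tau1=19.5))
    return generate_trace(spec, protocol)


def make_bulk_liquid(n=500, rho=0.8, temperature=0.723, seed=0,
                     equil_steps=2000, forcefield=None):
    """Small equilibrated one-species LJ liquid for engine tests."""
    ff = forcefield or ForceField.liquid_vapor()
    L = (n / rho) ** (1.0 / 3.0)
    box = np.array([L, L, L])
    pos = _lattice_positions(n, box)
    system = ParticleSystem(pos, maxwell_velocities(n, temperature, seed=seed),
                            np.zeros(n, dtype=np.int64), box)
    sim = Simulation(system, ff, thermostat_t=temperature, damping=1.0,
                     seed=seed + 1)
    sim.run(equil_steps)
    return system, ff


@pytest.fixture(scope="session")
def bulk_liquid_factory():
    return make_bulk_liquid


@pytest.fixture(scope="session")
def lj_liquid_500():
    """Session-shared 500-particle LJ liquid at T=0.723, rho=0.8."""
    return make_bulk_liquid(n=500, rho=0.8, temperature=0.723, seed=11)
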