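import numpy as np
import pytest

from mnph.chain_sim import SimulationConfig, SimulationState
from mnph.heating import ThermalSpec
from mnph.magnetics import EnvironmentSpec, FieldSpec, ParticleSpec


@pytest.fixture(scope="session")
def particle_40nm() -> ParticleSpec:
    return ParticleSpec(
        diameter_m=40e-9,
        mass_density_kgm3=5180.0,
        magnetization_Am2kg=92.0,
        anisotropy_Jm3=1.1e4,
        label="40nm",
    )


@pytest.fixture(scope="session")
def particle_10nm() -> ParticleSpec:
    return ParticleSpec(
        diameter_m=10e-9,
        mass_density_kgm3=5180.0,
        magnetization_Am2kg=30.0,
        anisotropy_Jm3=1.1e4,
        label="10nm",
    )


@pytest.fixture(scope="session")
def env_water() -> EnvironmentSpec:
    return EnvironmentSpec(temperature_K=300.0, viscosity_PaS=1.0e-3)


@pytest.fixture(scope="session")
def field_765() -> FieldSpec:
    return FieldSpec(static_T=0.040, ac_amplitude_T=0.030, ac_frequency_Hz=765e3)


@pytest.fixture(scope="session")
def thermal() -> ThermalSpec:
    return ThermalSpec()  # 1 mL water-like sample, tau = 500 s


def make_line_state(z_positions_d0, lengths, p, box_d0=200.0, seed=0):
    """Objects on the z axis at given heights (in diameters), shared x-y."""
    d0 = p.diameter_m
    box = box_d0 * d0
    n = len(z_positions_d0)
    pos = np.full((n, 3), box / 2.0)
    pos[:, 2] = np.asarray(z_positions_d0, dtype=float) * d0
    lengths = np.asarray(lengths, dtype=np.int64)
    return SimulationState(
        t_s=0.0,
        lengths=lengths,
        positions_m=pos,
        unwrapped_m=pos.copy(),
        ids=np.arange(n, dtype=np.int64),
        rng=np.random.default_rng(seed),
        box_m=box,
        next_id=n,
    )


@pytest.fixture
def line_state_factory():
    return make_line_state


@pytest.fixture
def big_box_cfg():
    def factory(n=1, field_on=True, seed=0, box_d0=200.0, **kw):
        return SimulationConfig(
            n_particles=n, box_d0_units=box_d0, field_on=field_on, seed=seed, **kw
        )

    return factory
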