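"""Synthetic inputs for every pipeline stage.

Bundles the study conditions into named scenario presets (particle,
medium, fields, simulation box, thermal model, noise level), generates
noisy calorimetry traces from the lumped thermal model with the true SLP
recorded in metadata, and builds hand-specified chain configurations for
statistics tests. Everything is a pure function of its parameters and a
seed.

The two particle populations:

* ``40nm``: magnetite, d0 = 40 nm, ρ = 5180 kg/m³, M_s = 92 A·m²/kg,
  K = 11 kJ/m³ — strong dipolar coupling (Γ ≈ 190 at 300 K in water),
  ferromagnetic at room temperature, chain-forming.
* ``10nm``: same material but with the strongly size-suppressed moment
  of small co-precipitated magnetite (M_s = 30 A·m²/kg assumed; the
  measured value is not available) — Γ ≈ 0.3 < 1, superparamagnetic,
  non-chain-forming.

Boxes are cubes of side 80·d0 with N = 380/760/1520 particles for
nominal concentrations of 1/2/4 mg/mL; alignment field 40 mT, AC drive
30 mT at 765 kHz (210 kHz variants available via ``FieldSpec``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chain_sim import SimulationConfig, SimulationState
from .errors import ConfigError
from .heating import HeatingCurve, ThermalSpec, lumped_curve
from .magnetics import EnvironmentSpec, FieldSpec, ParticleSpec

__all__ = [
    "ScenarioPreset",
    "make_preset",
    "preset_names",
    "scale_particle_count",
    "synthetic_trace",
    "synthetic_chain_snapshot",
    "PARTICLE_40NM",
    "PARTICLE_10NM",
    "ENV_WATER_300K",
    "ENV_HOT_ALIGNMENT",
]

PARTICLE_40NM = ParticleSpec(
    diameter_m=40e-9,
    mass_density_kgm3=5180.0,
    magnetization_Am2kg=92.0,
    anisotropy_Jm3=1.1e4,
    label="40nm",
)

# M_s chosen to place the population firmly in the weak-coupling regime
# (Γ < 1); small co-precipitated magnetite is strongly moment-suppressed.
PARTICLE_10NM = ParticleSpec(
    diameter_m=10e-9,
    mass_density_kgm3=5180.0,
    magnetization_Am2kg=30.0,
    anisotropy_Jm3=1.1e4,
    label="10nm",
)

ENV_WATER_300K = EnvironmentSpec(temperature_K=300.0, viscosity_PaS=1.0e-3, medium_label="water")

#: Viscosity of water near 80 °C, for alignment-while-hot variants.
ENV_HOT_ALIGNMENT = EnvironmentSpec(
    temperature_K=353.15, viscosity_PaS=0.355e-3, medium_label="water_80C"
)

_COUNTS = {1: 380, 2: 760, 4: 1520}

#: Default simulated duration. With water viscosity the aggregation
#: kinetics of the strong-coupling population reach their plateau within
#: a few milliseconds (time scale ∝ viscosity); 5 ms spans growth and
#: stabilization at all three concentrations.
DEFAULT_DURATION_S = 5e-3


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified study scenario, ready to feed every module."""

    name: str
    particle: ParticleSpec
    environment: EnvironmentSpec
    field: FieldSpec
    simulation: SimulationConfig
    thermal: ThermalSpec
    concentration_mg_ml: float
    noise_sigma_K: float = 0.05


def _preset(name: str, particle: ParticleSpec, conc: int) -> ScenarioPreset:
    return ScenarioPreset(
        name=name,
        particle=particle,
        environment=ENV_WATER_300K,
        field=FieldSpec(static_T=0.040, ac_amplitude_T=0.030, ac_frequency_Hz=765e3),
        simulation=SimulationConfig(
            n_particles=_COUNTS[conc],
            box_d0_units=80.0,
            total_time_s=DEFAULT_DURATION_S,
            field_on=True,
            boundary="periodic",
            seed=0,
        ),
        thermal=ThermalSpec(),
        concentration_mg_ml=float(conc),
    )


_PRESETS = {}
for _conc in (1, 2, 4):
    _PRESETS[f"paper_40nm_{_conc}mgml"] = _preset(
        f"paper_40nm_{_conc}mgml", PARTICLE_40NM, _conc
    )
    _PRESETS[f"paper_10nm_{_conc}mgml"] = _preset(
        f"paper_10nm_{_conc}mgml", PARTICLE_10NM, _conc
    )
# convenience aliases at the reference concentration
_PRESETS["paper_40nm"] = replace(_PRESETS["paper_40nm_4mgml"], name="paper_40nm")
_PRESETS["paper_10nm"] = replace(_PRESETS["paper_10nm_1mgml"], name="paper_10nm")


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def make_preset(name: str) -> ScenarioPreset:
    """Return a named scenario preset.

    Unknown names raise :class:`ConfigError` listing the valid presets.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset '{name}'; valid presets: {', '.join(preset_names())}"
        ) from None


def scale_particle_count(preset: ScenarioPreset, n_particles: int) -> ScenarioPreset:
    """Reduce the particle count at fixed number density.

    Shrinks the box side by (n/N)^(1/3) so that concentration — the
    physically meaningful control parameter — is preserved while the
    simulation gets cheaper. Used for scaled-down replicate studies.
    """
    if n_particles < 1:
        raise ConfigError("n_particles must be >= 1")
    factor = (n_particles / preset.simulation.n_particles) ** (1.0 / 3.0)
    sim = replace(
        preset.simulation,
        n_particles=n_particles,
        box_d0_units=preset.simulation.box_d0_units * factor,
    )
    return replace(preset, simulation=sim)


def synthetic_trace(
    q_true_Wm3: float,
    th: ThermalSpec,
    sigma_noise_K: float = 0.05,
    seed: int = 0,
    t_heat_s: float = 120.0,
    t_cool_s: float = 120.0,
    dt_sample_s: float = 0.4,
) -> HeatingCurve:
    """Noisy lumped-model heating/cooling trace with known ground truth.

    Adds i.i.d. Gaussian probe noise of standard deviation
    ``sigma_noise_K`` to the deterministic lumped curve. The generating
    Q is stored in ``metadata["q_true_Wm3"]`` so recovery studies can
    compare against truth. Deterministic under a fixed seed; σ = 0
    reproduces the noiseless curve exactly.
    """
    if sigma_noise_K < 0:
        raise ValueError("noise sigma must be nonnegative")
    curve = lumped_curve(q_true_Wm3, th, t_heat_s, t_cool_s, dt_sample_s=dt_sample_s)
    temp = curve.temperature_K
    if sigma_noise_K > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, sigma_noise_K, size=len(temp))
    meta = dict(curve.metadata or {})
    meta.update({"q_true_Wm3": q_true_Wm3, "sigma_noise_K": sigma_noise_K, "seed": seed})
    return HeatingCurve(curve.time_s, temp, curve.phase, metadata=meta)


def synthetic_chain_snapshot(
    lengths,
    spacing_d0: float = 10.0,
    particle: ParticleSpec = PARTICLE_40NM,
    box_d0_units: float = 80.0,
    seed: int = 0,
) -> SimulationState:
    """Deterministic hand-specified chain configuration.

    Chains of the given ``lengths`` are placed on a line along x with
    centre-to-centre spacing ``spacing_d0`` diameters, all at the same
    y, z (mid-box), axes on z. Raises if the row does not fit in the
    box or chains would overlap laterally.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) == 0 or np.any(lengths < 1):
        raise ConfigError("need at least one chain with length >= 1")
    d0 = particle.diameter_m
    box = box_d0_units * d0
    if len(lengths) > 1 and spacing_d0 < 1.0:
        raise ConfigError("spacing below one diameter: chains would overlap")
    extent = (len(lengths) - 1) * spacing_d0 * d0
    if extent >= box:
        raise ConfigError("chain row does not fit in the box")
    longest = int(lengths.max())
    if longest * d0 >= box:
        raise ConfigError("chain longer than the box")
    x0 = (box - extent) / 2.0
    pos = np.zeros((len(lengths), 3))
    pos[:, 0] = x0 + np.arange(len(lengths)) * spacing_d0 * d0
    pos[:, 1] = box / 2.0
    pos[:, 2] = box / 2.0
    return SimulationState(
        t_s=0.0,
        lengths=lengths.copy(),
        positions_m=pos,
        unwrapped_m=pos.copy(),
        ids=np.arange(len(lengths), dtype=np.int64),
        rng=np.random.default_rng(seed),
        box_m=box,
        n_merges=int(np.sum(lengths - 1)),
        next_id=len(lengths),
    )
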