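"""YAML configuration round-tripping for scenario presets.

All keys carry explicit unit suffixes. Missing sections fall back to the
corresponding defaults, so a config file only needs the fields it
changes.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .chain_sim import SimulationConfig
from .errors import ConfigError
from .heating import ThermalSpec
from .magnetics import EnvironmentSpec, FieldSpec, ParticleSpec
from .synthetic_data import ScenarioPreset
from .units import celsius_to_kelvin, kelvin_to_celsius

__all__ = ["preset_to_dict", "preset_from_dict", "load_preset", "save_preset"]


def preset_to_dict(preset: ScenarioPreset) -> dict:
    p, env, f, sim, th = (
        preset.particle,
        preset.environment,
        preset.field,
        preset.simulation,
        preset.thermal,
    )
    return {
        "name": preset.name,
        "concentration_mg_ml": preset.concentration_mg_ml,
        "noise_sigma_K": preset.noise_sigma_K,
        "particle": {
            "diameter_nm": p.diameter_m * 1e9,
            "mass_density_kg_m3": p.mass_density_kgm3,
            "magnetization_Am2_kg": p.magnetization_Am2kg,
            "anisotropy_J_m3": p.anisotropy_Jm3,
            "label": p.label,
        },
        "environment": {
            "temperature_K": env.temperature_K,
            "viscosity_mPa_s": env.viscosity_PaS * 1e3,
            "medium_label": env.medium_label,
        },
        "field": {
            "static_mT": f.static_T * 1e3,
            "ac_amplitude_mT": f.ac_amplitude_T * 1e3,
            "ac_frequency_kHz": f.ac_frequency_Hz * 1e-3,
        },
        "simulation": {
            "n_particles": sim.n_particles,
            "box_d0_units": sim.box_d0_units,
            "total_time_s": sim.total_time_s,
            "dt_s": sim.dt_s,
            "snapshot_interval_s": sim.snapshot_interval_s,
            "field_on": sim.field_on,
            "boundary": sim.boundary,
            "seed": sim.seed,
        },
        "thermal": {
            "sample_mass_g": th.mass_kg * 1e3,
            "specific_heat_J_kgK": th.specific_heat_JkgK,
            "ambient_C": float(kelvin_to_celsius(th.ambient_K)),
            "loss_coefficient_W_K": th.loss_coefficient_WK,
            "sample_volume_mL": th.volume_m3 * 1e6,
            "conductivity_W_mK": th.conductivity_WmK,
            "density_kg_m3": th.density_kgm3,
            "heat_capacity_J_kgK": th.heat_capacity_JkgK,
        },
    }


def _section(data: dict, key: str) -> dict:
    sec = data.get(key) or {}
    if not isinstance(sec, dict):
        raise ConfigError(f"config section '{key}' must be a mapping")
    return sec


def preset_from_dict(data: dict) -> ScenarioPreset:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        ps = _section(data, "particle")
        particle = ParticleSpec(
            diameter_m=float(ps.get("diameter_nm", 40.0)) * 1e-9,
            mass_density_kgm3=float(ps.get("mass_density_kg_m3", 5180.0)),
            magnetization_Am2kg=float(ps.get("magnetization_Am2_kg", 92.0)),
            anisotropy_Jm3=float(ps.get("anisotropy_J_m3", 1.1e4)),
            label=str(ps.get("label", "")),
        )
        es = _section(data, "environment")
        env = EnvironmentSpec(
            temperature_K=float(es.get("temperature_K", 300.0)),
            viscosity_PaS=float(es.get("viscosity_mPa_s", 1.0)) * 1e-3,
            medium_label=str(es.get("medium_label", "water")),
        )
        fs = _section(data, "field")
        fld = FieldSpec(
            static_T=float(fs.get("static_mT", 40.0)) * 1e-3,
            ac_amplitude_T=float(fs.get("ac_amplitude_mT", 30.0)) * 1e-3,
            ac_frequency_Hz=float(fs.get("ac_frequency_kHz", 765.0)) * 1e3,
        )
        ss = _section(data, "simulation")
        dt = ss.get("dt_s")
        snap = ss.get("snapshot_interval_s")
        sim = SimulationConfig(
            n_particles=int(ss.get("n_particles", 380)),
            box_d0_units=float(ss.get("box_d0_units", 80.0)),
            total_time_s=float(ss.get("total_time_s", 5e-3)),
            dt_s=None if dt is None else float(dt),
            snapshot_interval_s=None if snap is None else float(snap),
            field_on=bool(ss.get("field_on", True)),
            boundary=str(ss.get("boundary", "periodic")),
            seed=int(ss.get("seed", 0)),
        )
        ts = _section(data, "thermal")
        th = ThermalSpec(
            mass_kg=float(ts.get("sample_mass_g", 1.0)) * 1e-3,
            specific_heat_JkgK=float(ts.get("specific_heat_J_kgK", 4186.0)),
            ambient_K=float(celsius_to_kelvin(float(ts.get("ambient_C", 25.0)))),
            loss_coefficient_WK=float(ts.get("loss_coefficient_W_K", 8.372e-3)),
            volume_m3=float(ts.get("sample_volume_mL", 1.0)) * 1e-6,
            conductivity_WmK=float(ts.get("conductivity_W_mK", 0.60)),
            density_kgm3=float(ts.get("density_kg_m3", 1000.0)),
            heat_capacity_JkgK=float(ts.get("heat_capacity_J_kgK", 4186.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc
    return ScenarioPreset(
        name=str(data.get("name", "custom")),
        particle=particle,
        environment=env,
        field=fld,
        simulation=sim,
        thermal=th,
        concentration_mg_ml=float(data.get("concentration_mg_ml", 1.0)),
        noise_sigma_K=float(data.get("noise_sigma_K", 0.05)),
    )


def load_preset(path, seed: int | None = None) -> ScenarioPreset:
    """Load a scenario from YAML; an explicit ``seed`` overrides the file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    preset = preset_from_dict(data or {})
    if seed is not None:
        preset = replace(preset, simulation=replace(preset.simulation, seed=seed))
    return preset


def save_preset(preset: ScenarioPreset, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(preset_to_dict(preset), fh, sort_keys=False)
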