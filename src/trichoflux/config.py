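"""Configuration I/O: YAML round-trip of parameters, forcing and run options.

Config keys carry explicit unit suffixes (``_per_day``, ``_mol_per_m3``,
``_h`` ...) to keep the day/hour and molar/micromolar unit mix honest.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .params import ModelParameters, ParameterError
from .simulate import ForcingSchedule

SCHEMA_VERSION = 1

# config key -> ModelParameters field
_PARAM_KEYS = {
    "F_Nfix_full_molN_per_molC_per_day": "F_Nfix_full",
    "f_NITROGE": "f_NITROGE",
    "O2_crit_mol_per_m3": "O2_crit",
    "dark_gate_n2fix": "dark_gate_n2fix",
    "K_C_molC_per_molC": "K_C",
    "C_Sto_max_molC_per_molC": "C_Sto_max",
    "N_Sto_max_molN_per_molC": "N_Sto_max",
    "F_Bio_max_per_day": "F_Bio_max",
    "F_Cfix_MaxChl_per_day_per_chl": "F_Cfix_MaxChl",
    "K_I_per_light_unit": "K_I",
    "Chl_full_relative": "Chl_full",
    "Y_Nfix_CN_molC_per_molN": "Y_Nfix_CN",
    "Y_Bio_NC_molN_per_molC": "Y_Bio_NC",
    "Y_Res_Bio_molC_per_molC": "Y_Res_Bio",
    "Y_O2_C_molO2_per_molC": "Y_O2_C",
    "Y_ResN2_Nfix_molC_per_molN": "Y_ResN2_Nfix",
    "A_PB_water_per_day": "A_PB_water",
    "A_PN_water_per_day": "A_PN_water",
    "A_BN_water_per_day": "A_BN_water",
    "A_BE_per_day": "A_BE",
    "eps_membrane": "eps_membrane",
    "V_P_frac": "V_P_frac",
    "V_N_frac": "V_N_frac",
    "V_B_frac": "V_B_frac",
    "O2_env_mol_per_m3": "O2_env",
    "O2_N_floor_mol_per_m3": "O2_N_floor",
    "Q_C_conc_molC_per_m3": "Q_C_conc",
    "FvFm_P": "FvFm_P",
    "FvFm_N": "FvFm_N",
}
_FIELD_TO_KEY = {v: k for k, v in _PARAM_KEYS.items()}

_RUN_KEYS = {"days", "dt_days", "spinup_days"}
DEFAULT_RUN = {"days": 4, "dt_days": 0.001, "spinup_days": 3}


class ConfigError(ValueError):
    """Raised for malformed, unknown or out-of-domain config content."""


def default_parameters() -> ModelParameters:
    """The committed calibrated default parameter set."""
    return ModelParameters()


def default_schedule() -> ForcingSchedule:
    """12 h / 12 h light cycle with the 0.8 / 0.55 / 0.8 f_P steps."""
    return ForcingSchedule()


def params_to_mapping(params: ModelParameters) -> dict:
    d = params.to_dict()
    return {key: d[fld] for key, fld in _PARAM_KEYS.items()}


def schedule_to_mapping(schedule: ForcingSchedule) -> dict:
    return {
        "I_light": schedule.I_light,
        "light_start_h": schedule.light_start,
        "light_end_h": schedule.light_end,
        "f_P_steps": {float(s): float(v) for s, v in schedule.f_P_steps},
    }


def config_to_mapping(
    params: ModelParameters,
    schedule: ForcingSchedule,
    run_options: dict | None = None,
) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "parameters": params_to_mapping(params),
        "forcing": schedule_to_mapping(schedule),
        "run": dict(DEFAULT_RUN, **(run_options or {})),
    }


def _parse_parameters(mapping: dict) -> ModelParameters:
    unknown = set(mapping) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {_PARAM_KEYS[k]: v for k, v in mapping.items()}
    try:
        return ModelParameters(**kwargs)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc


def _parse_schedule(mapping: dict) -> ForcingSchedule:
    allowed = {"I_light", "light_start_h", "light_end_h", "f_P_steps"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown forcing keys: {sorted(unknown)}")
    steps = mapping.get("f_P_steps", dict(ForcingSchedule().f_P_steps))
    if not isinstance(steps, dict):
        raise ConfigError("f_P_steps must be a mapping {start_hour: f_P}")
    step_tuple = tuple(sorted((float(k), float(v)) for k, v in steps.items()))
    return ForcingSchedule(
        I_light=float(mapping.get("I_light", ForcingSchedule().I_light)),
        light_start=float(mapping.get("light_start_h", 0.0)),
        light_end=float(mapping.get("light_end_h", 12.0)),
        f_P_steps=step_tuple,
    )


def parse_config(mapping: dict) -> tuple[ModelParameters, ForcingSchedule, dict]:
    if not isinstance(mapping, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(mapping) - {"schema_version", "parameters", "forcing", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    version = mapping.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")
    params = _parse_parameters(mapping.get("parameters", {}))
    schedule = _parse_schedule(mapping.get("forcing", {}))
    run_map = mapping.get("run", {})
    unknown = set(run_map) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown run keys: {sorted(unknown)}")
    run_options = dict(DEFAULT_RUN, **run_map)
    if run_options["dt_days"] <= 0 or run_options["days"] < 1 or run_options["spinup_days"] < 0:
        raise ConfigError("run options out of domain")
    return params, schedule, run_options


def load_config(path: str | Path) -> tuple[ModelParameters, ForcingSchedule, dict]:
    """Read a YAML config; returns (parameters, schedule, run options)."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return parse_config(mapping)


def save_config(
    path: str | Path,
    params: ModelParameters,
    schedule: ForcingSchedule,
    run_options: dict | None = None,
) -> None:
    """Write a round-trippable YAML config."""
    mapping = config_to_mapping(params, schedule, run_options)
    Path(path).write_text(yaml.safe_dump(mapping, sort_keys=False))


def packaged_default_config_path() -> Path:
    """Path to the calibrated default config shipped with the package."""
    return Path(importlib.resources.files("trichoflux") / "data" / "default_config.yaml")
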