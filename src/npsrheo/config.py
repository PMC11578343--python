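"""Plain-text (YAML) configuration: device geometry and run configuration.

Geometry schema (all lengths µm, pressure Pa, rate samples/s)::

    pore: {L_pore: 1000.0, D_eff: 25.0}
    zones:
      - {L_zone: 6000.0, L_p: 500.0, w0: 11.25, a: 2.75, w_node: 21.0}
      - {L_zone: 6000.0, L_p: 250.0, w0: 11.25, a: 2.75, w_node: 21.0}
    zone_D_eff: [25.0, 25.0]        # optional, defaults to pore D_eff
    sample_rate: 10000.0
    applied_pressure: 13800.0
    node_length: 500.0
    mu_f: 0.1

Run configuration::

    geometry: geometry.yaml          # path, or an inline geometry mapping
    seed: 1
    pipeline: {lowpass_cutoff: 2000.0, ...}      # PipelineParams fields
    rheology: {mu_f: 0.1, pressure_mode: time_resolved, ...}
    simulation: {n_cells: 20, noise_sd: 0.0, ...}  # SimConfig fields
    log_level: INFO

Unknown keys are rejected everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .device_model import DeviceGeometry, PoreSpec, ZoneSpec
from .errors import ConfigError
from .rheology import RheologyParams
from .signal_pipeline import PipelineParams

__all__ = ["load_geometry", "geometry_from_dict", "RunConfig", "load_run_config"]

_GEOMETRY_KEYS = {
    "pore",
    "zones",
    "zone_D_eff",
    "sample_rate",
    "applied_pressure",
    "node_length",
    "mu_f",
}


def _require_mapping(obj, what: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{what} must be a mapping")
    return obj


def geometry_from_dict(data: dict) -> DeviceGeometry:
    data = _require_mapping(data, "geometry")
    unknown = set(data) - _GEOMETRY_KEYS
    if unknown:
        raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")
    if "pore" not in data or "zones" not in data:
        raise ConfigError("geometry needs 'pore' and 'zones'")
    pore_d = _require_mapping(data["pore"], "pore")
    if set(pore_d) != {"L_pore", "D_eff"}:
        raise ConfigError("pore block must have exactly L_pore and D_eff")
    pore = PoreSpec(L_pore=float(pore_d["L_pore"]), D_eff=float(pore_d["D_eff"]))
    zones = []
    zone_keys = {"L_zone", "L_p", "w0", "a", "w_node"}
    for i, zd in enumerate(data["zones"]):
        zd = _require_mapping(zd, f"zone {i}")
        if set(zd) != zone_keys:
            raise ConfigError(f"zone {i} must have exactly keys {sorted(zone_keys)}")
        zones.append(ZoneSpec(index=i, **{k: float(zd[k]) for k in zone_keys}))
    kwargs = {}
    for key in ("sample_rate", "applied_pressure", "node_length", "mu_f"):
        if key in data:
            kwargs[key] = float(data[key])
    if "zone_D_eff" in data:
        kwargs["zone_D_eff"] = tuple(float(v) for v in data["zone_D_eff"])
    return DeviceGeometry(pore=pore, zones=tuple(zones), **kwargs)


def load_geometry(path: str | Path) -> DeviceGeometry:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"geometry file not found: {path}")
    with path.open() as fh:
        data = yaml.safe_load(fh)
    return geometry_from_dict(data)


def _params_from_dict(cls, data: dict | None, what: str):
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Everything one processing run needs."""

    geometry: DeviceGeometry
    seed: int = 0
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    rheology: RheologyParams = field(default_factory=RheologyParams)
    simulation: dict = field(default_factory=dict)
    log_level: str = "INFO"


_RUN_KEYS = {"geometry", "seed", "pipeline", "rheology", "simulation", "log_level"}


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"run config not found: {path}")
    with path.open() as fh:
        data = yaml.safe_load(fh)
    data = _require_mapping(data, "run config")
    unknown = set(data) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    if "geometry" not in data:
        raise ConfigError("run config needs 'geometry'")
    geo_val = data["geometry"]
    if isinstance(geo_val, str):
        geo_path = Path(geo_val)
        if not geo_path.is_absolute():
            geo_path = path.parent / geo_path
        geometry = load_geometry(geo_path)
    else:
        geometry = geometry_from_dict(geo_val)
    sim = data.get("simulation") or {}
    if not isinstance(sim, dict):
        raise ConfigError("simulation block must be a mapping")
    # rheology mu_f defaults to the device's friction coefficient
    rheo_block = dict(data.get("rheology") or {})
    rheo_block.setdefault("mu_f", geometry.mu_f)
    return RunConfig(
        geometry=geometry,
        seed=int(data.get("seed", 0)),
        pipeline=_params_from_dict(PipelineParams, data.get("pipeline"), "pipeline"),
        rheology=_params_from_dict(RheologyParams, rheo_block, "rheology"),
        simulation=sim,
        log_level=str(data.get("log_level", "INFO")),
    )
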