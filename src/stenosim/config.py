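"""Structured configuration shared by the CLI and the library.

A single YAML document holds every model constant (units noted inline in
the shipped default) and maps one-to-one onto the dataclasses of the
geometry, material and circuit modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Any, Dict

import yaml

from .chamber import LVGeometryParams
from .circulation import CircuitParameters, ElastanceParams
from .materials.active import ActiveParameters
from .materials.passive import HOParameters


def default_config() -> Dict[str, Any]:
    """Shipped defaults: every printed constant of the study plus the
    artifact's own geometry/discretization choices."""
    return {
        "geometry": dataclasses.asdict(LVGeometryParams()),
        "passive": dataclasses.asdict(HOParameters()),      # kPa / 1/kPa
        "active": dataclasses.asdict(ActiveParameters()),   # kPa, s, um
        "circuit": _circuit_dict(CircuitParameters()),      # MPa, mm^3, s
        "simulation": {
            "dt": 5.0e-4,            # s
            "n_cycles": 3,
            "seed": 0,
            "restore_ef": True,      # rescale Tmax in stenosis scenarios
        },
        "targets": {                 # baseline calibration targets
            "ef_pct": 60.0,
            "edv_ml": 137.0,
            "aortic_systolic_mmhg": 113.0,
            "aortic_diastolic_mmhg": 56.5,
        },
    }


def _circuit_dict(c: CircuitParameters) -> Dict[str, Any]:
    d = dataclasses.asdict(c)
    return d


def load_config(path) -> Dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        if isinstance(values, dict):
            cfg[section] = _merge(cfg[section], values)
        else:
            cfg[section] = values
    return cfg


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise KeyError(f"unknown config key {k!r}")
        out[k] = _merge(base[k], v) if isinstance(v, dict) else v
    return out


def save_config(cfg: Dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: Dict[str, Any]) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def make_geometry(cfg: Dict[str, Any]) -> LVGeometryParams:
    return LVGeometryParams(**cfg["geometry"])


def make_passive(cfg: Dict[str, Any]) -> HOParameters:
    return HOParameters(**cfg["passive"])


def make_active(cfg: Dict[str, Any]) -> ActiveParameters:
    return ActiveParameters(**cfg["active"])


def make_circuit(cfg: Dict[str, Any]) -> CircuitParameters:
    d = dict(cfg["circuit"])
    for name in ("la", "ra", "rv"):
        if isinstance(d.get(name), dict):
            d[name] = ElastanceParams(**d[name])
    return CircuitParameters(**d)


def write_default_config(path) -> None:
    save_config(default_config(), path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
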