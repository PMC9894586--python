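"""Run configuration: schema-validated YAML/JSON loading, presets, and the
resolved-config echo that makes every run reproducible from one file.

A config names an engine ("agents" or "continuum"), supplies at most one of
``physical_params`` / ``nondim_groups`` (the continuum engine derives the
groups from physical parameters when given; supplying both is rejected),
and optionally overrides geometry, initial condition and run controls.
Every default actually used is materialized into ``RunConfig.resolved``,
which round-trips: loading the resolved dict reproduces an identical
RunConfig, and with the same seed an identical run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .agents import AgentSimConfig
from .continuum import ContinuumConfig
from .params import (Geometry, NonDimGroups, PhysicalParams, nondimensionalize)

__all__ = ["RunConfig", "ConfigError", "load_config", "resolve_config",
           "preset", "PRESETS"]


class ConfigError(ValueError):
    """Malformed configuration: unknown key, missing key, or inconsistent
    combination; the message names the offending key."""


@dataclass
class RunConfig:
    """A fully-resolved run: engine, seed, and the engine-specific config."""

    engine: str
    seed: int
    resolved: Dict[str, Any]
    agent: Optional[AgentSimConfig] = None
    continuum: Optional[ContinuumConfig] = None

    def dump_resolved(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.resolved, indent=2, sort_keys=True))
        return path


def _check_keys(d: Dict[str, Any], allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}; "
                          f"allowed: {sorted(allowed)}")


_TOP_KEYS = ("engine", "seed", "physical_params", "nondim_groups", "geometry",
             "initial_condition", "run", "agent")
_IC_KEYS = ("name", "center", "width", "amplitude", "c0", "noise_amp")
_RUN_KEYS = ("dt", "t_end", "snapshot_dt", "nx", "integrator",
             "breakthrough_threshold", "stop_on_breakthrough", "dt_safety",
             "domain_length", "substrate_interval")
_AGENT_KEYS = tuple(k for k in AgentSimConfig.__dataclass_fields__
                    if k not in ("geometry", "seed"))


def resolve_config(raw: Dict[str, Any]) -> RunConfig:
    """Validate a config dict, materialize every default, and build the
    engine config.  Unknown keys are rejected with the key named."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config root")
    engine = raw.get("engine")
    if engine not in ("agents", "continuum"):
        raise ConfigError(f"key 'engine' must be 'agents' or 'continuum', got {engine!r}")
    seed = int(raw.get("seed", 0))

    if "physical_params" in raw and "nondim_groups" in raw:
        raise ConfigError("supply only one of 'physical_params' / 'nondim_groups'")

    geom_d = dict(raw.get("geometry", {}))
    _check_keys(geom_d, ("Ro", "Ri", "domain_half_width", "center"), "geometry")
    if "center" in geom_d:
        geom_d["center"] = tuple(geom_d["center"])
    geometry = Geometry(**geom_d)

    if "physical_params" in raw:
        pp = dict(raw["physical_params"])
        _check_keys(pp, PhysicalParams.__dataclass_fields__, "physical_params")
        physical = PhysicalParams(**pp)
        groups = nondimensionalize(physical, geometry)
        groups_src = "physical_params"
    else:
        gg = dict(raw.get("nondim_groups", {}))
        _check_keys(gg, NonDimGroups.__dataclass_fields__, "nondim_groups")
        groups = NonDimGroups(**gg)
        physical = None
        groups_src = "nondim_groups"

    run = dict(raw.get("run", {}))
    _check_keys(run, _RUN_KEYS, "run")
    ic = dict(raw.get("initial_condition", {}))
    _check_keys(ic, _IC_KEYS, "initial_condition")

    agent_cfg = None
    cont_cfg = None
    if engine == "continuum":
        noise_amp = float(ic.pop("noise_amp", 0.01))
        ic_name = ic.pop("name", None)
        if ic_name is not None:
            ndim = 1 if ic_name.endswith("1d") else 2
        else:
            ndim = 1 if "domain_length" in run else 2
            ic_name = "gaussian_1d" if ndim == 1 else "uniform_disk_2d"
        sub = run.pop("substrate_interval", (0.6, 0.85))
        cont_cfg = ContinuumConfig(
            groups=groups, ndim=ndim, geometry=geometry if ndim == 2 else None,
            domain_length=float(run.pop("domain_length", 1.0)),
            substrate_interval=tuple(sub),
            nx=int(run.pop("nx", 256 if ndim == 1 else 128)),
            ic_name=ic_name, ic_params=ic, noise_amp=noise_amp, seed=seed,
            dt=run.pop("dt", None),
            dt_safety=float(run.pop("dt_safety", 0.4)),
            t_end=float(run.pop("t_end", 10.0)),
            snapshot_dt=float(run.pop("snapshot_dt", 0.5)),
            integrator=run.pop("integrator", "euler"),
            breakthrough_threshold=float(run.pop("breakthrough_threshold", 0.5)),
            stop_on_breakthrough=bool(run.pop("stop_on_breakthrough", False)),
        )
    else:
        ag = dict(raw.get("agent", {}))
        _check_keys(ag, _AGENT_KEYS, "agent")
        agent_cfg = AgentSimConfig(geometry=geometry, seed=seed, **ag)

    resolved: Dict[str, Any] = {
        "engine": engine,
        "seed": seed,
        "geometry": geometry.to_dict(),
        "groups_source": groups_src,
    }
    if physical is not None:
        resolved["physical_params"] = physical.to_dict()
    resolved["nondim_groups_resolved"] = groups.to_dict()
    if engine == "continuum":
        resolved["continuum"] = {
            "ndim": cont_cfg.ndim,
            "domain_length": cont_cfg.domain_length,
            "substrate_interval": list(cont_cfg.substrate_interval),
            "nx": cont_cfg.nx,
            "ic_name": cont_cfg.ic_name,
            "ic_params": cont_cfg.ic_params,
            "noise_amp": cont_cfg.noise_amp,
            "dt": cont_cfg.dt,
            "dt_safety": cont_cfg.dt_safety,
            "t_end": cont_cfg.t_end,
            "snapshot_dt": cont_cfg.snapshot_dt,
            "integrator": cont_cfg.integrator,
            "breakthrough_threshold": cont_cfg.breakthrough_threshold,
            "stop_on_breakthrough": cont_cfg.stop_on_breakthrough,
        }
    else:
        resolved["agent"] = {k: v for k, v in agent_cfg.to_dict().items()
                             if k not in ("geometry", "seed")}
    return RunConfig(engine=engine, seed=seed, resolved=resolved,
                     agent=agent_cfg, continuum=cont_cfg)


def _raw_from_resolved(resolved: Dict[str, Any]) -> Dict[str, Any]:
    """Invert the resolved echo back into a loadable raw config."""
    raw: Dict[str, Any] = {
        "engine": resolved["engine"],
        "seed": resolved["seed"],
        "geometry": {k: v for k, v in resolved["geometry"].items()},
    }
    if resolved.get("groups_source") == "physical_params":
        raw["physical_params"] = resolved["physical_params"]
    else:
        raw["nondim_groups"] = resolved["nondim_groups_resolved"]
    if resolved["engine"] == "continuum":
        c = resolved["continuum"]
        raw["initial_condition"] = {"name": c["ic_name"],
                                    "noise_amp": c["noise_amp"], **c["ic_params"]}
        raw["run"] = {k: c[k] for k in ("dt", "t_end", "snapshot_dt", "nx",
                                        "integrator", "breakthrough_threshold",
                                        "stop_on_breakthrough", "dt_safety",
                                        "domain_length", "substrate_interval")}
    else:
        raw["agent"] = resolved["agent"]
    return raw


def load_config(source: Union[str, Path, Dict[str, Any]]) -> RunConfig:
    """Load and resolve a YAML/JSON config file (or an in-memory dict,
    including a previously written resolved-config echo)."""
    if isinstance(source, dict):
        raw = source
        if "nondim_groups_resolved" in raw:      # a resolved echo
            raw = _raw_from_resolved(raw)
        return resolve_config(raw)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text)                   # YAML is a JSON superset
    if isinstance(raw, dict) and "nondim_groups_resolved" in raw:
        raw = _raw_from_resolved(raw)
    return resolve_config(raw)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _preset_fig4_1d() -> Dict[str, Any]:
    """1D coordinated-excavation preset: Gaussian collective at x=0.5
    digging through a substrate block, C and E above one."""
    return {
        "engine": "continuum",
        "seed": 0,
        "nondim_groups": {"C": 2.0, "E": 2.0, "V": 1.0, "k_hat": 2.0,
                          "Dc_hat": 1.0, "c_star": 0.25, "rho_a_star": 0.25,
                          "alpha_c": 20.0},
        "initial_condition": {"name": "gaussian_1d", "center": 0.5,
                              "width": 0.1, "amplitude": 2.0, "noise_amp": 0.0},
        "run": {"t_end": 6.0, "snapshot_dt": 0.25, "nx": 128,
                "domain_length": 1.0, "substrate_interval": [0.6, 0.85],
                "stop_on_breakthrough": False},
    }


def _preset_fig5_2d() -> Dict[str, Any]:
    """2D annular-corral preset at C=0.8, E=1.44, Ro=5, Ri=2.5: successful
    tunneling within 20 nondimensional time units."""
    return {
        "engine": "continuum",
        "seed": 0,
        "nondim_groups": {"C": 0.8, "E": 1.44, "V": 1.0, "k_hat": 2.0,
                          "Dc_hat": 1.0, "c_star": 0.25, "rho_a_star": 0.25,
                          "alpha_c": 20.0},
        "geometry": {"Ro": 5.0, "Ri": 2.5, "domain_half_width": 6.0},
        "initial_condition": {"name": "uniform_disk_2d", "amplitude": 1.0,
                              "noise_amp": 0.01},
        "run": {"t_end": 25.0, "snapshot_dt": 0.5, "nx": 128,
                "stop_on_breakthrough": False},
    }


def _preset_agents_default() -> Dict[str, Any]:
    """Agent-engine default: the annular element wall and thresholds under
    which mid-sized collectives excavate out before Tstop = 266."""
    return {"engine": "agents", "seed": 0,
            "geometry": {"Ro": 5.0, "Ri": 2.5, "domain_half_width": 6.0},
            "agent": {}}


def _preset_rant_arena() -> Dict[str, Any]:
    """Behavioral-controller arena: three layers of 200 wall elements, the
    cooperation parameter C scaling gradient following vs noise and a grasp
    probability E_grasp."""
    return {"engine": "agents", "seed": 0,
            "geometry": {"Ro": 5.0, "Ri": 2.5, "domain_half_width": 6.0},
            "agent": {"rant_mode": True, "C": 1.0, "E_grasp": 1.0,
                      "wall_layers": 3, "wall_total": 200,
                      "element_radius": 0.14}}


PRESETS = {
    "fig4-1d": _preset_fig4_1d,
    "fig5-2d": _preset_fig5_2d,
    "agents-default": _preset_agents_default,
    "rant-arena": _preset_rant_arena,
}


def preset(name: str) -> RunConfig:
    """A named shipped preset, resolved."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return resolve_config(PRESETS[name]())
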