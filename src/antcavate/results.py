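"""Persistence: NPZ containers with a resolved-config JSON sidecar and a
CSV event table; write -> read round-trips arrays bit-exactly."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .agents import AgentRunResult
from .continuum import ContinuumState

__all__ = ["write_results", "read_results", "ResultIntegrityError",
           "agent_result_arrays", "snapshots_arrays"]


class ResultIntegrityError(IOError):
    """A result container is missing members."""


def agent_result_arrays(res: AgentRunResult) -> Dict[str, np.ndarray]:
    arrays: Dict[str, np.ndarray] = {"times": res.times}
    if res.trajectory is not None:
        arrays["trajectory"] = res.trajectory
        arrays["headings"] = res.headings
    for t, f in res.field_snapshots.items():
        arrays[f"field_t{t:g}"] = f
    arrays["escape"] = np.array([
        res.config["Tstop"] if res.censored else res.escape_time,
        1.0 if res.censored else 0.0])
    return arrays


def snapshots_arrays(snapshots) -> Dict[str, np.ndarray]:
    """Stack continuum snapshots into /t, /rho_a, /c, /rho_s arrays."""
    return {
        "t": np.array([s.t for s in snapshots]),
        "rho_a": np.stack([s.rho_a for s in snapshots]),
        "c": np.stack([s.c for s in snapshots]),
        "rho_s": np.stack([s.rho_s for s in snapshots]),
        "grid": np.array([snapshots[0].h, *snapshots[0].origin]),
    }


def write_results(path, arrays: Dict[str, np.ndarray], config: Dict[str, Any],
                  events: Optional[pd.DataFrame] = None) -> Path:
    """Write ``<path>.npz`` (arrays), ``<path>.json`` (resolved config) and,
    when given, ``<path>.events.csv``."""
    path = Path(path)
    path = path.with_suffix("") if path.suffix == ".npz" else path
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = dict(config)
    meta["_members"] = sorted(arrays)
    meta["_has_events"] = events is not None
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if events is not None:
        events.to_csv(path.with_suffix(".events.csv"), index=False)
    return path


def read_results(path) -> Tuple[Dict[str, np.ndarray], Dict[str, Any],
                                Optional[pd.DataFrame]]:
    """Read a container back; verifies every member listed in the sidecar is
    present, else raises :class:`ResultIntegrityError` naming the missing."""
    path = Path(path)
    path = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    npz_path = path.with_suffix(".npz")
    json_path = path.with_suffix(".json")
    missing = [str(p) for p in (npz_path, json_path) if not p.exists()]
    if missing:
        raise ResultIntegrityError(f"missing container file(s): {missing}")
    config = json.loads(json_path.read_text())
    with np.load(npz_path) as z:
        arrays = {k: z[k] for k in z.files}
    wanted = set(config.get("_members", []))
    absent = sorted(wanted - set(arrays))
    if absent:
        raise ResultIntegrityError(f"container {npz_path} is missing members {absent}")
    events = None
    if config.get("_has_events"):
        csv_path = path.with_suffix(".events.csv")
        if not csv_path.exists():
            raise ResultIntegrityError(f"missing events table {csv_path}")
        events = pd.read_csv(csv_path)
    return arrays, config, events
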