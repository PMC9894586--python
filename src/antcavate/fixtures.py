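"""Deterministic generators for initial conditions, corral walls and tracks.

Everything here is a pure function of its parameters and a seed: Gaussian or
uniform density profiles for the continuum solver, rings of discrete wall
elements for the agent engine (the default arena mirrors a corral built from
three concentric layers of cylindrical elements), and synthetic trajectory
tables with a prescribed localization angle for exercising the observables
pipeline end to end.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "make_fixture",
    "gaussian_profile_1d",
    "uniform_disk_2d",
    "element_ring",
    "synthetic_tracks",
    "PackingError",
]


class PackingError(ValueError):
    """Requested element packing does not fit in the annulus."""


def gaussian_profile_1d(nx: int = 256, length: float = 1.0, center: float = 0.5,
                        width: float = 0.08, mass: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Discrete Gaussian density on cell centers, normalized so the grid
    quadrature (sum * h) equals ``mass`` exactly."""
    h = length / nx
    x = (np.arange(nx) + 0.5) * h
    rho = np.exp(-0.5 * ((x - center) / width) ** 2)
    rho *= mass / (rho.sum() * h)
    return x, rho


def uniform_disk_2d(nx: int = 128, half_width: float = 6.0, radius: float = 2.5,
                    amplitude: float = 1.0, noise_amp: float = 0.01,
                    seed: int = 0) -> np.ndarray:
    """Uniform density inside a centered disk with relative seeded noise."""
    rng = np.random.default_rng(seed)
    h = 2.0 * half_width / nx
    xc = -half_width + (np.arange(nx) + 0.5) * h
    X, Y = np.meshgrid(xc, xc)
    rho = amplitude * (np.hypot(X, Y) < radius).astype(float)
    if noise_amp > 0.0:
        rho = rho * (1.0 + noise_amp * rng.standard_normal(rho.shape))
        np.clip(rho, 0.0, None, out=rho)
    return rho


def element_ring(layers: int = 3, total: int = 200, r_min: float = 2.5,
                 r_max: float = 4.0, element_radius: Optional[float] = None,
                 seed: int = 0) -> Tuple[np.ndarray, float]:
    """Pack ``total`` wall elements into ``layers`` concentric circles
    between radii ``r_min`` and ``r_max`` (annulus of the corral wall).

    Counts per layer are proportional to the layer circumference so that the
    angular spacing is as uniform as possible; each layer gets a seeded
    angular offset.  Returns (positions (total, 2), element_radius).

    Raises :class:`PackingError`, reporting the maximum feasible count, if
    neighbouring elements of any layer would overlap.
    """
    if layers < 1 or total < layers:
        raise PackingError(f"need at least one element per layer (layers={layers}, total={total})")
    rng = np.random.default_rng(seed)
    band = (r_max - r_min) / layers
    radii = r_min + (np.arange(layers) + 0.5) * band
    if element_radius is None:
        element_radius = 0.45 * band  # adjacent layers nearly touch
    if 2.0 * element_radius > band:
        raise PackingError(
            f"element_radius={element_radius:g} exceeds the layer band {band:g}/2; "
            f"max feasible radius is {band / 2:g}")
    # distribute counts proportionally to circumference, fixing the total
    weights = radii / radii.sum()
    counts = np.floor(weights * total).astype(int)
    counts[counts < 1] = 1
    for i in np.argsort(-radii):
        if counts.sum() >= total:
            break
        counts[i] += total - counts.sum()
    while counts.sum() > total:
        counts[np.argmax(counts)] -= 1
    max_total = int(sum(math.floor(math.pi * r / element_radius) for r in radii))
    for r, cnt in zip(radii, counts):
        if cnt * 2.0 * element_radius > 2.0 * math.pi * r:
            raise PackingError(
                f"cannot fit {cnt} elements of radius {element_radius:g} on a circle of "
                f"radius {r:g}; maximum feasible total for this geometry is {max_total}")
    pos = []
    for r, cnt in zip(radii, counts):
        phi0 = rng.uniform(0.0, 2.0 * math.pi)
        phis = phi0 + 2.0 * math.pi * np.arange(cnt) / cnt
        pos.append(np.column_stack([r * np.cos(phis), r * np.sin(phis)]))
    positions = np.concatenate(pos, axis=0)
    assert positions.shape[0] == total
    return positions, float(element_radius)


def synthetic_tracks(phi0: float = 1.0, n_agents: int = 10, duration: float = 100.0,
                     dt: float = 1.0, r_loc: float = 3.0, spread: float = 0.4,
                     seed: int = 0) -> pd.DataFrame:
    """Trajectory table (t, id, x, y) of agents jittering around a site at
    polar angle ``phi0`` and radius ``r_loc`` — a localized collective."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 1e-9, dt)
    cx, cy = r_loc * math.cos(phi0), r_loc * math.sin(phi0)
    rows = []
    for aid in range(n_agents):
        x = cx + spread * rng.standard_normal(times.size)
        y = cy + spread * rng.standard_normal(times.size)
        rows.append(pd.DataFrame({"t": times, "id": aid, "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


_KINDS = {
    "gaussian_1d": gaussian_profile_1d,
    "uniform_disk_2d": uniform_disk_2d,
    "element_ring": element_ring,
    "synthetic_tracks": synthetic_tracks,
}


def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0):
    """Dispatch to the named generator; every kind is deterministic given
    (params, seed)."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    params = dict(params or {})
    fn = _KINDS[kind]
    if kind in ("uniform_disk_2d", "element_ring", "synthetic_tracks"):
        params.setdefault("seed", seed)
    return fn(**params)
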