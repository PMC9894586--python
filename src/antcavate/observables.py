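"""Summary statistics of excavation runs: coarse-grained densities, angular
and radial marginals, boundary-shape Fourier spectra, corral area series and
escape-time tables.

These operate on trajectory tables (columns t, id, x, y — the simulator's
output or externally tracked data), on continuum substrate fields, or on
discrete wall-element sets, and mirror the standard analysis of confined
collectives: a density localizing at one angle of the corral, a radial
density front propagating outward, and a boundary contour R(phi) whose
low-order Fourier modes count the tunnels being formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agents import FieldGrid, BoundaryElementSet, IN_WALL

__all__ = [
    "DensityField",
    "BoundaryShape",
    "coarse_grain_density",
    "marginal_profiles",
    "localization_index",
    "boundary_shape_spectrum",
    "corral_area_series",
    "escape_statistics",
    "boundary_from_substrate",
    "boundary_from_elements",
]


# --------------------------------------------------------------------------
# density estimation
# --------------------------------------------------------------------------

@dataclass
class DensityField:
    """Time-averaged agent density (counts per unit area) on a Cartesian
    grid; integrates to the mean number of agents in the window."""

    values: np.ndarray                 # (ny, nx)
    h: float
    origin: Tuple[float, float]
    window: Tuple[float, float]

    def integral(self) -> float:
        return float(self.values.sum()) * self.h * self.h

    def as_grid(self) -> FieldGrid:
        return FieldGrid(self.values, self.h, self.origin)


def coarse_grain_density(tracks: pd.DataFrame, window: Tuple[float, float],
                         extent: float = 6.0, nbins: int = 64,
                         center: Tuple[float, float] = (0.0, 0.0),
                         smooth_sigma: float = 0.0) -> DensityField:
    """2D histogram of agent positions averaged over the time frames in
    ``window``, normalized to counts per unit area.

    Averaging over a window longer than one task cycle (for the dimensional
    ant preset, 250 s) turns discrete positions into a smooth density whose
    integral equals the average number of agents present.  Optional Gaussian
    smoothing (sigma in length units) preserves the integral.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError(f"empty time window ({t0}, {t1})")
    sel = tracks[(tracks["t"] >= t0) & (tracks["t"] <= t1)]
    if sel.empty:
        raise ValueError(f"no track samples inside window ({t0}, {t1})")
    n_frames = sel["t"].nunique()
    edges = np.linspace(-extent, extent, nbins + 1)
    H, _, _ = np.histogram2d(sel["y"] - center[1], sel["x"] - center[0],
                             bins=(edges, edges))
    h = 2.0 * extent / nbins
    values = H / (n_frames * h * h)
    if smooth_sigma > 0.0:
        from scipy.ndimage import gaussian_filter
        values = gaussian_filter(values, smooth_sigma / h, mode="constant")
    origin = (center[0] - extent, center[1] - extent)
    return DensityField(values, h, origin, (t0, t1))


def _polar_resample(dens: DensityField, n_r: int = 64, n_phi: int = 256,
                    r_max: Optional[float] = None,
                    center: Tuple[float, float] = (0.0, 0.0),
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear resampling of the Cartesian density onto (r, phi) samples.
    Returns (r (n_r,), phi (n_phi,), rho (n_r, n_phi))."""
    if r_max is None:
        ny, nx = dens.values.shape
        r_max = 0.5 * min(nx, ny) * dens.h
    r = (np.arange(n_r) + 0.5) * (r_max / n_r)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi) - math.pi
    R, PHI = np.meshgrid(r, phi, indexing="ij")
    pts = np.stack([center[0] + R * np.cos(PHI), center[1] + R * np.sin(PHI)], axis=-1)
    grid = dens.as_grid()
    inside = grid.contains(pts)
    rho = np.zeros(R.shape)
    rho[inside] = grid._bilinear(dens.values, pts[inside])
    return r, phi, rho


def marginal_profiles(dens: DensityField, sector_half_width: float = math.pi / 12.0,
                      sector_center: Optional[float] = None,
                      n_r: int = 64, n_phi: int = 256,
                      r_max: Optional[float] = None,
                      kernel: str = "indicator",
                      ) -> Tuple[Tuple[np.ndarray, np.ndarray],
                                 Tuple[np.ndarray, np.ndarray]]:
    """Angular and radial marginals of a density field.

    P_phi(phi) = integral of rho r dr (so that its circular integral equals
    the field's domain integral); P_r(r) = integral of rho S(phi) dphi with
    S a normalized sector kernel centered on the excavation site (default:
    the argmax of P_phi; half-width pi/12, i.e. a pi/6 sector — a robot
    preset would use pi/2).  ``kernel`` is "indicator" or "cosine" (tapered).

    Returns ((phi, P_phi), (r, P_r)).
    """
    if sector_half_width > math.pi:
        raise ValueError("sector wider than 2 pi")
    r, phi, rho = _polar_resample(dens, n_r, n_phi, r_max)
    dr = r[1] - r[0]
    dphi = phi[1] - phi[0]
    P_phi = (rho * r[:, None]).sum(axis=0) * dr
    if sector_center is None:
        sector_center = float(phi[np.argmax(P_phi)])
    dang = np.angle(np.exp(1j * (phi - sector_center)))
    if kernel == "indicator":
        S = (np.abs(dang) <= sector_half_width).astype(float)
    elif kernel == "cosine":
        S = np.where(np.abs(dang) <= sector_half_width,
                     0.5 * (1.0 + np.cos(math.pi * dang / sector_half_width)), 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    norm = S.sum() * dphi
    if norm <= 0.0:
        raise ValueError("sector kernel has zero mass")
    S = S / norm
    P_r = (rho * S[None, :]).sum(axis=1) * dphi
    return (phi, P_phi), (r, P_r)


def localization_index(dens_or_Pphi, **kwargs) -> float:
    """Peak-to-mean ratio of the angular marginal P_phi: ~1 for an isotropic
    collective, large for a localized (or jammed) one."""
    if isinstance(dens_or_Pphi, DensityField):
        (_, P_phi), _ = marginal_profiles(dens_or_Pphi, **kwargs)
    else:
        P_phi = np.asarray(dens_or_Pphi, dtype=float)
    mean = P_phi.mean()
    if mean <= 0.0:
        return 1.0
    return float(P_phi.max() / mean)


# --------------------------------------------------------------------------
# boundary shape
# --------------------------------------------------------------------------

@dataclass
class BoundaryShape:
    """Corral boundary radius sampled at m uniform angles in [0, 2 pi)."""

    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.R <= 0.0):
            raise ValueError("boundary radius must be positive everywhere")

    @property
    def m(self) -> int:
        return self.R.size

    def fourier_coefficients(self) -> np.ndarray:
        """R_hat(k) = (1/m) sum_j R_j exp(-i k phi_j); conjugate-symmetric
        for the real signal."""
        return np.fft.fft(self.R) / self.m


def boundary_shape_spectrum(shape: BoundaryShape, K: int = 5) -> np.ndarray:
    """Power |R_hat(k)|^2 of the first K+1 Fourier modes (k = 0 .. K).

    For a circle all power sits at k=0 (|R_hat(0)|^2 = R0^2); a two-lobed
    (elliptic) deformation R0 (1 + eps cos 2 phi) carries (R0 eps / 2)^2 at
    k = 2 — the mode that counts a single localized tunnel.
    """
    if K + 1 > shape.m:
        raise ValueError(f"K={K} needs at least {K + 1} samples, got {shape.m}")
    coeff = shape.fourier_coefficients()
    return np.abs(coeff[:K + 1]) ** 2


def corral_area_series(shapes: Sequence[BoundaryShape], R0: float) -> pd.DataFrame:
    """Enclosed area of each boundary contour, normalized by pi R0^2.

    The area is the polar quadrature (1/2) closed-integral R(phi)^2 dphi on
    the uniform angular grid (spectrally accurate for smooth contours and
    exact for band-limited ones); the untouched circle gives exactly 1.
    A non-finite or non-positive sample flags the frame instead of failing.
    """
    rows = []
    for s in shapes:
        ok = bool(np.all(np.isfinite(s.R)) and np.all(s.R > 0.0))
        area = 0.5 * float(np.sum(s.R ** 2)) * (2.0 * math.pi / s.m)
        rows.append({"t": s.t, "area_ratio": area / (math.pi * R0 * R0), "valid": ok})
    return pd.DataFrame(rows)


def boundary_from_substrate(rho_s: np.ndarray, h: float, origin: Tuple[float, float],
                            center: Tuple[float, float] = (0.0, 0.0),
                            threshold: float = 0.5, m: int = 256,
                            r_max: Optional[float] = None, t: float = 0.0,
                            ) -> BoundaryShape:
    """Extract R(phi): along each ray, the first radius at which the
    substrate density reaches ``threshold`` (the cavity wall); rays that
    never reach it (a finished tunnel) extend to ``r_max``."""
    ny, nx = rho_s.shape
    if r_max is None:
        r_max = 0.5 * min(nx, ny) * h
    grid = FieldGrid(rho_s, h, origin)
    phi = (np.arange(m) + 0.5) * (2.0 * math.pi / m) - math.pi
    n_r = max(ny, nx)
    r = np.linspace(0.5 * h, r_max, n_r)
    R, PHI = np.meshgrid(r, phi, indexing="ij")
    pts = np.stack([center[0] + R * np.cos(PHI), center[1] + R * np.sin(PHI)], axis=-1)
    inside = grid.contains(pts)
    vals = np.zeros(R.shape)
    vals[inside] = grid._bilinear(rho_s, pts[inside])
    wall = vals >= threshold
    first = np.argmax(wall, axis=0)
    Rphi = np.where(wall.any(axis=0), r[first], r_max)
    return BoundaryShape(Rphi, t=t)


def boundary_from_elements(elements: BoundaryElementSet, m: int = 64,
                           r_max: float = 5.0,
                           center: Tuple[float, float] = (0.0, 0.0),
                           t: float = 0.0) -> BoundaryShape:
    """Cavity boundary from discrete wall elements: per angular bin, the
    innermost in-wall element radius (element surface); empty bins — where
    the wall has been carried away — extend to ``r_max``."""
    pos = elements.positions[elements.state == IN_WALL] - np.asarray(center)
    Rphi = np.full(m, float(r_max))
    if pos.size:
        ang = np.arctan2(pos[:, 1], pos[:, 0])
        rad = np.hypot(pos[:, 0], pos[:, 1]) - elements.radius
        bins = ((ang + math.pi) / (2.0 * math.pi) * m).astype(int) % m
        for b, rr in zip(bins, rad):
            if rr < Rphi[b]:
                Rphi[b] = max(rr, 1e-9)
    return BoundaryShape(Rphi, t=t)


# --------------------------------------------------------------------------
# escape statistics
# --------------------------------------------------------------------------

def escape_statistics(results: Iterable, ts: float,
                      group_keys: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-run scaled escape times T/ts with censoring flags.

    ``results`` is an iterable of AgentRunResult (censored runs contribute
    T = Tstop); ``group_keys`` optionally labels each run (e.g. the
    cooperation parameter of a sweep), and per-group mean and median T/ts
    are attached as columns.
    """
    if not ts > 0.0:
        raise ValueError("ts must be positive")
    rows = []
    for i, res in enumerate(results):
        key = group_keys[i] if group_keys is not None else None
        rows.append({"run": i, "group": key, "T": res.T,
                     "T_over_ts": res.T / ts, "censored": res.censored})
    df = pd.DataFrame(rows)
    if group_keys is not None:
        g = df.groupby("group")["T_over_ts"]
        df["group_mean"] = df["group"].map(g.mean())
        df["group_median"] = df["group"].map(g.median())
    return df
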