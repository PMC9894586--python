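"""Finite-difference solver for the nondimensional continuum excavation model.

Three coupled fields on a shared grid (1D interval or 2D square lattice):

    d/dt rho_a = lap(rho_a) - div[(C grad c + V (1 - rho_s) phat) rho_a]
    d/dt c     = Dc_hat lap(c) + k_hat rho_a - c
    d/dt rho_s = -(E/4) rho_s (1 + tanh[alpha_c (c - c*)])
                              (1 + tanh[alpha_rho (rho_a - rho_a*)])

``rho_a`` is the (conserved) agent density, ``c`` the self-generated
communication field, ``rho_s`` the erodible substrate in [0, 1].  ``phat``
is the preferred migration direction: +x in 1D, radially outward in 2D
(zero within one cell of the corral center, where it is singular).

Numerics: conservative finite-volume fluxes with first-order upwinding for
advection and second-order stencils for diffusion, no-flux boundaries for
rho_a and c on the outer square boundary, explicit Euler (or midpoint RK2)
time stepping with an adaptive step bounded by both the diffusive and the
advective (CFL) stability limits.  Positivity and exact discrete mass
conservation are preferred over formal order of accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .params import Geometry, NonDimGroups

__all__ = [
    "ContinuumState",
    "ContinuumConfig",
    "continuum_rhs",
    "integrate_continuum",
    "breakthrough_time",
    "has_breakthrough",
]


# --------------------------------------------------------------------------
# state & config
# --------------------------------------------------------------------------

@dataclass
class ContinuumState:
    """The field triple at one instant.

    Arrays share a shape: (nx,) in 1D or (ny, nx) in 2D.  ``origin`` is the
    coordinate of the *corner* of the first cell; cell centers sit at
    origin + (i + 1/2) h.
    """

    rho_a: np.ndarray
    c: np.ndarray
    rho_s: np.ndarray
    t: float
    h: float
    origin: Tuple[float, ...] = (0.0,)

    @property
    def ndim(self) -> int:
        return self.rho_a.ndim

    def cell_centers(self) -> Tuple[np.ndarray, ...]:
        """Per-axis 1D arrays of cell-center coordinates (x last)."""
        out = []
        # origin stored x-first; array axes are (y, x) in 2D
        for ax in range(self.ndim):
            n = self.rho_a.shape[self.ndim - 1 - ax]
            out.append(self.origin[ax] + (np.arange(n) + 0.5) * self.h)
        return tuple(out)

    def copy(self) -> "ContinuumState":
        return ContinuumState(self.rho_a.copy(), self.c.copy(), self.rho_s.copy(),
                              self.t, self.h, self.origin)

    def total_mass(self) -> float:
        return float(self.rho_a.sum()) * self.h ** self.ndim


@dataclass
class ContinuumConfig:
    """Run controls for :func:`integrate_continuum`.

    1D runs live on [0, domain_length] with the substrate block occupying
    ``substrate_interval``; 2D runs live on the square
    [-domain_half_width, +domain_half_width]^2 with the substrate filling the
    annulus Ri <= r <= Ro of ``geometry``.
    """

    groups: NonDimGroups = field(default_factory=NonDimGroups)
    ndim: int = 1
    geometry: Optional[Geometry] = None        # 2D only
    domain_length: float = 1.0                 # 1D only
    substrate_interval: Tuple[float, float] = (0.6, 0.85)  # 1D only
    nx: int = 256
    ic_name: str = "gaussian_1d"               # or "uniform_disk_2d"
    ic_params: dict = field(default_factory=dict)
    noise_amp: float = 0.0                     # relative IC noise on rho_a
    seed: int = 0
    dt: Optional[float] = None                 # None -> adaptive from stability bounds
    dt_safety: float = 0.4
    t_end: float = 10.0
    snapshot_dt: float = 0.5
    integrator: str = "euler"                  # or "rk2"
    breakthrough_threshold: float = 0.5
    stop_on_breakthrough: bool = False

    def __post_init__(self) -> None:
        if self.ndim not in (1, 2):
            raise ValueError("ndim must be 1 or 2")
        if self.ndim == 2 and self.geometry is None:
            self.geometry = Geometry()
        if self.integrator not in ("euler", "rk2"):
            raise ValueError(f"unknown integrator {self.integrator!r}")


# --------------------------------------------------------------------------
# initial conditions
# --------------------------------------------------------------------------

def _initial_state(cfg: ContinuumConfig) -> Tuple[ContinuumState, np.ndarray]:
    """Build the t=0 state and the migration direction field ``phat``
    (shape (ndim,) + grid shape, x component first)."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.ndim == 1:
        h = cfg.domain_length / cfg.nx
        x = (np.arange(cfg.nx) + 0.5) * h
        name = cfg.ic_name or "gaussian_1d"
        if name == "gaussian_1d":
            p = cfg.ic_params
            center = p.get("center", 0.5)
            width = p.get("width", 0.08)
            amp = p.get("amplitude", 1.0)
            rho_a = amp * np.exp(-0.5 * ((x - center) / width) ** 2)
        elif name == "uniform_1d":
            rho_a = np.full(cfg.nx, cfg.ic_params.get("amplitude", 1.0))
        else:
            raise ValueError(f"unknown 1D initial condition {name!r}")
        if cfg.noise_amp > 0.0:
            rho_a = rho_a * (1.0 + cfg.noise_amp * rng.standard_normal(cfg.nx))
            np.clip(rho_a, 0.0, None, out=rho_a)
        lo, hi = cfg.substrate_interval
        rho_s = ((x >= lo) & (x <= hi)).astype(float)
        c0 = cfg.ic_params.get("c0", 0.0) * np.ones_like(x)
        state = ContinuumState(rho_a, c0, rho_s, 0.0, h, (0.0,))
        phat = np.ones((1, cfg.nx))
        return state, phat

    geom = cfg.geometry
    L = geom.domain_half_width
    h = 2.0 * L / cfg.nx
    xc = -L + (np.arange(cfg.nx) + 0.5) * h
    X, Y = np.meshgrid(xc, xc)      # arrays indexed (y, x)
    X = X - geom.center[0]
    Y = Y - geom.center[1]
    R = np.hypot(X, Y)
    name = cfg.ic_name or "uniform_disk_2d"
    if name == "uniform_disk_2d":
        amp = cfg.ic_params.get("amplitude", 1.0)
        rho_a = amp * (R < geom.Ri).astype(float)
    else:
        raise ValueError(f"unknown 2D initial condition {name!r}")
    if cfg.noise_amp > 0.0:
        rho_a = rho_a * (1.0 + cfg.noise_amp * rng.standard_normal(rho_a.shape))
        np.clip(rho_a, 0.0, None, out=rho_a)
    rho_s = ((R >= geom.Ri) & (R <= geom.Ro)).astype(float)
    c0 = cfg.ic_params.get("c0", 0.0) * np.ones_like(rho_a)
    state = ContinuumState(rho_a, c0, rho_s, 0.0, h, (-L, -L))
    # radial unit vector: regularized at the center and zero beyond the
    # corral (outward migration models digging toward the outside; past the
    # outer edge there is nothing left to migrate toward)
    inside = (R > h) & (R <= geom.Ro)
    with np.errstate(invalid="ignore", divide="ignore"):
        px = np.where(inside, X / R, 0.0)
        py = np.where(inside, Y / R, 0.0)
    phat = np.stack([px, py])
    return state, phat


# --------------------------------------------------------------------------
# spatial operators
# --------------------------------------------------------------------------

def _diff_faces(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """(f[i+1]-f[i])/h on interior faces along ``axis``."""
    return np.diff(f, axis=axis) / h


def _avg_faces(f: np.ndarray, axis: int) -> np.ndarray:
    sl_lo = [slice(None)] * f.ndim
    sl_hi = [slice(None)] * f.ndim
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    return 0.5 * (f[tuple(sl_lo)] + f[tuple(sl_hi)])


def _div_from_faces(F: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Divergence contribution from interior-face fluxes, with zero flux on
    the two boundary faces of ``axis`` (the no-flux condition)."""
    pad = [(0, 0)] * F.ndim
    pad[axis] = (1, 1)
    Fp = np.pad(F, pad)
    return np.diff(Fp, axis=axis) / h


def _laplacian_noflux(f: np.ndarray, h: float) -> np.ndarray:
    out = np.zeros_like(f)
    for axis in range(f.ndim):
        grad = _diff_faces(f, axis, h)   # diffusive flux = -grad
        out += _div_from_faces(grad, axis, h)
    return out


def _face_velocities(state: ContinuumState, groups: NonDimGroups,
                     phat: np.ndarray) -> List[np.ndarray]:
    """Advection velocity C grad c + V (1 - rho_s) phat on interior faces,
    one array per grid axis (axis order matches numpy axes: y first in 2D)."""
    h = state.h
    nd = state.ndim
    one_minus_s = 1.0 - state.rho_s
    vels = []
    for axis in range(nd):
        # x component corresponds to the *last* numpy axis
        comp = phat[nd - 1 - axis]
        u = groups.C * _diff_faces(state.c, axis, h) \
            + groups.V * _avg_faces(one_minus_s * comp, axis)
        vels.append(u)
    return vels


def _advective_div(rho: np.ndarray, vels: Sequence[np.ndarray], h: float) -> np.ndarray:
    """div(u rho) with first-order upwinding on interior faces, no-flux edges."""
    out = np.zeros_like(rho)
    for axis, u in enumerate(vels):
        sl_lo = [slice(None)] * rho.ndim
        sl_hi = [slice(None)] * rho.ndim
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        up = np.maximum(u, 0.0)
        un = np.minimum(u, 0.0)
        F = up * rho[tuple(sl_lo)] + un * rho[tuple(sl_hi)]
        out += _div_from_faces(F, axis, h)
    return out


def erosion_rate(c: np.ndarray, rho_a: np.ndarray, groups: NonDimGroups) -> np.ndarray:
    """Pointwise erosion rate (E/4)(1+tanh[ac(c-c*)])(1+tanh[ar(rho_a-rho_a*)])."""
    g = groups
    return 0.25 * g.E \
        * (1.0 + np.tanh(g.alpha_c * (c - g.c_star))) \
        * (1.0 + np.tanh(g.alpha_rho * (rho_a - g.rho_a_star)))


def _check_finite(state: ContinuumState) -> None:
    for name, f in (("rho_a", state.rho_a), ("c", state.c), ("rho_s", state.rho_s)):
        if not np.all(np.isfinite(f)):
            bad = np.argwhere(~np.isfinite(f))[0]
            raise FloatingPointError(
                f"non-finite value in {name} at index {tuple(int(i) for i in bad)}, "
                f"t={state.t:g}")


def _rhs_from_vels(state: ContinuumState, groups: NonDimGroups,
                   vels: Sequence[np.ndarray],
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    h = state.h
    d_rho_a = _laplacian_noflux(state.rho_a, h) - _advective_div(state.rho_a, vels, h)
    d_c = groups.Dc_hat * _laplacian_noflux(state.c, h) + groups.k_hat * state.rho_a - state.c
    d_rho_s = -erosion_rate(state.c, state.rho_a, groups) * state.rho_s
    return d_rho_a, d_c, d_rho_s


def continuum_rhs(state: ContinuumState, groups: NonDimGroups,
                  phat: Optional[np.ndarray] = None,
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (d rho_a, d c, d rho_s) of the three fields.

    ``phat`` defaults to +x in 1D; it must be supplied in 2D (the radial
    direction field is tied to the corral geometry).
    """
    _check_finite(state)
    if phat is None:
        if state.ndim != 1:
            raise ValueError("phat must be supplied for 2D states")
        phat = np.ones((1,) + state.rho_a.shape)
    vels = _face_velocities(state, groups, phat)
    return _rhs_from_vels(state, groups, vels)


# --------------------------------------------------------------------------
# time integration
# --------------------------------------------------------------------------

def _stable_dt(state: ContinuumState, groups: NonDimGroups,
               vels: Sequence[np.ndarray], safety: float) -> float:
    h = state.h
    nd = state.ndim
    d_max = max(1.0, groups.Dc_hat)
    dt = safety * h * h / (2.0 * nd * d_max)
    umax = max((float(np.abs(u).max()) for u in vels), default=0.0)
    if umax > 0.0:
        dt = min(dt, safety * h / umax)
    # erosion and field relaxation rates are O(E), O(1): keep dt below them too
    dt = min(dt, safety / max(1.0, groups.E))
    return dt


def integrate_continuum(cfg: ContinuumConfig) -> List[ContinuumState]:
    """Integrate the model from t=0 to ``cfg.t_end``; return snapshots.

    Snapshots are taken at (approximately) every ``cfg.snapshot_dt`` time
    units, always including the initial and final states.  With
    ``stop_on_breakthrough`` the run ends at the first snapshot whose
    substrate field contains a connected excavated path spanning the corral.
    Substrate positivity and monotone erosion hold by construction; rho_a
    and c are never projected.  A NaN/Inf anywhere aborts with the last
    good time in the error message.
    """
    state, phat = _initial_state(cfg)
    groups = cfg.groups
    snaps = [state.copy()]
    next_snap = cfg.snapshot_dt
    geom = _breakthrough_geometry(cfg)
    with np.errstate(over="ignore", invalid="ignore"):
        return _integrate_loop(cfg, state, phat, groups, snaps, next_snap, geom)


def _integrate_loop(cfg, state, phat, groups, snaps, next_snap, geom):
    while state.t < cfg.t_end - 1e-12:
        vels = _face_velocities(state, groups, phat)
        dt = cfg.dt if cfg.dt is not None else _stable_dt(state, groups, vels, cfg.dt_safety)
        if not math.isfinite(dt) or dt <= 0.0:
            raise FloatingPointError(
                f"integration diverged (last good t={snaps[-1].t:g}): "
                f"non-finite step size")
        dt = min(dt, cfg.t_end - state.t, next_snap - state.t + 1e-12)
        if cfg.integrator == "euler":
            da, dc, ds = _rhs_from_vels(state, groups, vels)
            state.rho_a += dt * da
            state.c += dt * dc
            state.rho_s += dt * ds
        else:  # rk2 (midpoint)
            da, dc, ds = _rhs_from_vels(state, groups, vels)
            mid = ContinuumState(state.rho_a + 0.5 * dt * da,
                                 state.c + 0.5 * dt * dc,
                                 state.rho_s + 0.5 * dt * ds,
                                 state.t + 0.5 * dt, state.h, state.origin)
            mvels = _face_velocities(mid, groups, phat)
            da, dc, ds = _rhs_from_vels(mid, groups, mvels)
            state.rho_a += dt * da
            state.c += dt * dc
            state.rho_s += dt * ds
        np.clip(state.rho_s, 0.0, 1.0, out=state.rho_s)  # guards Euler round-off only
        state.t += dt
        if state.t >= next_snap - 1e-9:
            try:
                _check_finite(state)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"integration diverged (last good t={snaps[-1].t:g}): {err}") from err
            snaps.append(state.copy())
            next_snap += cfg.snapshot_dt
            if cfg.stop_on_breakthrough and geom is not None and \
                    has_breakthrough(state, geom, cfg.breakthrough_threshold):
                return snaps
    if snaps[-1].t < state.t - 1e-12:
        snaps.append(state.copy())
    return snaps


def _breakthrough_geometry(cfg: ContinuumConfig):
    if cfg.ndim == 2:
        return cfg.geometry
    return cfg.substrate_interval


# --------------------------------------------------------------------------
# breakthrough detection
# --------------------------------------------------------------------------

def has_breakthrough(state: ContinuumState, geometry, threshold: float = 0.5) -> bool:
    """True if {rho_s < threshold} contains a connected path joining the
    inner corral edge to the outer edge (4-connectivity in 2D)."""
    passable = state.rho_s < threshold
    if state.ndim == 1:
        lo, hi = geometry
        (x,) = state.cell_centers()
        labels, _ = ndimage.label(passable)
        inner = labels[x < lo]
        outer = labels[x > hi]
        inner = set(inner[inner > 0].tolist())
        outer = set(outer[outer > 0].tolist())
        return bool(inner & outer)
    geom: Geometry = geometry
    x, y = state.cell_centers()
    X, Y = np.meshgrid(x, y)
    R = np.hypot(X - geom.center[0], Y - geom.center[1])
    labels, _ = ndimage.label(passable)  # default structure = 4-connectivity
    inner = labels[(R < geom.Ri - 2 * state.h) & passable]
    outer = labels[(R > geom.Ro + 2 * state.h) & passable]
    inner = set(np.unique(inner[inner > 0]).tolist())
    outer = set(np.unique(outer[outer > 0]).tolist())
    return bool(inner & outer)


def breakthrough_time(snapshots: Sequence[ContinuumState], geometry,
                      threshold: float = 0.5) -> Optional[float]:
    """Earliest snapshot time with a spanning excavated path, or None
    (censored) if none exists.  ``geometry`` is a :class:`Geometry` in 2D or
    the 1D substrate interval (lo, hi)."""
    if not snapshots:
        raise ValueError("empty snapshot list")
    for s in snapshots:
        if has_breakthrough(s, geometry, threshold):
            return s.t
    return None
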