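"""Linear stability of the homogeneous excavating state.

The homogeneous state (rho_a_ss, c_ss, rho_s_ss = 1), with the field in
production/decay balance c_ss = k_hat * rho_a_ss, is perturbed with a plane
wave exp(i k x + Omega t).  The linearized dynamics in Fourier space is a
3x3 complex operator acting on the amplitudes (rho_a~, c~, rho_s~):

    density row    [-k^2,  C rho_a_ss k^2,  i k V rho_a_ss]
    field row      [k_hat, -(1 + Dc_hat k^2),  0]
    substrate row  [0, 0, -E/2]

The substrate branch decays at Omega = -E/2 independently of the wavenumber
and of every other parameter: excavation, once triggered, proceeds at a rate
set only by E.  The -E/2 entry corresponds to linearizing the smoothed
threshold erosion law with the density switch saturated (the collective well
above its density threshold) and the field switch at its midpoint; the
sharp-threshold delta terms are dropped.  :func:`measured_growth_rate`
verifies each branch against the full nonlinear solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence
import warnings

import numpy as np

from .continuum import ContinuumConfig, ContinuumState, integrate_continuum
from .params import NonDimGroups

__all__ = [
    "LinearizationPoint",
    "DispersionResult",
    "assemble_linear_operator",
    "growth_rates",
    "measured_growth_rate",
]

BRANCHES = ("density", "field", "substrate")


@dataclass
class LinearizationPoint:
    """Homogeneous base state for the plane-wave linearization.

    By default ``rho_a_ss`` is the density threshold and ``c_ss`` is derived
    from the production/decay balance c_ss = k_hat * rho_a_ss; overriding
    ``c_ss`` breaks that balance and triggers a warning.
    """

    groups: NonDimGroups = field(default_factory=NonDimGroups)
    rho_a_ss: Optional[float] = None
    c_ss: Optional[float] = None
    rho_s_ss: float = 1.0

    def __post_init__(self) -> None:
        if self.rho_a_ss is None:
            self.rho_a_ss = self.groups.rho_a_star
        balance = self.groups.k_hat * self.rho_a_ss
        if self.c_ss is None:
            self.c_ss = balance
        elif not math.isclose(self.c_ss, balance, rel_tol=1e-9, abs_tol=1e-12):
            warnings.warn(
                f"c_ss={self.c_ss:g} overrides the production/decay balance "
                f"k_hat*rho_a_ss={balance:g}; the base state is not steady",
                stacklevel=2)


@dataclass
class DispersionResult:
    """Growth rates on a wavenumber grid, one complex rate per branch."""

    k: np.ndarray
    omega: Dict[str, np.ndarray]      # branch -> complex array, same length as k
    defective: bool = False           # True if eigenvectors were ill-conditioned

    def max_real(self, branch: str) -> float:
        return float(self.omega[branch].real.max())


def assemble_linear_operator(point: LinearizationPoint, k: float) -> np.ndarray:
    """The 3x3 Fourier-space Jacobian at wavenumber ``k`` (complex)."""
    g = point.groups
    k2 = k * k
    rho0 = point.rho_a_ss
    M = np.zeros((3, 3), dtype=complex)
    M[0, 0] = -k2
    M[0, 1] = g.C * rho0 * k2
    M[0, 2] = 1j * k * g.V * rho0
    M[1, 0] = g.k_hat
    M[1, 1] = -(1.0 + g.Dc_hat * k2)
    M[2, 2] = -0.5 * g.E
    return M


def _label_branches(vals: np.ndarray, vecs: np.ndarray) -> Dict[str, complex]:
    """Assign the three eigenvalues to branches by eigenvector dominance,
    via optimal assignment on component magnitudes."""
    from scipy.optimize import linear_sum_assignment

    weight = np.abs(vecs)                       # rows: variable, cols: eigenvector
    weight = weight / np.maximum(weight.sum(axis=0, keepdims=True), 1e-300)
    row, col = linear_sum_assignment(-weight.T)  # eigenvector -> variable
    out: Dict[str, complex] = {}
    for eig_idx, var_idx in zip(row, col):
        out[BRANCHES[var_idx]] = complex(vals[eig_idx])
    return out


def growth_rates(point: LinearizationPoint, k_grid: Sequence[float]) -> DispersionResult:
    """Eigendecompose the linear operator over ``k_grid``; branches labeled
    by eigenvector dominance (density / field / substrate)."""
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    omega = {b: np.empty(k_grid.size, dtype=complex) for b in BRANCHES}
    defective = False
    for i, k in enumerate(k_grid):
        M = assemble_linear_operator(point, float(k))
        try:
            vals, vecs = np.linalg.eig(M)
            if np.linalg.cond(vecs) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned eigenvectors")
        except np.linalg.LinAlgError:
            from scipy.linalg import schur
            T, _ = schur(M, output="complex")
            vals = np.diag(T)
            vecs = np.eye(3, dtype=complex)
            defective = True
            warnings.warn(f"defective linear operator at k={k:g}; "
                          "falling back to Schur values", stacklevel=2)
        labeled = _label_branches(vals, vecs)
        for b in BRANCHES:
            omega[b][i] = labeled[b]
    return DispersionResult(k=k_grid, omega=omega, defective=defective)


# --------------------------------------------------------------------------
# numerical verification against the nonlinear solver
# --------------------------------------------------------------------------

_BRANCH_FIELD = {"density": "rho_a", "field": "c", "substrate": "rho_s"}


def _perturbed_run(groups: NonDimGroups, branch: str, k: float, eps: float,
                   rho_a_ss: float, t_end: float, nx: int) -> tuple:
    """Integrate from the homogeneous state plus eps*cos(kx) on one field;
    return (times, complex mode amplitudes of the perturbed field)."""
    L = 1.0
    n_half = max(1, round(k * L / math.pi))
    k_eff = n_half * math.pi / L              # Neumann-compatible wavenumber
    h = L / nx
    x = (np.arange(nx) + 0.5) * h
    base = {
        "rho_a": np.full(nx, rho_a_ss),
        "c": np.full(nx, groups.k_hat * rho_a_ss),
        "rho_s": np.ones(nx),
    }
    fname = _BRANCH_FIELD[branch]
    base[fname] = base[fname] + eps * np.cos(k_eff * x)
    state = ContinuumState(base["rho_a"], base["c"], base["rho_s"], 0.0, h, (0.0,))
    phat = np.ones((1, nx))

    from .continuum import continuum_rhs, _stable_dt, _face_velocities

    times = [0.0]
    mode = np.cos(k_eff * x)
    norm = 0.5 * nx                            # sum(cos^2) on a half-period grid
    amps = [float(np.dot(getattr(state, fname), mode)) / norm]
    while state.t < t_end:
        vels = _face_velocities(state, groups, phat)
        dt = min(_stable_dt(state, groups, vels, 0.3), t_end - state.t)
        da, dc, ds = continuum_rhs(state, groups, phat)
        state.rho_a += dt * da
        state.c += dt * dc
        state.rho_s += dt * ds
        state.t += dt
        times.append(state.t)
        amps.append(float(np.dot(getattr(state, fname), mode)) / norm)
    return np.asarray(times), np.asarray(amps), k_eff


def _fit_rate(times: np.ndarray, amps: np.ndarray) -> float:
    good = np.abs(amps) > 1e-14
    if good.sum() < 3:
        raise RuntimeError("perturbation amplitude vanished; cannot fit a rate")
    slope = np.polyfit(times[good], np.log(np.abs(amps[good])), 1)[0]
    return float(slope)


def measured_growth_rate(groups: NonDimGroups, k: float, eps: float = 1e-4,
                         branch: str = "substrate", t_end: Optional[float] = None,
                         nx: int = 128, linearity_tol: float = 0.02) -> float:
    """Growth rate of a small cos(kx) perturbation measured from the full
    nonlinear solver (log-amplitude slope over an early window).

    The base state puts the communication field exactly at its threshold
    (c_star = c_ss) with the collective above its density threshold, the
    configuration whose substrate branch decays at -E/2.  Each branch is
    measured in its decoupled configuration: the substrate branch with V=0
    (its row in the linear operator is diagonal; V only feeds the substrate
    perturbation *into* the density equation), the density and field
    branches with E=0 (substrate frozen, the Keller-Segel subsystem).
    Linearity is checked by halving ``eps``; a relative change beyond
    ``linearity_tol`` raises with advice to reduce ``eps``.
    """
    if branch not in BRANCHES:
        raise ValueError(f"branch must be one of {BRANCHES}")
    g = NonDimGroups(**{**groups.to_dict()})
    if branch == "substrate":
        g.V = 0.0
    else:
        g.E = 0.0
    rho_a_ss = max(1.0, 2.0 * g.rho_a_star + 0.5)   # density switch saturated
    g.c_star = g.k_hat * rho_a_ss                    # field switch at midpoint
    if t_end is None:
        # a window over which the branch amplitude changes by O(10%)
        scale = abs(0.5 * g.E) if branch == "substrate" else 1.0
        t_end = 0.2 / max(scale, 0.5)
    rate = _fit_rate(*_perturbed_run(g, branch, k, eps, rho_a_ss, t_end, nx)[:2])
    rate_half = _fit_rate(*_perturbed_run(g, branch, k, 0.5 * eps, rho_a_ss, t_end, nx)[:2])
    denom = max(abs(rate), 1e-12)
    if abs(rate - rate_half) / denom > linearity_tol:
        raise RuntimeError(
            f"nonlinear response detected (rate {rate:g} vs {rate_half:g} at eps/2); "
            "reduce eps")
    return rate
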