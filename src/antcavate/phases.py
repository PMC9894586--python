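"""Classification of run outcomes into the four collective phases and the
(C, E) phase-diagram sweep.

The phase space of cooperative excavation is spanned by the cooperation
parameter C (gradient following vs diffusion) and the excavation rate E:
low C and E give a diffused, non-functional collective; high C with
vanishing E gives a jammed collective focused on its own communication
field; high E with low C gives shallow, delocalized partial tunnels; high C
and E give coordinated excavation — a breakthrough tunnel spanning the
corral.  ``regime_limit_check`` verifies the asymptotic reductions of the
model in the decay-, diffusion- and chemotaxis-dominated limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .continuum import (ContinuumConfig, ContinuumState, breakthrough_time,
                        integrate_continuum)
from .observables import DensityField, localization_index
from .params import NonDimGroups

__all__ = [
    "OutcomeRecord",
    "PhaseThresholds",
    "classify_outcome",
    "calibration_sweep_config",
    "sweep_phase_diagram",
    "regime_limit_check",
    "PHASES",
]

PHASES = ("coordinated_excavation", "partial_tunneling", "jammed", "diffused")


@dataclass
class PhaseThresholds:
    """Classification thresholds (config keys, not fitted quantities):
    a run with breakthrough is coordinated; else removed substrate mass
    fraction > ``removed_mass`` means partial tunneling; else a density
    focusing index > ``localization`` means jammed (the collective has
    collapsed onto its own communication field); else diffused."""

    removed_mass: float = 0.1
    localization: float = 3.0
    breakthrough: float = 0.5


@dataclass
class OutcomeRecord:
    phase: str
    breakthrough_time: Optional[float]   # None when censored
    removed_fraction: float
    localization: float                  # focusing index used for the label
    angular_localization: float = 1.0    # peak/mean of the angular marginal
    C: float = 0.0
    E: float = 0.0
    seed: int = 0
    error: Optional[str] = None


def _metrics_from_snapshots(snapshots: Sequence[ContinuumState], geometry,
                            thresholds: PhaseThresholds,
                            ) -> Tuple[Optional[float], float, float, float]:
    first, last = snapshots[0], snapshots[-1]
    tb = breakthrough_time(snapshots, geometry, thresholds.breakthrough)
    m0 = float(first.rho_s.sum())
    removed = 1.0 - float(last.rho_s.sum()) / m0 if m0 > 0 else 0.0
    # focusing index: amplification of the density maximum over the run —
    # the signature of chemotactic collapse; a diffusing collective has <= 1
    peak0 = max(float(first.rho_a.max()), 1e-300)
    focus = float(last.rho_a.max()) / peak0
    if last.ndim == 2:
        dens = DensityField(last.rho_a, last.h,
                            (last.origin[0], last.origin[1]), (first.t, last.t))
        ang = localization_index(dens)
    else:
        P = last.rho_a
        ang = float(P.max() / P.mean()) if P.mean() > 0 else 1.0
    return tb, removed, focus, ang


def classify_outcome(snapshots: Sequence[ContinuumState], geometry,
                     groups: NonDimGroups,
                     thresholds: Optional[PhaseThresholds] = None,
                     seed: int = 0) -> OutcomeRecord:
    """Deterministic phase label from the metrics of one continuum run."""
    if not snapshots:
        raise ValueError("classify_outcome needs at least one snapshot")
    thresholds = thresholds or PhaseThresholds()
    tb, removed, focus, ang = _metrics_from_snapshots(snapshots, geometry, thresholds)
    if tb is not None:
        phase = "coordinated_excavation"
    elif removed > thresholds.removed_mass:
        phase = "partial_tunneling"
    elif focus > thresholds.localization:
        phase = "jammed"
    else:
        phase = "diffused"
    return OutcomeRecord(phase, tb, removed, focus, ang, groups.C, groups.E, seed)


def calibration_sweep_config(nx: int = 64, t_end: float = 25.0,
                             seed: int = 1) -> ContinuumConfig:
    """Base configuration of the (C, E) calibration sweep: the annular
    corral with a sparser, more strongly migrating collective than the
    tunneling preset (amplitude 1.0, V = 1.5, a sharper field halo
    Dc_hat = 0.5 and thresholds 0.35) — chosen so that the four corner
    outcomes (diffused / jammed / partial / coordinated) are robustly
    separated at modest resolution."""
    groups = NonDimGroups(V=1.5, Dc_hat=0.5, c_star=0.35, rho_a_star=0.35)
    return ContinuumConfig(
        groups=groups, ndim=2, geometry=None, nx=nx,
        ic_name="uniform_disk_2d", ic_params={"amplitude": 1.0},
        noise_amp=0.01, seed=seed, t_end=t_end, snapshot_dt=1.0,
        stop_on_breakthrough=True)


def sweep_phase_diagram(base_cfg: ContinuumConfig, C_values: Sequence[float],
                        E_values: Sequence[float], seeds: Sequence[int] = (0,),
                        thresholds: Optional[PhaseThresholds] = None,
                        ) -> pd.DataFrame:
    """Run the continuum engine over the (C, E) grid (x seeds), classify
    each run, and return a tidy table with the per-cell modal label.

    Run failures are recorded in the cell's ``error`` column rather than
    aborting the sweep.  Deterministic given the seed list.
    """
    if len(C_values) == 0 or len(E_values) == 0:
        raise ValueError("C_values and E_values must be non-empty")
    thresholds = thresholds or PhaseThresholds()
    rows = []
    for C in C_values:
        for E in E_values:
            for s in seeds:
                groups = replace(base_cfg.groups, C=float(C), E=float(E))
                cfg = replace(base_cfg, groups=groups, seed=int(s))
                geometry = cfg.geometry if cfg.ndim == 2 else cfg.substrate_interval
                try:
                    snaps = integrate_continuum(cfg)
                    rec = classify_outcome(snaps, geometry, groups, thresholds, int(s))
                except (FloatingPointError, ValueError) as err:
                    rec = OutcomeRecord("error", None, math.nan, math.nan,
                                        float(C), float(E), int(s), error=str(err))
                rows.append({
                    "C": float(C), "E": float(E), "seed": int(s),
                    "label": rec.phase,
                    "breakthrough_time": rec.breakthrough_time,
                    "removed_fraction": rec.removed_fraction,
                    "localization_index": rec.localization,
                    "error": rec.error,
                })
    df = pd.DataFrame(rows)
    modal = (df[df["label"] != "error"]
             .groupby(["C", "E"])["label"]
             .agg(lambda s: s.mode().iloc[0]))
    df["modal_label"] = df.set_index(["C", "E"]).index.map(modal)
    return df


# --------------------------------------------------------------------------
# asymptotic regime checks
# --------------------------------------------------------------------------

def _uniform_1d_cfg(groups: NonDimGroups, nx: int = 128, t_end: float = 3.0,
                    seed: int = 0) -> ContinuumConfig:
    return ContinuumConfig(
        groups=groups, ndim=1, nx=nx,
        ic_name="gaussian_1d",
        ic_params={"center": 0.3, "width": 0.12, "amplitude": 1.0},
        substrate_interval=(2.0, 3.0),   # outside [0,1]: substrate inert
        noise_amp=0.01, seed=seed, t_end=t_end, snapshot_dt=t_end / 10.0)


def regime_limit_check(groups: NonDimGroups, regime: str,
                       nx: int = 128, seed: int = 0) -> Dict[str, float]:
    """Quantify how well the full model obeys its asymptotic reduction.

    decay (Dc_hat << 1): the field slaves to the density, c = k_hat rho_a;
    reports the max relative deviation after the decay transient.
    diffusion (Dc_hat >> 1): the field obeys the quasi-static Poisson
    balance -Dc_hat lap(c) = k_hat rho_a - c; reports the scaled residual.
    chemotaxis (C >> 1, E = 0): the density focuses (effective negative
    diffusivity); reports the growth factor of the density maximum.

    A ``warning`` flag of 1.0 marks parameters inconsistent with the
    requested limit.
    """
    g = groups
    report: Dict[str, float] = {"warning": 0.0}
    if regime == "decay":
        if g.Dc_hat > 0.1:
            report["warning"] = 1.0
        cfg = _uniform_1d_cfg(replace(g, E=0.0), nx=nx, t_end=8.0, seed=seed)
        snaps = integrate_continuum(cfg)
        last = snaps[-1]
        dev = np.abs(last.c - g.k_hat * last.rho_a)
        report["max_rel_deviation"] = float(dev.max() / max(last.c.max(), 1e-300))
    elif regime == "diffusion":
        if g.Dc_hat < 1.0:
            report["warning"] = 1.0
        # the field slaves to the density on the fast 1/(Dc_hat k^2) scale,
        # so a short horizon suffices (the explicit step shrinks as 1/Dc_hat)
        cfg = _uniform_1d_cfg(replace(g, E=0.0), nx=nx, t_end=0.3, seed=seed)
        snaps = integrate_continuum(cfg)
        last = snaps[-1]
        from .continuum import _laplacian_noflux
        resid = g.Dc_hat * _laplacian_noflux(last.c, last.h) + g.k_hat * last.rho_a - last.c
        scale = max(float(np.abs(g.k_hat * last.rho_a).max()), 1e-300)
        report["scaled_residual"] = float(np.abs(resid).max() / scale)
    elif regime == "chemotaxis":
        if g.C < 2.0 or g.E > 0.0:
            report["warning"] = 1.0
        cfg = _uniform_1d_cfg(replace(g, E=0.0, V=0.0), nx=nx, t_end=2.0, seed=seed)
        cfg.ic_name = "uniform_1d"
        cfg.ic_params = {"amplitude": 1.0}
        cfg.noise_amp = 0.02
        snaps = integrate_continuum(cfg)
        maxima = np.array([float(s.rho_a.max()) for s in snaps])
        report["focus_growth"] = float(maxima[-1] / maxima[0])
        # skip the first interval: seeded noise is smoothed before the
        # chemotactic instability takes over
        report["monotone_fraction"] = float(np.mean(np.diff(maxima[1:]) >= -1e-12))
        m0 = float(snaps[0].rho_s.sum())
        report["substrate_removed"] = (float(1.0 - snaps[-1].rho_s.sum() / m0)
                                       if m0 > 0 else 0.0)
    else:
        raise ValueError("regime must be one of {'decay', 'diffusion', 'chemotaxis'}")
    return report
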