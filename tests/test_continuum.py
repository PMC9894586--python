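"""Continuum solver: conservation, positivity, erosion monotonicity,
breakthrough detection and the asymptotic regime reductions."""

from dataclasses import replace

import numpy as np
import pytest

from antcavate.continuum import (ContinuumConfig, ContinuumState,
                                 breakthrough_time, continuum_rhs,
                                 has_breakthrough, integrate_continuum)
from antcavate.params import Geometry, NonDimGroups
from antcavate.phases import regime_limit_check


def _cfg_1d(**kw):
    base = dict(groups=NonDimGroups(C=2.0, E=2.0),
                ndim=1, nx=48, t_end=2.0, snapshot_dt=0.25,
                ic_name="gaussian_1d",
                ic_params={"center": 0.5, "width": 0.1, "amplitude": 2.0},
                substrate_interval=(0.6, 0.85))
    base.update(kw)
    return ContinuumConfig(**base)


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

def test_zero_excavation_rate_freezes_substrate(rng):
    cfg = _cfg_1d(groups=NonDimGroups(C=1.0, E=0.0))
    state, _ = _state_from(cfg, rng)
    _, _, d_rho_s = continuum_rhs(state, cfg.groups)
    assert np.all(d_rho_s == 0.0)


def _state_from(cfg, rng, randomize=False):
    from antcavate.continuum import _initial_state
    state, phat = _initial_state(cfg)
    if randomize:
        n = state.rho_a.size
        x = np.linspace(0, 2 * np.pi, n)
        state.rho_a = 0.5 + 0.3 * np.sin(3 * x + rng.uniform(0, 6)) \
            + 0.1 * rng.standard_normal(n)
        state.rho_a = np.abs(state.rho_a)
        state.c = np.abs(0.4 + 0.2 * np.cos(2 * x + rng.uniform(0, 6)))
    return state, phat


def test_homogeneous_subthreshold_state_is_a_fixed_point():
    g = NonDimGroups(C=1.0, E=1.0, V=0.0, k_hat=2.0, c_star=0.9, rho_a_star=0.9,
                     alpha_c=40.0)
    nx = 32
    rho0 = 0.1   # c = k_hat rho0 = 0.2, far below both thresholds
    state = ContinuumState(np.full(nx, rho0), np.full(nx, g.k_hat * rho0),
                           np.ones(nx), 0.0, 1.0 / nx, (0.0,))
    da, dc, ds = continuum_rhs(state, g)
    assert np.abs(da).max() < 1e-12
    assert np.abs(dc).max() < 1e-12
    assert np.abs(ds).max() < 1e-8  # tanh tails only


def test_discrete_mass_balance_of_density_rhs(rng):
    """Conservative fluxes telescope: the grid sum of d(rho_a)/dt vanishes
    for arbitrary smooth states, in 1D and 2D."""
    for _ in range(50):
        cfg = _cfg_1d()
        state, phat = _state_from(cfg, rng, randomize=True)
        da, _, _ = continuum_rhs(state, cfg.groups, phat)
        assert abs(da.sum()) / np.abs(da).sum() < 1e-12
    geom = Geometry()
    cfg2 = ContinuumConfig(groups=NonDimGroups(), ndim=2, geometry=geom, nx=32,
                           ic_name="uniform_disk_2d", noise_amp=0.3, seed=7,
                           t_end=1.0)
    from antcavate.continuum import _initial_state
    for seed in range(5):
        cfg2.seed = seed
        state, phat = _initial_state(cfg2)
        state.c = np.abs(rng.standard_normal(state.c.shape)) * 0.3
        da, _, _ = continuum_rhs(state, cfg2.groups, phat)
        assert abs(da.sum()) <= 1e-12 * max(np.abs(da).sum(), 1.0)


# --------------------------------------------------------------------------
# integration invariants
# --------------------------------------------------------------------------

def test_integration_conserves_mass_and_erodes_monotonically():
    cfg = _cfg_1d(t_end=1.5)
    snaps = integrate_continuum(cfg)
    m0 = snaps[0].total_mass()
    for a, b in zip(snaps[:-1], snaps[1:]):
        drift = abs(b.total_mass() - m0) / m0
        assert drift < 1e-6 * max(b.t, 1.0)
        assert np.all(b.rho_s <= a.rho_s + 1e-12)      # monotone erosion
    last = snaps[-1]
    assert np.all(last.rho_s >= 0.0) and np.all(last.rho_s <= 1.0)
    assert np.all(last.rho_a >= -1e-12)
    assert np.all(last.c >= 0.0)


def test_coordinated_1d_preset_excavates_through_the_block():
    """Strong cooperation and excavation (C, E > 1) remove the substrate on
    a connected interval spanning the block."""
    cfg = _cfg_1d(t_end=2.0)
    snaps = integrate_continuum(cfg)
    tb = breakthrough_time(snaps, cfg.substrate_interval, threshold=0.1)
    assert tb is not None and tb <= 2.0
    x = snaps[-1].cell_centers()[0]
    block = (x >= 0.6) & (x <= 0.85)
    assert snaps[-1].rho_s[block].max() < 0.1


def test_zero_excavation_is_censored():
    cfg = _cfg_1d(groups=NonDimGroups(C=2.0, E=0.0), t_end=0.5)
    snaps = integrate_continuum(cfg)
    assert breakthrough_time(snaps, cfg.substrate_interval) is None


def test_breakthrough_time_monotone_in_excavation_rate():
    times = []
    for E in (1.0, 2.0, 4.0):
        cfg = _cfg_1d(groups=NonDimGroups(C=2.0, E=E), t_end=1.6)
        snaps = integrate_continuum(cfg)
        tb = breakthrough_time(snaps, cfg.substrate_interval)
        assert tb is not None
        times.append(tb)
    assert np.all(np.diff(times) <= 1e-9)


def test_breakthrough_requires_spanning_path_2d():
    geom = Geometry(Ro=5.0, Ri=2.5, domain_half_width=6.0)
    nx = 48
    h = 12.0 / nx
    x = -6.0 + (np.arange(nx) + 0.5) * h
    X, Y = np.meshgrid(x, x)
    R = np.hypot(X, Y)
    annulus = ((R >= 2.5) & (R <= 5.0)).astype(float)
    intact = ContinuumState(np.zeros_like(annulus), np.zeros_like(annulus),
                            annulus.copy(), 0.0, h, (-6.0, -6.0))
    assert not has_breakthrough(intact, geom)
    # carve a radial channel along +x
    tunneled = intact.copy()
    tunneled.rho_s[(np.abs(Y) < 2 * h) & (X > 0)] = 0.0
    assert has_breakthrough(tunneled, geom)
    # a blind pocket does not span
    pocket = intact.copy()
    pocket.rho_s[(np.abs(Y) < 2 * h) & (X > 0) & (R < 3.5)] = 0.0
    assert not has_breakthrough(pocket, geom)


def test_empty_snapshot_list_is_a_usage_error():
    with pytest.raises(ValueError):
        breakthrough_time([], (0.6, 0.85))


def test_halving_dt_self_convergence():
    """Fixed-step runs converge as dt shrinks (order >= 1)."""
    diffs = []
    sols = []
    for dt in (4e-4, 2e-4, 1e-4):
        cfg = _cfg_1d(nx=32, t_end=0.4, dt=dt, snapshot_dt=0.4)
        sols.append(integrate_continuum(cfg)[-1])
    d1 = np.abs(sols[0].rho_a - sols[1].rho_a).max()
    d2 = np.abs(sols[1].rho_a - sols[2].rho_a).max()
    assert d2 < 0.75 * d1   # at first order, d2 ~ d1 / 2


def test_divergence_reports_last_good_time():
    """An unstable fixed step blows up; the error names the last sound
    snapshot time instead of returning garbage."""
    cfg = _cfg_1d(nx=48, t_end=2.0, dt=5e-3)   # far above the h^2 bound
    with pytest.raises(FloatingPointError, match="last good t"):
        integrate_continuum(cfg)


# --------------------------------------------------------------------------
# asymptotic regimes
# --------------------------------------------------------------------------

def test_decay_dominated_field_slaves_to_density():
    """At Dc_hat = 1e-3 the field tracks k_hat * rho_a within 2%."""
    g = NonDimGroups(C=0.5, E=0.0, V=0.5, Dc_hat=1e-3)
    report = regime_limit_check(g, "decay", nx=48)
    assert report["warning"] == 0.0
    assert report["max_rel_deviation"] < 0.02


def test_diffusion_dominated_residual_shrinks_with_Dc():
    res = []
    for Dch in (3.0, 30.0):
        g = NonDimGroups(C=0.5, E=0.0, V=0.5, Dc_hat=Dch, k_hat=Dch)
        report = regime_limit_check(g, "diffusion", nx=32)
        res.append(report["scaled_residual"])
    assert res[1] < res[0]


def test_chemotaxis_dominated_regime_focuses_density():
    g = NonDimGroups(C=10.0, E=0.0, V=0.0, Dc_hat=0.5)
    report = regime_limit_check(g, "chemotaxis", nx=48)
    assert report["focus_growth"] > 2.0
    assert report["monotone_fraction"] > 0.9
    assert report["substrate_removed"] == pytest.approx(0.0, abs=1e-12)
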