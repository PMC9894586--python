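"""Stochastic agent-based simulator of cooperative excavation.

Each agent is a disk of radius ``a`` moving at constant speed ``vo`` along
its heading.  The heading turns up the gradient of a self-generated
communication field (gain ``G``) and diffuses with rotational noise
intensity ``Da_rot`` (Euler-Maruyama).  Agents deposit the field at rate
``k_plus`` inside their footprint; the field diffuses (``Dc``) and decays
(``k_minus``) on a square lattice with no-flux edges.  The confining corral
is a set of discrete wall elements: an agent next to a wall element where
the local field exceeds the threshold ``c_star`` picks it up, carries it,
and drops it where the field has fallen below ``drop_fraction * c_star``;
deposited elements become static obstacles.  A run ends when an agent's
center crosses the outer radius ``Ro`` (escape) or at ``Tstop`` (censored).

An optional behavioral-controller mode ("rant mode") mimics programmable
robots: the deterministic turning term is scaled by a cooperation parameter
``C`` in [0, 1] and the rotational noise by (1 - C), interpolating from pure
random motion (C=0) to pure gradient tracking (C=1), and a grasp succeeds
only with probability ``E_grasp`` per encounter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import Geometry
from .fixtures import element_ring

__all__ = [
    "AgentState",
    "BoundaryElementSet",
    "FieldGrid",
    "AgentSimConfig",
    "AgentRunResult",
    "step_agents",
    "update_field",
    "pick_drop_update",
    "run_agent_sim",
    "sweep_population",
    "crossing_time",
    "rant_sweep_config",
]

IN_WALL, CARRIED, DEPOSITED = 0, 1, 2


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class AgentState:
    """Positions (n, 2), headings (n,) in (-pi, pi], and the index of the
    carried element per agent (-1 when empty-handed)."""

    positions: np.ndarray
    headings: np.ndarray
    carry_idx: np.ndarray
    radius: float = 0.2
    speed: float = 0.5

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def carrying(self) -> np.ndarray:
        return self.carry_idx >= 0

    def copy(self) -> "AgentState":
        return AgentState(self.positions.copy(), self.headings.copy(),
                          self.carry_idx.copy(), self.radius, self.speed)


@dataclass
class BoundaryElementSet:
    """Discrete corral wall elements; the total count is conserved."""

    positions: np.ndarray          # (m, 2)
    state: np.ndarray              # (m,) in {IN_WALL, CARRIED, DEPOSITED}
    radius: float
    carrier: np.ndarray = None     # (m,) agent index or -1

    def __post_init__(self) -> None:
        if self.carrier is None:
            self.carrier = np.full(self.positions.shape[0], -1, dtype=int)

    @property
    def m(self) -> int:
        return self.positions.shape[0]

    def counts(self) -> Dict[str, int]:
        return {"in_wall": int((self.state == IN_WALL).sum()),
                "carried": int((self.state == CARRIED).sum()),
                "deposited": int((self.state == DEPOSITED).sum())}

    def copy(self) -> "BoundaryElementSet":
        return BoundaryElementSet(self.positions.copy(), self.state.copy(),
                                  self.radius, self.carrier.copy())


@dataclass
class FieldGrid:
    """Communication field on a square lattice; ``origin`` is the corner of
    cell (0, 0), values indexed (y, x)."""

    values: np.ndarray
    h: float
    origin: Tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def contains(self, points: np.ndarray) -> np.ndarray:
        ny, nx = self.values.shape
        x0, y0 = self.origin
        x = points[..., 0]
        y = points[..., 1]
        return (x >= x0) & (x <= x0 + nx * self.h) & (y >= y0) & (y <= y0 + ny * self.h)

    def _frac_index(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Continuous (col, row) index of points relative to cell centers."""
        x0, y0 = self.origin
        fx = (points[..., 0] - x0) / self.h - 0.5
        fy = (points[..., 1] - y0) / self.h - 0.5
        return fx, fy

    def _bilinear(self, arr: np.ndarray, points: np.ndarray) -> np.ndarray:
        ny, nx = arr.shape
        fx, fy = self._frac_index(points)
        fx = np.clip(fx, 0.0, nx - 1.000001)
        fy = np.clip(fy, 0.0, ny - 1.000001)
        i0 = fx.astype(int)
        j0 = fy.astype(int)
        tx = fx - i0
        ty = fy - j0
        i1 = np.minimum(i0 + 1, nx - 1)
        j1 = np.minimum(j0 + 1, ny - 1)
        return ((1 - tx) * (1 - ty) * arr[j0, i0] + tx * (1 - ty) * arr[j0, i1]
                + (1 - tx) * ty * arr[j1, i0] + tx * ty * arr[j1, i1])

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated field value at (..., 2) points."""
        if not np.all(self.contains(points)):
            raise ValueError("point outside field support")
        return self._bilinear(self.values, points)

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated centered-difference gradient, (..., 2)."""
        if not np.all(self.contains(points)):
            raise ValueError("point outside field support")
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("non-finite communication field")
        gy, gx = np.gradient(self.values, self.h)
        return np.stack([self._bilinear(gx, points), self._bilinear(gy, points)], axis=-1)

    def copy(self) -> "FieldGrid":
        return FieldGrid(self.values.copy(), self.h, self.origin)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class AgentSimConfig:
    """Default preset: an annular wall of three element layers inside a
    square arena, tuned so that mid-sized collectives excavate out before
    Tstop while lone agents never trip the field threshold and large crowds
    get trapped in their own field."""

    n_agents: int = 8
    geometry: Geometry = field(default_factory=lambda: Geometry(Ro=5.0, Ri=2.5,
                                                                domain_half_width=6.0))
    vo: float = 0.5
    a: float = 0.2
    Da_rot: float = 0.4
    G: float = 0.7
    Dc: float = 0.1
    k_plus: float = 1.0
    k_minus: float = 0.25
    c_star: float = 0.45
    drop_fraction: float = 0.7
    # wall
    wall_layers: int = 2
    wall_total: int = 60
    wall_r_min: float = 2.5
    wall_r_max: float = 3.5
    element_radius: Optional[float] = None
    # behavioral-controller (robot) mode
    rant_mode: bool = False
    C: float = 1.0            # cooperation parameter, used in rant mode
    E_grasp: float = 1.0      # grasp probability per encounter, rant mode
    rant_noise_floor: float = 0.2   # residual exploration noise at C=1
    # numerics & run controls
    grid_nx: int = 64
    dt: float = 0.05
    dt_safety: float = 0.9
    Tstop: float = 266.0
    seed: int = 0
    resolve_collisions: bool = True
    store_trajectory: bool = True
    save_every: int = 20      # trajectory sampling stride, in steps
    field_snapshot_times: Tuple[float, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["field_snapshot_times"] = list(self.field_snapshot_times)
        return d

    def crossing_time(self) -> float:
        """ts: time for an agent to cross the arena along a diameter."""
        return 2.0 * self.geometry.Ro / self.vo


def crossing_time(cfg: AgentSimConfig) -> float:
    return cfg.crossing_time()


def rant_sweep_config(n_agents: int = 5, E_grasp: float = 1.0) -> AgentSimConfig:
    """Base configuration of the behavioral-controller cooperation sweep:
    a small collective with a deliberately diffusive baseline (Da_rot=1.6)
    and noise floor 0.5, so that raising the cooperation parameter C from
    random motion toward gradient tracking shortens the mean escape time."""
    return AgentSimConfig(n_agents=n_agents, rant_mode=True, E_grasp=E_grasp,
                          Da_rot=1.6, rant_noise_floor=0.5,
                          store_trajectory=False)


@dataclass
class AgentRunResult:
    times: np.ndarray                      # sampled times (nt,)
    trajectory: Optional[np.ndarray]       # (nt, n, 2) or None
    headings: Optional[np.ndarray]         # (nt, n) or None
    field_snapshots: Dict[float, np.ndarray]
    events: pd.DataFrame                   # columns t, event, agent, element, x, y
    escape_time: Optional[float]           # None when censored
    censored: bool
    config: dict

    @property
    def T(self) -> float:
        """Escape time, with censored runs contributing Tstop."""
        return self.config["Tstop"] if self.censored else self.escape_time


# --------------------------------------------------------------------------
# elementary updates
# --------------------------------------------------------------------------

def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Reduce angles to (-pi, pi]."""
    out = np.mod(theta + math.pi, 2.0 * math.pi) - math.pi
    out[out == -math.pi] = math.pi
    return out


def step_agents(state: AgentState, fieldgrid: FieldGrid, cfg: AgentSimConfig,
                rng: np.random.Generator,
                elements: Optional[BoundaryElementSet] = None) -> AgentState:
    """One Euler-Maruyama step of headings and positions (in place).

    Heading: d theta = G (grad c . p_perp) dt + sqrt(2 Da_rot dt) xi, with
    p_perp = (-sin theta, cos theta), which steers agents up-gradient and
    makes gradient-aligned motion a fixed point.  In rant mode the turning
    term is scaled by C and the noise by (1 - C).  A proposed move that
    would overlap another agent, a wall element or a deposited obstacle is
    rejected (the heading keeps its new value); the square arena walls
    reflect both position and heading.
    """
    n = state.n
    grad = fieldgrid.gradient_at(state.positions)
    p_perp = np.column_stack([-np.sin(state.headings), np.cos(state.headings)])
    turn = cfg.G * np.einsum("ij,ij->i", grad, p_perp)
    noise = math.sqrt(2.0 * cfg.Da_rot * cfg.dt) * rng.standard_normal(n)
    if cfg.rant_mode:
        # cooperation interpolates gradient tracking vs exploration; a small
        # noise floor mimics actuation imperfections of physical robots and
        # keeps C=1 from freezing in a cold (field-free) arena
        noise_scale = max(1.0 - cfg.C, cfg.rant_noise_floor)
        state.headings += cfg.dt * cfg.C * turn + noise_scale * noise
    else:
        state.headings += cfg.dt * turn + noise
    state.headings = _wrap_angle(state.headings)

    step = cfg.dt * state.speed
    proposed = state.positions + step * np.column_stack(
        [np.cos(state.headings), np.sin(state.headings)])

    # reflecting square walls
    L = cfg.geometry.domain_half_width
    cx, cy = cfg.geometry.center
    for dim, c0 in ((0, cx), (1, cy)):
        lo, hi = c0 - L + state.radius, c0 + L - state.radius
        under = proposed[:, dim] < lo
        over = proposed[:, dim] > hi
        proposed[under, dim] = 2 * lo - proposed[under, dim]
        proposed[over, dim] = 2 * hi - proposed[over, dim]
        if dim == 0:
            state.headings[under | over] = _wrap_angle(
                math.pi - state.headings[under | over])
        else:
            state.headings[under | over] = -state.headings[under | over]

    if not cfg.resolve_collisions:
        state.positions = proposed
        return state

    # sequential acceptance in fixed index order (deterministic)
    pos = state.positions
    if elements is not None:
        solid = (elements.state != CARRIED)
        solid_pos = elements.positions[solid]
        min_de = state.radius + elements.radius
    for j in range(n):
        p = proposed[j]
        d2 = np.sum((pos - p) ** 2, axis=1)
        d2[j] = np.inf
        if np.any(d2 < (2.0 * state.radius) ** 2):
            continue
        if elements is not None and solid_pos.size and \
                np.any(np.sum((solid_pos - p) ** 2, axis=1) < min_de ** 2):
            continue
        pos[j] = p
    return state


def update_field(fieldgrid: FieldGrid, state: AgentState, cfg: AgentSimConfig,
                 dt: float) -> FieldGrid:
    """Explicit step of dc/dt = Dc lap(c) + k_plus sum_j H(r_j; a) - k_minus c
    with a 5-point Laplacian and no-flux edges (in place).

    The source indicator H marks lattice cells whose centers lie within the
    agent disk.  Refuses dt beyond the diffusive stability bound, stating
    the admissible step.
    """
    h = fieldgrid.h
    if cfg.Dc > 0.0:
        dt_max = cfg.dt_safety * h * h / (4.0 * cfg.Dc)
        if dt > dt_max:
            raise ValueError(
                f"dt={dt:g} violates the field stability bound; admissible dt <= {dt_max:g}")
    c = fieldgrid.values
    ny, nx = c.shape
    src = np.zeros_like(c)
    x0, y0 = fieldgrid.origin
    ncell = int(math.ceil(state.radius / h)) + 1
    for p in state.positions:
        ci = int((p[0] - x0) / h - 0.5 + 0.5)
        cj = int((p[1] - y0) / h - 0.5 + 0.5)
        i_lo, i_hi = max(0, ci - ncell), min(nx, ci + ncell + 1)
        j_lo, j_hi = max(0, cj - ncell), min(ny, cj + ncell + 1)
        if i_lo >= i_hi or j_lo >= j_hi:
            continue
        xs = x0 + (np.arange(i_lo, i_hi) + 0.5) * h
        ys = y0 + (np.arange(j_lo, j_hi) + 0.5) * h
        inside = ((xs[None, :] - p[0]) ** 2 + (ys[:, None] - p[1]) ** 2
                  <= state.radius ** 2)
        src[j_lo:j_hi, i_lo:i_hi] += inside  # additive over overlapping agents
    cp = np.pad(c, 1, mode="edge")
    lap = (cp[:-2, 1:-1] + cp[2:, 1:-1] + cp[1:-1, :-2] + cp[1:-1, 2:] - 4.0 * c) / (h * h)
    c += dt * (cfg.Dc * lap + cfg.k_plus * src - cfg.k_minus * c)
    np.clip(c, 0.0, None, out=c)
    return fieldgrid


def pick_drop_update(state: AgentState, elements: BoundaryElementSet,
                     fieldgrid: FieldGrid, cfg: AgentSimConfig,
                     rng: np.random.Generator, t: float = 0.0,
                     events: Optional[List] = None,
                     ) -> Tuple[AgentState, BoundaryElementSet]:
    """Threshold pick-and-drop (in place).

    Pick: an empty-handed agent within grasp distance of an in-wall element
    where the local field exceeds c_star grasps the nearest one (in rant
    mode, with probability E_grasp per encounter).  Drop: a carrying agent
    whose local field has fallen below drop_fraction * c_star deposits its
    element just behind itself; deposited elements are static obstacles.
    No-op when no rule fires.
    """
    c_here = fieldgrid.value_at(state.positions)
    grasp = state.radius + elements.radius + 0.1 * fieldgrid.h
    L = cfg.geometry.domain_half_width

    # picks, in agent index order
    for j in range(state.n):
        if state.carry_idx[j] >= 0 or c_here[j] <= cfg.c_star:
            continue
        in_wall = np.flatnonzero(elements.state == IN_WALL)
        if in_wall.size == 0:
            continue
        d2 = np.sum((elements.positions[in_wall] - state.positions[j]) ** 2, axis=1)
        nearest = int(np.argmin(d2))
        if d2[nearest] > grasp * grasp:
            continue
        if cfg.rant_mode and rng.random() >= cfg.E_grasp:
            continue
        e = int(in_wall[nearest])
        elements.state[e] = CARRIED
        elements.carrier[e] = j
        state.carry_idx[j] = e
        if events is not None:
            events.append((t, "pick", j, e, state.positions[j, 0], state.positions[j, 1]))

    # drops
    for j in range(state.n):
        e = state.carry_idx[j]
        if e < 0 or c_here[j] >= cfg.drop_fraction * cfg.c_star:
            continue
        back = -np.array([math.cos(state.headings[j]), math.sin(state.headings[j])])
        spot = state.positions[j] + (state.radius + elements.radius) * back
        cx, cy = cfg.geometry.center
        spot[0] = np.clip(spot[0], cx - L + elements.radius, cx + L - elements.radius)
        spot[1] = np.clip(spot[1], cy - L + elements.radius, cy + L - elements.radius)
        elements.positions[e] = spot
        elements.state[e] = DEPOSITED
        elements.carrier[e] = -1
        state.carry_idx[j] = -1
        if events is not None:
            events.append((t, "drop", j, e, spot[0], spot[1]))

    # carried elements travel with their carriers
    carried = np.flatnonzero(elements.state == CARRIED)
    if carried.size:
        elements.positions[carried] = state.positions[elements.carrier[carried]]
    return state, elements


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _init_agents(cfg: AgentSimConfig, rng: np.random.Generator) -> AgentState:
    geom = cfg.geometry
    r_max = geom.Ri - cfg.a - 0.05
    pts = []
    while len(pts) < cfg.n_agents:
        cand = rng.uniform(-r_max, r_max, size=(2,))
        if cand[0] ** 2 + cand[1] ** 2 < r_max ** 2:
            pts.append(cand + np.asarray(geom.center))
    headings = rng.uniform(-math.pi, math.pi, size=cfg.n_agents)
    return AgentState(np.asarray(pts), headings,
                      np.full(cfg.n_agents, -1, dtype=int), cfg.a, cfg.vo)


def _init_field(cfg: AgentSimConfig) -> FieldGrid:
    L = cfg.geometry.domain_half_width
    h = 2.0 * L / cfg.grid_nx
    origin = (cfg.geometry.center[0] - L, cfg.geometry.center[1] - L)
    return FieldGrid(np.zeros((cfg.grid_nx, cfg.grid_nx)), h, origin)


def _init_elements(cfg: AgentSimConfig, seed: int) -> BoundaryElementSet:
    if cfg.wall_total == 0:      # free arena (e.g. transport benchmarks)
        return BoundaryElementSet(np.zeros((0, 2)), np.zeros(0, dtype=int),
                                  cfg.element_radius or 0.2)
    positions, radius = element_ring(cfg.wall_layers, cfg.wall_total,
                                     cfg.wall_r_min, cfg.wall_r_max,
                                     cfg.element_radius, seed=seed)
    positions = positions + np.asarray(cfg.geometry.center)
    return BoundaryElementSet(positions, np.zeros(cfg.wall_total, dtype=int), radius)


def run_agent_sim(cfg: AgentSimConfig, seed: Optional[int] = None) -> AgentRunResult:
    """Interleave heading/position, field and pick-drop updates until an
    agent crosses Ro (escape) or t reaches Tstop (censored).

    The full state trajectory is a pure function of (config, seed): one RNG
    stream drives initialization, heading noise and grasp draws in a fixed
    order, so identical inputs give a bit-identical event log.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    state = _init_agents(cfg, rng)
    fieldgrid = _init_field(cfg)
    elements = _init_elements(cfg, seed)
    geom = cfg.geometry
    center = np.asarray(geom.center)

    n_steps = int(round(cfg.Tstop / cfg.dt))
    events: List = []
    times: List[float] = []
    traj: List[np.ndarray] = []
    heads: List[np.ndarray] = []
    snaps: Dict[float, np.ndarray] = {}
    snap_queue = sorted(cfg.field_snapshot_times)
    escape_time = None

    t = 0.0
    for istep in range(n_steps):
        step_agents(state, fieldgrid, cfg, rng, elements)
        update_field(fieldgrid, state, cfg, cfg.dt)
        pick_drop_update(state, elements, fieldgrid, cfg, rng, t, events)
        t = (istep + 1) * cfg.dt
        if cfg.store_trajectory and istep % cfg.save_every == 0:
            times.append(t)
            traj.append(state.positions.copy())
            heads.append(state.headings.copy())
        while snap_queue and t >= snap_queue[0]:
            snaps[snap_queue.pop(0)] = fieldgrid.values.copy()
        r = np.hypot(*(state.positions - center).T)
        if np.any(r > geom.Ro):
            escape_time = t
            break

    ev = pd.DataFrame(events, columns=["t", "event", "agent", "element", "x", "y"])
    if cfg.store_trajectory:
        times.append(t)
        traj.append(state.positions.copy())
        heads.append(state.headings.copy())
    return AgentRunResult(
        times=np.asarray(times),
        trajectory=np.asarray(traj) if cfg.store_trajectory else None,
        headings=np.asarray(heads) if cfg.store_trajectory else None,
        field_snapshots=snaps,
        events=ev,
        escape_time=escape_time,
        censored=escape_time is None,
        config=cfg.to_dict(),
    )


def sweep_population(cfg: AgentSimConfig, n_values: Sequence[int],
                     seeds: Sequence[int]) -> pd.DataFrame:
    """Run the simulator over population sizes x seeds; returns a tidy table
    with per-run scaled escape times T/ts (censored runs contribute
    T = Tstop) and the per-n median.  Deterministic given the seed list."""
    from dataclasses import replace

    ts = cfg.crossing_time()
    rows = []
    for n in n_values:
        cfg_n = replace(cfg, n_agents=int(n), store_trajectory=False)
        for s in seeds:
            res = run_agent_sim(cfg_n, seed=int(s))
            rows.append({"n": int(n), "seed": int(s), "T": res.T,
                         "T_over_ts": res.T / ts, "censored": res.censored})
    df = pd.DataFrame(rows)
    df["median_T_over_ts"] = df.groupby("n")["T_over_ts"].transform("median")
    return df
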