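# antcavate

Models of **cooperative excavation**: how a confined collective — ants in an
erodible corral, or gradient-following robots in an arena of movable wall
elements — switches from individual exploration to a localized, cooperative
tunnel and escapes. The package is for quantitative ethologists, active-matter
theorists and swarm-robotics researchers who want a minimal, fully
reproducible implementation of the coupled agent–field–substrate dynamics and
its analysis.

## The models

**Agent engine.** Each agent is a self-propelled disk: positions advance at
speed `v_o` along headings that turn up the gradient of a self-generated
communication field and diffuse rotationally,

    dr_j/dt = v_o p_j,      d(theta_j)/dt = G (grad c · p_perp_j) + eta_j,

while the field obeys `dc/dt = Dc lap c + k+ Σ_j H(r_j; a) − k− c`. Agents
pick discrete wall elements where `c > c*` and deposit them where
`c < drop_fraction · c*`; the run ends at escape (crossing the outer radius
`Ro`) or at `Tstop`. A behavioral-controller mode scales turning by a
cooperation parameter `C ∈ [0, 1]`, noise by `1 − C`, and grasping by a
probability `E`.

**Continuum engine.** Coarse-graining gives three coupled fields — agent
density `ϱ_a`, communication field `c`, substrate density `ϱ_s` — in
dimensionless form:

    ∂t ϱ_a + ∇·[(C ∇c + V (1 − ϱ_s) p̂) ϱ_a] = ∇² ϱ_a
    ∂t c = D̂c ∇² c + k̂± ϱ_a − c
    ∂t ϱ_s = −(E/4) ϱ_s (1 + tanh[α_c (c − c*)]) (1 + tanh[α_ϱ (ϱ_a − ϱ_a*)])

with cooperation `C`, excavation rate `E`, migration `V`, production/decay
ratio `k̂±`, scaled field diffusivity `D̂c`. With `E = 0` this reduces to a
Keller–Segel chemotaxis system. The linearized homogeneous state has a
substrate branch with growth rate `Ω = −E/2`, independent of every other
parameter, and the outcome space over `(C, E)` splits into four phases:
diffused, jammed, partial tunneling and coordinated excavation.

See `docs/methods.md` for numerics, defaults and their rationale.

## Worked example

```bash
python examples/tunneling_2d.py
```

prints (reduced 64² grid, seed 1):

```
breakthrough time: t = 6.00 (nondimensional)
substrate removed by then: 71%
A connected path of eroded corral (rho_s < 0.5) joins the inner chamber to
the outside; the collective has tunneled out, well before the t = 20
horizon of the reference run.
```

The breakthrough time is the first instant an eroded channel (`ϱ_s < 0.5`)
connects the inner chamber to the outside — the continuum analogue of the
collective tunneling out. Other examples: `dispersion_relation.py` (the
`Ω = −E/2` substrate branch, analytic and simulation-measured),
`agent_escape.py` (a stochastic escape with its pick/drop log),
`phase_diagram.py` (the four phase-diagram corners), and
`track_observables.py` (density marginals and boundary Fourier modes from a
trajectory table).

A thin CLI mirrors the library: `antcavate simulate-agents`,
`simulate-continuum`, `dispersion`, `phase-sweep`, `analyze`,
`make-fixture`; every run writes a resolved-config JSON that reproduces it
exactly.

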