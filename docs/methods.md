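# Methods

`antcavate` models a confined collective that escapes by cooperatively
eroding its confinement. Two engines share one conceptual core — agents
deposit a communication field that diffuses and decays; the field gates and
guides substrate removal — and a common observables layer quantifies the
outcome.

## Agent engine

Each of n agents is a disk of radius `a` moving at constant speed `vo`
along its heading `theta_j`:

    dr_j/dt     = vo (cos theta_j, sin theta_j)
    dtheta_j/dt = G (grad c . p_perp_j) + eta_j(t)

with `p_perp = (-sin theta, cos theta)` and `eta` Gaussian white noise of
intensity `2 Da_rot`. The torque term turns agents up the field gradient
and leaves gradient-aligned motion invariant. Headings are integrated by
Euler–Maruyama and wrapped to (-pi, pi].

The communication field obeys

    dc/dt = Dc lap(c) + k_plus sum_j H(r_j; a) - k_minus c

on a square lattice (5-point Laplacian, no-flux edges, explicit stepping
refused beyond the h^2/(4 Dc) bound). `H` marks the lattice cells inside an
agent's footprint, and overlapping footprints add — co-located agents
produce proportionally more field, which is what makes the pick threshold
an effective quorum detector.

The corral is a set of discrete wall elements in concentric layers. An
empty-handed agent beside an in-wall element picks it when the local field
exceeds `c_star`; a carrier deposits it where the field has dropped below
`drop_fraction * c_star`; deposited elements obstruct motion. Collisions
(agent–agent, agent–element) are resolved by rejecting the offending
position update in fixed index order; the square arena wall reflects. A run
ends when an agent crosses the outer radius `Ro` (escape time `T`) or at
`Tstop` (censored, `T = Tstop`). The crossing time `ts = 2 Ro / vo`
nondimensionalizes escape times.

### Default preset and what it encodes

The reference parameter tables behind the published agent runs are not
available, so the default preset is this package's own calibration, chosen
once so that the qualitative population-size story holds and then frozen:

| knob | value | role |
|---|---|---|
| `vo`, `a` | 0.5, 0.2 | transit speed, footprint |
| `Da_rot` | 0.4 | exploration (long enough wall dwell for quorums) |
| `G` | 0.7 | recruitment to field maxima |
| `Dc`, `k_plus`, `k_minus` | 0.1, 1.0, 0.25 | short-ranged, long-lived field |
| `c_star` | 0.45 | pick quorum (a lone agent's trail stays below it) |
| `drop_fraction` | 0.7 | carriers release quickly outside the hot zone |
| wall | 2 layers, 60 elements, r in [2.5, 3.5] | erodible annulus |
| `Tstop` | 266 | censoring horizon |

Small collectives never trip the quorum (censored); mid-sized ones dig a
localized tunnel and escape; large ones raise the field everywhere and the
gradient term traps them on their own signal (censored) — the non-monotone
escape-time curve with an interior optimum. Because the published parameter
tables are unavailable, the *location* of the optimum is a property of this
calibration, not a fitted quantity.

The behavioral-controller ("rant") mode reinterprets the same engine as
programmable robots: the turning term is scaled by a cooperation parameter
`C` in [0, 1] and the noise by `(1 - C)`, and a grasp succeeds with
probability `E_grasp`. A small residual noise floor (`rant_noise_floor`,
default 0.2) persists at C = 1: physical robots never track a gradient
noiselessly, and a strictly noise-free controller freezes in a cold,
field-free arena before any field exists to follow.

## Continuum engine

The coarse-grained model evolves agent density `rho_a` (conserved),
communication field `c`, and substrate density `rho_s` in [0, 1]:

    d rho_a/dt = lap(rho_a) - div[(C grad c + V (1 - rho_s) phat) rho_a]
    d c/dt     = Dc_hat lap(c) + k_hat rho_a - c
    d rho_s/dt = -(E/4) rho_s (1 + tanh[alpha_c (c - c*)])
                                (1 + tanh[alpha_rho (rho_a - rho_a*)])

`C` is the cooperation (chemotaxis) parameter, `E` the excavation rate, `V`
the migration parameter, `k_hat` production/decay, `Dc_hat` the scaled
field diffusivity. The erosion switch uses two independent sharpness
parameters: the printed form reuses one symbol for both, but the two
arguments carry different units (field amplitude vs density), so
`alpha_rho` is its own knob, defaulting to `alpha_c = 20`. With E = 0 and
the substrate frozen the (rho_a, c) pair is a Keller–Segel chemotaxis
system; its instability at large `C k_hat rho_a` is the jamming route.

`phat` is the preferred migration direction: +x in 1D, radially outward in
2D. It is zeroed within one cell of the corral center (singular) and
*outside the outer radius*: outward migration models digging toward the
outside, and past the corral there is nothing to migrate toward — with a
globally outward `phat`, density that leaks diffusively through the intact
wall is swept into the domain corners and permanently lost, an artifact no
physical reading of the term supports.

Numerics: finite-volume fluxes (first-order upwinding for advection,
second-order diffusion stencils), no-flux boundaries for `rho_a` and `c`,
forward Euler (midpoint RK2 optional) with an adaptive step at 0.4x the
binding diffusive/advective/reactive stability bound. This buys exact
discrete mass conservation and positivity at the cost of formal order;
`rho_s` is monotone non-increasing by construction. The solver aborts with
the last sound snapshot time if any field loses finiteness.

Default grids are 256 cells (1D) and 128^2 (2D). The adaptive step scales
as h^2, so 1D studies at unit diffusivity are run at 48–128 cells in the
test suite; outcomes (breakthrough, phase labels) are grid-stable down to
48 cells, which is what the sweeps use.

### Thresholds and the tunneling preset

The published appendix with the dimensional parameter tables is not part of
the available text, so the nondimensional defaults are design decisions:
`k_hat = 2`, `Dc_hat = 1`, `V = 1`, `c* = rho_a* = 0.25`, calibrated once
against the published 2D benchmark (C = 0.8, E = 1.44, annulus Ro = 5,
Ri = 2.5, uniform unit density in the inner disk with 1% seeded noise),
which then tunnels through by t ~ 6, comfortably within the published
t = 20 horizon. Higher placeholder thresholds (0.5) fail structurally: the
density leaks diffusively through the wall (the model's plain Laplacian
does not see the substrate) and dilutes below threshold before erosion can
open a channel.

### Breakthrough and phase classification

Breakthrough is the first snapshot whose excavated set {rho_s < 0.5}
contains a connected path (4-connectivity) joining the inner corral edge to
the outside. Each run is classified as:

- **coordinated excavation** — breakthrough occurred;
- **partial tunneling** — no breakthrough, but removed substrate mass
  fraction > 0.1;
- **jammed** — no breakthrough, removal <= 0.1, and density focusing index
  max(rho_a)_final / max(rho_a)_initial > 3;
- **diffused** — otherwise.

The focusing index replaces the angular peak-to-mean marginal as the
jamming detector: chemotactic collapse typically produces many spots tiling
the wall ring almost uniformly in angle, which leaves the angular marginal
flat (measured ~1.3 for violently jammed runs) while the density maximum
grows a hundredfold. The angular index is still computed and reported. All
classification thresholds are config keys; the four corner labels of the
calibration sweep are unchanged under +-20% perturbations of them.

The calibration sweep (`calibration_sweep_config`) uses a sparser, more
strongly migrating collective than the tunneling preset (amplitude 1.0,
V = 1.5, Dc_hat = 0.5, thresholds 0.35): a single fixed configuration in
which the four quadrant outcomes — diffused (low C, low E), jammed (high C,
E -> 0), partial (low C, high E), coordinated (high C, high E) — are
robustly separated at 48–64 cell resolution.

## Linear stability

About the homogeneous state (rho_a_ss, c_ss = k_hat rho_a_ss, rho_s = 1), a
plane-wave perturbation exp(ikx + Omega t) obeys a 3x3 linear system:

    [-k^2,   C rho_a_ss k^2,   i k V rho_a_ss]
    [k_hat,  -(1 + Dc_hat k^2), 0            ]
    [0,      0,                 -E/2         ]

The substrate branch Omega = -E/2 is independent of every other parameter:
once triggered, excavation relaxes at a rate set only by E. The -E/2 entry
corresponds to linearizing the smoothed threshold law with the density
switch saturated (the collective well above its density threshold) and the
field switch at its midpoint; a literal midpoint linearization of both
switches would give -E/4, and the sharp-threshold delta contributions are
dropped. `measured_growth_rate` verifies each branch against the full
nonlinear solver in its decoupled configuration — the substrate branch with
V = 0 (its operator row is diagonal; V only couples the substrate into the
density equation), the density and field branches with E = 0 — fitting the
log-amplitude slope of a cos(kx) mode over an early window and rejecting
the fit if halving the amplitude shifts the rate by more than 2%
(nonlinearity guard). Eigenvalues are independently cross-checked by
integrating a hand-written linear ODE system and taking a matrix logarithm.

## Observables

- Coarse-grained density: a time-averaged 2D histogram of agent positions
  (counts per unit area), integrating to the mean agent count; the
  averaging window should exceed one pick-carry-drop task cycle (the
  dimensional ant preset uses 250 s).
- Angular marginal `P_phi = int rho r dr` (the radial Jacobian is included
  so its circular integral equals the domain integral) and radial marginal
  `P_r = int rho S(phi) dphi` with `S` a normalized sector kernel centered
  on the excavation site (default: the argmax of `P_phi`; half-width
  pi/12 by default, pi/2 for the robot preset; indicator or tapered-cosine
  kernel).
- Boundary shape `R(phi)`: from a substrate field, the first radius per ray
  at which `rho_s` reaches 0.5; from wall elements, the innermost in-wall
  element per angular bin (the wall the collective actually faces). Its
  FFT power spectrum `|R_hat(k)|^2` (first K+1 modes) counts tunnels; the
  enclosed area is the polar quadrature `(1/2) int R^2 dphi`, spectrally
  accurate on the uniform angular grid and exact for band-limited shapes.
- Escape statistics: per-run `T/ts` with censored runs at `Tstop`, plus
  per-group means/medians.

## Known limitations

- The continuum density diffuses through intact substrate (the model has no
  density-dependent mobility), so confinement is only metastable; the
  calibrated presets operate where the excavation race is won before the
  leak matters, and very long horizons drain any confined state.
- First-order upwinding smears sharp chemotactic peaks; jammed-phase peak
  magnitudes are resolution-dependent (the jam/no-jam classification is
  not).
- The agent engine's collision rule is sequential rejection, adequate at
  the packing fractions used here but not a contact-dynamics model; grasp
  mechanics, multi-element carrying and heterogeneous castes are out of
  scope.
- The synthetic fixtures (element rings, localized track tables) emulate
  geometry and localization only — not real trajectory statistics of
  animals or robots — so passing observables tests demonstrates correctness
  of the estimators, not fidelity to any particular dataset.
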