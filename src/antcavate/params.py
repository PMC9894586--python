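"""Physical and nondimensional parameters of the cooperative-excavation models.

The models couple three ingredients: self-propelled agents (or their
coarse-grained density), a self-generated communication field ``c`` that is
produced by the agents, diffuses and decays, and an erodible substrate that
the agents remove when the field and the density exceed thresholds.  Seven
process timescales govern the dynamics; their ratios collapse onto five
dimensionless groups

    C    = chi * c_o / Da        (cooperation: gradient following vs diffusion)
    E    = ks * l / vo           (excavation rate vs transit rate)
    V    = vo * l / Da           (migration vs diffusion)
    k_hat  = k_plus * rho_o / (k_minus * c_o)   (field production vs decay)
    Dc_hat = Dc / (l**2 * k_minus)              (field diffusion vs decay)

with characteristic length ``l = min(sqrt(Dc/k_minus), la)`` — the zone of
influence of the communication field, capped at the agent body length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

__all__ = [
    "InvalidParameterError",
    "PhysicalParams",
    "NonDimGroups",
    "Timescales",
    "Geometry",
    "nondimensionalize",
    "timescales",
    "characteristic_length",
]


class InvalidParameterError(ValueError):
    """A parameter is missing, non-positive where positivity is required,
    or would produce a zero denominator in a derived quantity."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise InvalidParameterError(f"parameter {name!r} must be finite and > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if value < 0.0 or not math.isfinite(value):
        raise InvalidParameterError(f"parameter {name!r} must be finite and >= 0, got {value!r}")


@dataclass
class PhysicalParams:
    """Dimensional parameters of the agent and continuum models.

    The single symbol ``Da`` of the field-theoretic literature is split here
    into ``Da_rot`` (rotational noise intensity of discrete agents, rad^2/time)
    and ``Da_trans`` (translational diffusivity of the coarse-grained density,
    length^2/time): the two have different units and roles.

    ``c_o`` (the characteristic field amplitude) defaults to the steady-state
    production/decay balance ``k_plus * rho_o / k_minus`` when not supplied.
    """

    vo: float = 1.0          # agent speed
    Da_rot: float = 0.5      # rotational noise intensity (agent model)
    Da_trans: float = 1.0    # translational diffusivity (continuum density)
    G: float = 1.0           # rotational gain on the field gradient
    chi: float = 1.0         # chemotactic gain
    k_plus: float = 1.0      # field production rate per source
    k_minus: float = 1.0     # field decay rate
    Dc: float = 1.0          # field diffusivity
    ks: float = 1.0          # substrate excavation rate
    c_star: float = 0.5      # field threshold for excavation
    rho_a_star: float = 0.5  # density threshold for excavation
    rho_o: float = 1.0       # mean agent density
    c_o: Optional[float] = None  # characteristic field amplitude (None -> k_plus*rho_o/k_minus)
    la: float = 1.0          # agent body length
    a: float = 0.2           # agent disk radius

    def __post_init__(self) -> None:
        for name in ("Da_rot", "Da_trans", "G", "chi", "k_plus", "k_minus",
                     "Dc", "ks", "c_star", "rho_a_star"):
            _require_nonnegative(name, getattr(self, name))
        for name in ("vo", "rho_o", "la", "a"):
            _require_positive(name, getattr(self, name))
        if self.c_o is None:
            if self.k_minus <= 0.0:
                raise InvalidParameterError(
                    "c_o cannot default to k_plus*rho_o/k_minus with k_minus == 0; "
                    "supply c_o explicitly or a positive k_minus")
            self.c_o = self.k_plus * self.rho_o / self.k_minus
        _require_positive("c_o", self.c_o)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NonDimGroups:
    """The dimensionless groups plus scaled thresholds and sharpnesses.

    ``alpha_c`` and ``alpha_rho`` are the steepnesses of the smoothed
    threshold switches in the erosion law; they default equal, and the
    density switch is given its own symbol because its argument is a density
    rather than a field amplitude.
    """

    C: float = 1.0
    E: float = 1.0
    V: float = 1.0
    k_hat: float = 2.0
    Dc_hat: float = 1.0
    c_star: float = 0.25
    rho_a_star: float = 0.25
    alpha_c: float = 20.0
    alpha_rho: Optional[float] = None
    l: float = 1.0

    def __post_init__(self) -> None:
        for name in ("C", "E", "V", "k_hat", "Dc_hat"):
            _require_nonnegative(name, getattr(self, name))
        _require_positive("l", self.l)
        if self.alpha_rho is None:
            self.alpha_rho = self.alpha_c

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Timescales:
    """The seven process timescales.

    tau_a     density diffusion over l          l^2 / Da_trans
    tau_v     migration over l                  l / vo
    tau_x     chemotactic drift over l          l^2 / (chi c_o)
    tau_c     field diffusion over l            l^2 / Dc
    tau_minus field decay                       1 / k_minus
    tau_prod  field production to amplitude c_o c_o / (k_plus rho_o)
    tau_s     substrate erosion                 1 / ks
    """

    tau_a: float
    tau_v: float
    tau_x: float
    tau_c: float
    tau_minus: float
    tau_prod: float
    tau_s: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Geometry:
    """Annular corral inside a square simulation domain."""

    Ro: float = 5.0
    Ri: float = 2.5
    domain_half_width: float = 6.0
    center: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.Ri < self.Ro <= self.domain_half_width):
            raise InvalidParameterError(
                f"geometry requires 0 < Ri < Ro <= domain_half_width, got "
                f"Ri={self.Ri}, Ro={self.Ro}, domain_half_width={self.domain_half_width}")

    def to_dict(self) -> dict:
        return {"Ro": self.Ro, "Ri": self.Ri,
                "domain_half_width": self.domain_half_width,
                "center": list(self.center)}


def characteristic_length(p: PhysicalParams) -> float:
    """l = min(sqrt(Dc / k_minus), la); ties resolved by plain <=."""
    if p.k_minus <= 0.0:
        raise InvalidParameterError("characteristic length needs k_minus > 0")
    return min(math.sqrt(p.Dc / p.k_minus), p.la)


def nondimensionalize(p: PhysicalParams, geom: Optional[Geometry] = None) -> NonDimGroups:
    """Map dimensional parameters onto the five dimensionless groups.

    Thresholds are scaled by their natural amplitudes: ``c_star / c_o`` and
    ``rho_a_star / rho_o``.  The geometry is accepted for interface symmetry
    (lengths in it are not rescaled here; solvers rescale on demand).
    """
    for name in ("vo", "Da_trans", "k_minus", "c_o", "rho_o"):
        _require_positive(name, getattr(p, name))
    l = characteristic_length(p)
    return NonDimGroups(
        C=p.chi * p.c_o / p.Da_trans,
        E=p.ks * l / p.vo,
        V=p.vo * l / p.Da_trans,
        k_hat=p.k_plus * p.rho_o / (p.k_minus * p.c_o),
        Dc_hat=p.Dc / (l * l * p.k_minus),
        c_star=p.c_star / p.c_o,
        rho_a_star=p.rho_a_star / p.rho_o,
        l=l,
    )


def timescales(p: PhysicalParams, l: Optional[float] = None) -> Timescales:
    """The seven process timescales at characteristic length ``l``
    (defaults to ``characteristic_length(p)``)."""
    if l is None:
        l = characteristic_length(p)
    _require_positive("l", l)
    for name in ("Da_trans", "vo", "chi", "Dc", "k_minus", "k_plus", "ks", "c_o", "rho_o"):
        _require_positive(name, getattr(p, name))
    return Timescales(
        tau_a=l * l / p.Da_trans,
        tau_v=l / p.vo,
        tau_x=l * l / (p.chi * p.c_o),
        tau_c=l * l / p.Dc,
        tau_minus=1.0 / p.k_minus,
        tau_prod=p.c_o / (p.k_plus * p.rho_o),
        tau_s=1.0 / p.ks,
    )
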