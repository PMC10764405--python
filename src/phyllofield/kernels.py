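"""Distance- and age-dependent field factors.

Each primordium emits fields whose strength at a point is
``threshold * E(d/d_max; alpha) * F(t; A, B)``: a distance kernel ``E``
normalized to 1 at the scaled distance ``x = 1``, times a logistic age factor
``F`` that switches the emission on as the primordium matures.  Two kernel
families are used: the power law ``x**-alpha`` (dual-field model, both the
inductive and the inhibitory field) and a tanh-based kernel (EDC2 baseline).

The maximum range ``d_max`` enters only through the adimensional ratio
``Gamma = d_max / (R0 sqrt(N))``; with ``R0 = 1`` the kernel's unit length is
``Gamma * sqrt(N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import ApexGeometry, Primordium, radial_position, surface_distance

__all__ = [
    "AgeFactorParams",
    "FieldSpec",
    "kernel_power",
    "kernel_tanh",
    "age_factor",
    "field_strength",
    "effective_range",
]


@dataclass(frozen=True)
class AgeFactorParams:
    """Logistic age response: A is the steepness, B the timing (midpoint age)."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("age steepness A must be >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """One field emitted by every primordium.

    gamma is the maximum range over SAM size (Gamma = d_max/(R0 sqrt N)),
    alpha the steepness of the distance decline, age the logistic emission
    schedule.  threshold is 1 throughout this work.
    """

    gamma: float
    alpha: float
    age: AgeFactorParams
    threshold: float = 1.0
    kernel_kind: Literal["power", "tanh"] = "power"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.kernel_kind not in ("power", "tanh"):
            raise ValueError(f"unknown kernel kind {self.kernel_kind!r}")


def kernel_power(x, alpha: float):
    """Power-law distance kernel ``x**-alpha``; equals 1 at x = 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("scaled distance x must be positive")
    out = x ** (-alpha)
    return float(out) if out.ndim == 0 else out


def kernel_tanh(x, alpha: float, E_th: float = 1.0):
    """EDC2 distance kernel ``E_th * (coth(alpha x) - 1) / (coth(alpha) - 1)``.

    Positive and strictly decreasing for x > 0, equals E_th at x = 1 and
    decays to 0 as x -> inf.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("scaled distance x must be positive")
    norm = 1.0 / np.tanh(alpha) - 1.0
    out = E_th * (1.0 / np.tanh(alpha * x) - 1.0) / norm
    return float(out) if out.ndim == 0 else out


def age_factor(t, p: AgeFactorParams):
    """Logistic emission schedule ``F(t) = 1 / (1 + exp(-A (t - B)))``."""
    t = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + np.exp(-p.A * (t - p.B)))
    return float(out) if out.ndim == 0 else out


def field_strength(theta_deg, primordia: Sequence[Primordium], spec: FieldSpec,
                   g: ApexGeometry):
    """Total field strength at grid angle(s) on the SAM periphery.

    Sums ``threshold * E(d_m/d_max) * F(t_m)`` over all primordia, with
    ``d_m`` the surface distance from primordium m to the point
    ``(R0, psi/2, theta)`` and ``d_max = gamma * R0 * sqrt(N)``.  A point
    coinciding with a primordium centre is assigned +inf (it can never host a
    new primordium).  This is the readable reference implementation; the
    simulation engine uses an equivalent vectorized path.
    """
    scalar = np.ndim(theta_deg) == 0
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    total = np.zeros(theta.shape)
    d_max = spec.gamma * g.R0 * np.sqrt(g.N)
    for p in primordia:
        r = radial_position(p, g)
        d = np.atleast_1d(surface_distance(r, p.theta, g.R0, theta, g))
        x = d / d_max
        contrib = np.full_like(x, np.inf)
        pos = x > 0.0
        if spec.kernel_kind == "power":
            contrib[pos] = x[pos] ** (-spec.alpha)
        else:
            norm = 1.0 / np.tanh(spec.alpha) - 1.0
            contrib[pos] = (1.0 / np.tanh(spec.alpha * x[pos]) - 1.0) / norm
        total += spec.threshold * contrib * age_factor(p.t, spec.age)
    return float(total[0]) if scalar else total


def effective_range(t, spec: FieldSpec):
    """Scaled radius at which a lone primordium's field equals its threshold.

    For the power kernel, ``E(x) F(t) = 1`` solves to ``x = F(t)**(1/alpha)``,
    i.e. an effective range ``Gamma * F(t)**(1/alpha)`` in units of
    ``R0 sqrt N``; it increases with age and saturates at Gamma.  The tanh
    kernel has no closed form and is not needed by the theory.
    """
    if spec.kernel_kind != "power":
        raise NotImplementedError("effective_range is defined for the power kernel only")
    t = np.asarray(t, dtype=float)
    F = 1.0 / (1.0 + np.exp(-spec.age.A * (t - spec.age.B)))
    out = spec.gamma * F ** (1.0 / spec.alpha)
    return float(out) if out.ndim == 0 else out
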