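"""Coordinates and growth bookkeeping on the conical shoot apex.

The shoot apex is modelled as a cone with apical angle ``psi``; its flatness is
``N = sin(psi/2)`` (``N = 1`` is a flat disc, ``N -> 0`` a needle).  New leaf
primordia arise on the SAM periphery, the circle at slant distance ``R0`` from
the cone vertex, and are carried away radially by the exponential growth of the
apex, so a primordium of standardized age ``t`` sits at radius ``R0 * exp(t)``.
All lengths are expressed in units of ``R0`` unless stated otherwise; angles are
stored in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ApexGeometry",
    "Primordium",
    "radial_position",
    "standardized_plastochron",
    "surface_distance",
    "wrap_angle",
    "signed_angle_difference",
]


def wrap_angle(theta_deg):
    """Map an angle (degrees) into [0, 360)."""
    return np.asarray(theta_deg) % 360.0 if np.ndim(theta_deg) else float(theta_deg) % 360.0


def signed_angle_difference(a_deg, b_deg):
    """Signed difference ``a - b`` in degrees, mapped to (-180, 180].

    The representative of a half-turn is +180 by convention, so distichous
    divergence series come out constant rather than sign-flipping.
    """
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float) + 180.0) % 360.0 - 180.0
    d = np.where(d == -180.0, 180.0, d)
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class ApexGeometry:
    """Conical apex shape: flatness ``N`` and SAM peripheral radius ``R0``."""

    N: float
    R0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.N <= 1.0:
            raise ValueError(f"flatness N must be in (0, 1], got {self.N}")
        if self.R0 <= 0.0:
            raise ValueError(f"SAM radius R0 must be positive, got {self.R0}")

    @property
    def psi(self) -> float:
        """Apical angle in radians, ``psi = 2*arcsin(N)``."""
        return 2.0 * math.asin(self.N)


@dataclass
class Primordium:
    """One leaf primordium.

    index is the ordinal position in emergence order (1 = oldest), theta the
    angular position in degrees in [0, 360), t the standardized age
    (dimensionless, 0 at initiation) and t_emergence the simulation time at
    which it was initiated.  The radial position is always derived from the age
    (see :func:`radial_position`), never stored.
    """

    index: int
    theta: float
    t: float = 0.0
    t_emergence: float = 0.0

    def __post_init__(self) -> None:
        self.theta = wrap_angle(self.theta)
        if self.t < 0.0:
            raise ValueError("standardized age t must be >= 0")


def radial_position(p: Primordium, g: ApexGeometry) -> float:
    """Radial (slant) distance of a primordium from the cone vertex.

    Exponential apical growth gives ``r = R0 * exp(t)``; a newly initiated
    primordium (t = 0) sits exactly on the SAM periphery.
    """
    if p.t < 0.0:
        raise ValueError("standardized age t must be >= 0")
    return g.R0 * math.exp(p.t)


def standardized_plastochron(r_m: float, r_next: float) -> float:
    """Standardized plastochron ``G = ln(r_m / r_next)`` of consecutive primordia.

    Equals the natural log of the plastochron ratio, and the difference of the
    standardized ages of the two primordia.  ``r_m`` is the older (outer)
    primordium's radius.
    """
    if r_m <= 0.0 or r_next <= 0.0:
        raise ValueError("radii must be positive")
    if r_m < r_next:
        raise ValueError("older primordium must lie at or beyond the younger one")
    return math.log(r_m / r_next)


def surface_distance(r1, theta1_deg, r2, theta2_deg, g: ApexGeometry):
    """Modified surface distance between two points on the cone.

    ``d = sqrt((r1-r2)^2/N + 2 N r1 r2 (1 - cos(theta1-theta2)))``: a smooth
    stand-in for the geodesic that avoids the discontinuity of unrolling the
    cone.  Symmetric in its two points; zero iff they coincide.  Accepts
    scalars or numpy arrays.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("radii must be positive")
    dtheta = np.radians(np.asarray(theta1_deg, dtype=float) - np.asarray(theta2_deg, dtype=float))
    d2 = (r1 - r2) ** 2 / g.N + 2.0 * g.N * r1 * r2 * (1.0 - np.cos(dtheta))
    d = np.sqrt(d2)
    return float(d) if d.ndim == 0 else d
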