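"""Closed-form analysis of the simplified one-primordium situation.

With a single existing primordium, a new one can only be initiated at the
moment t* when the primordium's effective induction range first exceeds its
effective inhibition range at a point of the SAM periphery, i.e. when

    Gamma_Y * F_Y(t*)^(1/alpha_Y) = Gamma_S * F_S(t*)^(1/alpha_S)

(equivalently d_Y/d_S equals the ratio of the logistic bracket terms).  The
divergence angle theta* follows by intersecting the effective induction
circle of the aged primordium with the periphery circle in the modified cone
metric.  t* and theta* predict the standardized plastochron G and the
divergence angle of the steep-spiral (costoid) and one-sided distichous
patterns.  The B_Y axis splits into zones: induction always encompassing
inhibition (EDC2-like patterns; no solution), a solution with t* below or
above the inhibition-only plastochron G_S, and inhibition always encompassing
induction on the periphery (no primordium formation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .kernels import AgeFactorParams, FieldSpec, effective_range
from .simulator import NewModelParams, SimulationConfig, run

__all__ = [
    "Zone",
    "TheorySolution",
    "DegenerateIdentityError",
    "NoSolutionError",
    "solve_tstar",
    "theta_star",
    "zone",
    "classify_zone",
    "reference_plastochron",
    "theta_vs_R0_curve",
]


class Zone(str, Enum):
    """Existence zones of the one-primordium solution along a parameter axis."""

    INDUCTION_ENCOMPASSES = "induction_encompasses"   # red: no solution, Y-range always wider
    SOLUTION_BELOW_GS = "solution_below_GS"           # yellow: t* < G_S
    SOLUTION_ABOVE_GS = "solution_above_GS"           # blue: t* > G_S
    INHIBITION_ENCOMPASSES = "inhibition_encompasses"  # grey: no solution on the periphery


class DegenerateIdentityError(ValueError):
    """The range-balance equation holds identically (symmetric parameters)."""


class NoSolutionError(ValueError):
    """theta* does not exist (the induction circle misses the SAM periphery)."""


@dataclass(frozen=True)
class TheorySolution:
    t_star: Optional[float]
    theta_star: Optional[float]
    zone: Zone
    G_S: float


def _range_specs(params: NewModelParams) -> tuple[FieldSpec, FieldSpec]:
    spec_Y = FieldSpec(params.gamma_Y, params.alpha_Y,
                       AgeFactorParams(params.A_Y, params.B_Y))
    spec_S = FieldSpec(params.gamma_S, params.alpha_S,
                       AgeFactorParams(params.A_S, params.B_S))
    return spec_Y, spec_S


def _range_balance(params: NewModelParams):
    """f(t) = effective induction range - effective inhibition range."""
    spec_Y, spec_S = _range_specs(params)

    def f(t):
        return effective_range(t, spec_Y) - effective_range(t, spec_S)

    return f


def solve_tstar(params: NewModelParams, t_max: float = 10.0,
                scan_step: float = 1e-3, tol: float = 1e-10) -> list[float]:
    """All roots t* of the range-balance equation in (0, t_max].

    Sign-change scan on a uniform grid followed by bisection refinement.  An
    empty list means the ranges never balance (red or grey zone).  Raises
    DegenerateIdentityError when the equation holds identically (both fields
    have the same range, steepness and age schedule).
    """
    if (params.gamma_Y == params.gamma_S and params.alpha_Y == params.alpha_S
            and params.A_Y == params.A_S and params.B_Y == params.B_S):
        raise DegenerateIdentityError(
            "inductive and inhibitory ranges are identical for all ages")
    f = _range_balance(params)
    ts = np.arange(scan_step, t_max + scan_step, scan_step)
    vals = np.array([f(t) for t in ts])
    if np.all(np.abs(vals) < tol):
        raise DegenerateIdentityError("range balance holds identically on the scan grid")
    roots: list[float] = []
    for i in range(len(ts) - 1):
        if vals[i] == 0.0:
            roots.append(float(ts[i]))
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(float(brentq(f, ts[i], ts[i + 1], xtol=tol)))
    if vals[-1] == 0.0:
        roots.append(float(ts[-1]))
    return roots


def theta_star(t_star: float, params: NewModelParams, R0: float = 1.0) -> float:
    """Divergence angle (degrees) of the one-primordium solution.

    Intersects the effective induction circle of the primordium aged t* with
    the SAM periphery in the modified cone metric:

        cos(theta*) = 1 - (d_Y^2/R0^2 * F_Y(t*)^(2/alpha_Y)
                           - (e^t* - 1)^2 / N) / (2 e^t* N)

    The gamma parameters define the physical ranges at unit SAM radius
    (d_Y = Gamma_Y * sqrt(N)); passing another ``R0`` rescales the apex while
    holding those physical ranges fixed, which is how the size dependence of
    the divergence angle is probed.  Raises NoSolutionError when the argument
    leaves [-1, 1] (the circles do not intersect).
    """
    p = params
    F_Y = 1.0 / (1.0 + np.exp(-p.A_Y * (t_star - p.B_Y)))
    rho2_scaled = p.gamma_Y ** 2 * p.N / R0 ** 2 * F_Y ** (2.0 / p.alpha_Y)  # (rho_Y/R0)^2
    e_t = np.exp(t_star)
    arg = 1.0 - (rho2_scaled - (e_t - 1.0) ** 2 / p.N) / (2.0 * e_t * p.N)
    if arg > 1.0 + 1e-12 or arg < -1.0 - 1e-12:
        raise NoSolutionError(
            f"induction circle does not intersect the SAM periphery (cos theta* = {arg:.6g})")
    return float(np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))))


def reference_plastochron(params: NewModelParams,
                          config: Optional[SimulationConfig] = None,
                          window: int = 8) -> float:
    """G_S: converged plastochron of an inhibition-only run with the same
    inhibitory parameters (the EDC2-like reference level of the zone plots)."""
    if config is None:
        config = SimulationConfig(max_primordia=24)
    result = run(params, config, induction_test=False)
    G = np.diff(result.emergence_times)
    if G.size == 0:
        raise NoSolutionError("inhibition-only run formed no primordia")
    return float(G[-window:].mean())


def classify_zone(params: NewModelParams, G_S: float,
                  t_max: float = 10.0) -> TheorySolution:
    """Zone label plus the solution (if any) for one parameter setting.

    A root of the range-balance equation is a solution only if its theta*
    exists (the balanced circles actually intersect the periphery).  Without a
    solution the axis point is either red — at the moment the inhibition
    circle first frees a point of the periphery the induction range is
    already the wider one, so initiation is never induction-limited — or grey,
    where the induction circle never pokes beyond the inhibition circle on the
    periphery and nothing forms.
    """
    roots = solve_tstar(params, t_max=t_max)
    valid: list[tuple[float, float]] = []
    for t in roots:
        try:
            valid.append((t, theta_star(t, params)))
        except NoSolutionError:
            continue
    if valid:
        t0, th0 = valid[0]
        z = Zone.SOLUTION_BELOW_GS if t0 < G_S else Zone.SOLUTION_ABOVE_GS
        return TheorySolution(t0, th0, z, G_S)
    spec_Y, spec_S = _range_specs(params)
    N = params.N

    def freed(t):
        # scaled far-edge distance of the periphery minus the inhibition range
        d_max = np.sqrt(((np.exp(t) - 1.0) ** 2 / N + 4.0 * N * np.exp(t)) / N)
        return d_max - effective_range(t, spec_S)

    ts = np.linspace(1e-3, t_max, 4000)
    vals = np.array([freed(t) for t in ts])
    pos = np.flatnonzero(vals > 0.0)
    if pos.size == 0:
        # inhibition never releases the periphery in the scan window
        return TheorySolution(None, None, Zone.INHIBITION_ENCOMPASSES, G_S)
    i = pos[0]
    t_S = ts[i] if i == 0 else brentq(freed, ts[i - 1], ts[i], xtol=1e-10)
    if effective_range(t_S, spec_Y) >= effective_range(t_S, spec_S):
        z = Zone.INDUCTION_ENCOMPASSES
    else:
        z = Zone.INHIBITION_ENCOMPASSES
    return TheorySolution(None, None, z, G_S)


def zone(params: NewModelParams, G_S: float) -> Zone:
    """Zone label only (see :func:`classify_zone`)."""
    return classify_zone(params, G_S).zone


def theta_vs_R0_curve(R0_values, eff_range: float = 3.0, G: float = 0.6,
                      N: float = 1.0 / 3.0):
    """theta*(R0) with the effective ranges and plastochron held fixed.

    Holds the physical effective induction range (d_Y/sqrt N) F_Y^(1/alpha_Y)
    at ``eff_range`` and the plastochron at ``G`` while the SAM radius varies;
    the divergence angle then decreases monotonically with R0.  Returns a list
    of (R0, theta*) pairs; radii where the circles do not intersect are
    omitted.
    """
    rho2 = eff_range ** 2 * N  # (d_Y F^(1/alpha))^2 in length^2
    e_t = np.exp(G)
    out = []
    for R0 in np.atleast_1d(np.asarray(R0_values, dtype=float)):
        arg = 1.0 - (rho2 / R0 ** 2 - (e_t - 1.0) ** 2 / N) / (2.0 * e_t * N)
        if -1.0 <= arg <= 1.0:
            out.append((float(R0), float(np.degrees(np.arccos(arg)))))
    return out
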