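"""Time-stepping engine for the inhibitory-field and dual-field models.

A single primordium is seeded on the SAM periphery; at every time step the
field(s) are evaluated on a fine angular grid of the periphery and a new
primordium is initiated wherever the initiation condition holds (dual-field
model: inductive strength above threshold AND inhibitory strength below
threshold; EDC2: inhibitory strength below threshold).  Ages advance by the
time step, which through the exponential growth law moves every primordium
radially outward.  The engine is fully deterministic.

Symmetric ties.  A single seed is a mirror-symmetric initial condition, and
with exact arithmetic a deterministic engine would stay on the (unstable)
mirror-symmetric orbit forever — spirals could never emerge, although any
physical noise breaks the symmetry immediately (seedlings show random
handedness).  The engine therefore resolves exact ties between simultaneous
candidate sites deterministically: when several disjoint admissible arcs have
equal inhibitory minima (within ``tie_tol``), only the candidate nearest in
the positive angular direction from the youngest primordium is placed.  This
fixes the chirality convention (``chirality="cw"`` mirrors it).  Stable
whorls are unaffected: the suppressed twin site becomes admissible again
within a few steps and the pair is initiated with a near-zero plastochron.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import _engine
from .geometry import ApexGeometry, Primordium, wrap_angle

__all__ = [
    "NewModelParams",
    "EDC2Params",
    "EnlargementSchedule",
    "SimulationConfig",
    "SimulationResult",
    "gamma_schedule",
    "admissible_arcs",
    "place_primordia",
    "step",
    "run",
]


@dataclass(frozen=True)
class NewModelParams:
    """The nine independent parameters of the dual-field model.

    N: flatness of the apex cone; gamma_S/alpha_S/A_S/B_S the inhibitory
    field's range, distance steepness and age schedule; gamma_Y/alpha_Y/
    A_Y/B_Y the same for the inductive field.  Thresholds are fixed to 1.
    """

    N: float
    gamma_S: float
    alpha_S: float
    A_S: float
    B_S: float
    gamma_Y: float
    alpha_Y: float
    A_Y: float
    B_Y: float
    Y_th: float = 1.0
    S_th: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.N <= 1.0:
            raise ValueError("N must be in (0, 1]")
        for name in ("gamma_S", "alpha_S", "gamma_Y", "alpha_Y", "Y_th", "S_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("A_S", "A_Y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def geometry(self) -> ApexGeometry:
        return ApexGeometry(N=self.N)

    def replace(self, **kw) -> "NewModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EDC2Params:
    """The five independent parameters of the EDC2 baseline (tanh kernel)."""

    N: float
    gamma: float
    alpha: float
    A: float
    B: float
    E_th: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.N <= 1.0:
            raise ValueError("N must be in (0, 1]")
        if self.gamma <= 0 or self.alpha <= 0 or self.E_th <= 0:
            raise ValueError("gamma, alpha and E_th must be positive")
        if self.A < 0:
            raise ValueError("A must be >= 0")

    @property
    def geometry(self) -> ApexGeometry:
        return ApexGeometry(N=self.N)

    def replace(self, **kw) -> "EDC2Params":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EnlargementSchedule:
    """Time-dependent field ranges emulating SAM enlargement.

    As the SAM radius grows from an initial to a final value, both adimensional
    ranges shrink along a tanh ramp centred at t_i with time scale tau:
    ``Gamma_S(t) = (Gamma_S_i + Gamma_S_f)/2 - (Gamma_S_i - Gamma_S_f)/2 *
    tanh((t - t_i)/tau)`` and ``Gamma_Y(t) = Gamma_S(t) * Gamma_Y_f /
    Gamma_S_f`` (both ranges scale with the same 1/R0(t)).
    """

    gamma_S_i: float
    gamma_S_f: float
    t_i: float
    tau: float
    gamma_Y_f: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.gamma_S_i, self.gamma_S_f, self.gamma_Y_f) <= 0:
            raise ValueError("range limits must be positive")


def gamma_schedule(t_sim: float, schedule: EnlargementSchedule) -> tuple[float, float]:
    """Instantaneous (Gamma_S, Gamma_Y) of the enlargement schedule."""
    s = schedule
    g_S = 0.5 * (s.gamma_S_i + s.gamma_S_f) \
        - 0.5 * (s.gamma_S_i - s.gamma_S_f) * np.tanh((t_sim - s.t_i) / s.tau)
    g_Y = g_S * s.gamma_Y_f / s.gamma_S_f
    return float(g_S), float(g_Y)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical controls of the engine.

    dt is the standardized time step, angular_resolution the peripheral grid
    spacing in degrees.  Stopping rules: at most max_primordia primordia, a
    running emergence-gap monitor (stop once the time since the last
    initiation exceeds max_gap_G) and a time budget (stop once elapsed time
    reaches t_budget_factor times the primordium count).  start_time shifts
    the clock (used by enlargement runs so a chosen primordium emerges near
    t_sim = 0); jitter adds a tiny angular offset to the seed for chirality
    experiments and is off by default.
    """

    dt: float = 1e-3
    angular_resolution: float = 0.1
    max_primordia: int = 100
    max_gap_G: float = 5.0
    t_budget_factor: float = 2.0
    initial_theta: float = 0.0
    start_time: float = 0.0
    jitter: float = 0.0
    chirality: str = "ccw"
    tie_tol: float = 1e-9
    trace_every: int = 200

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_grid = 360.0 / self.angular_resolution
        if abs(n_grid - round(n_grid)) > 1e-9:
            raise ValueError("angular_resolution must divide 360")
        if self.max_primordia < 1:
            raise ValueError("max_primordia must be >= 1")
        if self.chirality not in ("ccw", "cw"):
            raise ValueError("chirality must be 'ccw' or 'cw'")

    @property
    def n_grid(self) -> int:
        return int(round(360.0 / self.angular_resolution))


@dataclass
class SimulationResult:
    """Outcome of a run: emergence order, angles, times and bookkeeping."""

    thetas: np.ndarray            # degrees, emergence order
    emergence_times: np.ndarray   # simulation time of initiation
    termination: str              # max_primordia | gap_exceeded | time_budget
    params_used: Union[NewModelParams, EDC2Params]
    config: SimulationConfig
    t_final: float
    initiation_Y: np.ndarray      # inductive strength at each initiation (nan for EDC2)
    initiation_S: np.ndarray      # inhibitory strength at each initiation
    schedule: Optional[EnlargementSchedule] = None
    schedule_trace: Optional[np.ndarray] = None  # columns t_sim, Gamma_S, Gamma_Y

    @property
    def n_primordia(self) -> int:
        return len(self.thetas)

    @property
    def primordia(self) -> list[Primordium]:
        return [
            Primordium(index=i + 1, theta=float(th),
                       t=float(self.t_final - te), t_emergence=float(te))
            for i, (th, te) in enumerate(zip(self.thetas, self.emergence_times))
        ]


class _State:
    """Mutable engine state (internal)."""

    def __init__(self, params, config: SimulationConfig,
                 schedule: Optional[EnlargementSchedule], induction_test: bool):
        self.params = params
        self.config = config
        self.schedule = schedule
        self.is_edc2 = isinstance(params, EDC2Params)
        self.induction_test = induction_test and not self.is_edc2
        J = config.n_grid
        self.theta_grid = np.arange(J) * config.angular_resolution
        self._grid_rad = np.radians(self.theta_grid)
        cap = config.max_primordia
        self.cos_table = np.empty((cap, J))
        self.thetas = np.empty(cap)
        self.t_em = np.empty(cap)
        self.init_Y = np.empty(cap)
        self.init_S = np.empty(cap)
        self.n = 0
        self.t_sim = config.start_time
        self.step_count = 0
        self.Y = np.zeros(J)
        self.S = np.zeros(J)
        self.trace: list[tuple[float, float, float]] = []
        seed_theta = wrap_angle(config.initial_theta + config.jitter)
        self.add_primordium(seed_theta, self.t_sim, np.nan, np.nan)

    def add_primordium(self, theta_deg: float, t_sim: float, Y_val, S_val) -> None:
        i = self.n
        self.thetas[i] = theta_deg
        self.t_em[i] = t_sim
        self.cos_table[i] = np.cos(self._grid_rad - np.radians(theta_deg))
        self.init_Y[i] = Y_val
        self.init_S[i] = S_val
        self.n += 1

    def current_gammas(self) -> tuple[float, float]:
        if self.schedule is not None:
            return gamma_schedule(self.t_sim, self.schedule)
        if self.is_edc2:
            return self.params.gamma, np.nan
        return self.params.gamma_S, self.params.gamma_Y

    def evaluate_fields(self) -> None:
        p = self.params
        ages = self.t_sim - self.t_em[: self.n]
        g_S, g_Y = self.current_gammas()
        if self.is_edc2:
            d0 = g_S * np.sqrt(p.N)
            _engine.accumulate_tanh(self.S, self.cos_table, self.n, ages,
                                    p.N, 1.0 / d0, p.alpha, p.A, p.B)
            self.Y.fill(np.inf)  # no induction requirement
        else:
            inv_dY2 = 1.0 / (g_Y * g_Y * p.N)
            inv_dS2 = 1.0 / (g_S * g_S * p.N)
            _engine.accumulate_dual(self.Y, self.S, self.cos_table, self.n, ages,
                                    p.N, inv_dY2, p.alpha_Y, p.A_Y, p.B_Y,
                                    inv_dS2, p.alpha_S, p.A_S, p.B_S)


def admissible_arcs(theta_grid, Y, S, Y_th: float, S_th: float) -> list[np.ndarray]:
    """Maximal contiguous grid arcs where Y > Y_th and S < S_th.

    Arcs wrap around 360 degrees; pass ``Y=None`` to drop the induction test
    (EDC2).  Returns a list of index arrays, in ascending order of their first
    (wrap-adjusted) index.
    """
    cond = S < S_th
    if Y is not None:
        cond = cond & (Y > Y_th)
    if not cond.any():
        return []
    idx = np.flatnonzero(cond)
    if cond.all():
        return [idx]
    brk = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, brk + 1)
    if cond[0] and cond[-1] and len(runs) > 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    return runs


def place_primordia(arcs: Sequence[np.ndarray], Y, S, state=None) -> list[int]:
    """One candidate site per disjoint arc: the arc's grid point of minimal
    inhibitory strength (ties broken to the lowest grid index).

    Returns the chosen grid indices, one per arc.
    """
    chosen = []
    for arc in arcs:
        s_arc = S[arc]
        smin = s_arc.min()
        chosen.append(int(arc[s_arc <= smin].min()))
    return chosen


def _resolve_ties(cands: list[int], S, last_theta: float,
                  resolution: float, tie_tol: float, chirality: str) -> list[int]:
    """Deterministic chirality rule for exactly tied simultaneous candidates."""
    if len(cands) <= 1:
        return cands
    smins = np.array([S[c] for c in cands])
    keep: list[int] = []
    used = np.zeros(len(cands), dtype=bool)
    for i in np.argsort(smins, kind="stable"):
        if used[i]:
            continue
        tol = tie_tol * max(1.0, abs(smins[i]))
        tied = [k for k in range(len(cands))
                if not used[k] and abs(smins[k] - smins[i]) <= tol]
        for k in tied:
            used[k] = True
        if len(tied) == 1:
            keep.append(tied[0])
            continue
        offsets = []
        for k in tied:
            off = (cands[k] * resolution - last_theta) % 360.0
            if chirality == "cw":
                off = (360.0 - off) % 360.0
            offsets.append((off, k))
        keep.append(min(offsets)[1])
    return [cands[k] for k in sorted(keep)]


def step(state: _State) -> list[int]:
    """Advance one time step; returns grid indices of primordia initiated."""
    state.step_count += 1
    state.t_sim = state.config.start_time + state.step_count * state.config.dt
    state.evaluate_fields()
    if state.schedule is not None and state.step_count % state.config.trace_every == 1:
        g_S, g_Y = state.current_gammas()
        state.trace.append((state.t_sim, g_S, g_Y))
    p = state.params
    if state.is_edc2:
        arcs = admissible_arcs(state.theta_grid, None, state.S, np.nan, p.E_th)
    else:
        Y = state.Y if state.induction_test else None
        arcs = admissible_arcs(state.theta_grid, Y, state.S, p.Y_th, p.S_th)
    if not arcs:
        return []
    cands = place_primordia(arcs, state.Y, state.S)
    cands = _resolve_ties(cands, state.S, state.thetas[state.n - 1],
                          state.config.angular_resolution,
                          state.config.tie_tol, state.config.chirality)
    placed = []
    for c in cands:
        if state.n >= state.config.max_primordia:
            break
        y_val = np.nan if state.is_edc2 else state.Y[c]
        state.add_primordium(c * state.config.angular_resolution, state.t_sim,
                             y_val, state.S[c])
        placed.append(c)
    return placed


def run(params: Union[NewModelParams, EDC2Params],
        config: Optional[SimulationConfig] = None,
        schedule: Optional[EnlargementSchedule] = None,
        induction_test: bool = True) -> SimulationResult:
    """Run a simulation from a single seed primordium until a stopping rule fires.

    ``induction_test=False`` disables the inductive-threshold requirement of
    the dual-field model (used for the inhibition-only reference runs of the
    theory); it is ignored for EDC2 parameters.
    """
    if config is None:
        config = SimulationConfig()
    if schedule is not None and isinstance(params, EDC2Params):
        raise ValueError("enlargement schedule is defined for the dual-field model")
    state = _State(params, config, schedule, induction_test)
    while True:
        if state.n >= config.max_primordia:
            termination = "max_primordia"
            break
        if state.t_sim - state.t_em[state.n - 1] > config.max_gap_G:
            termination = "gap_exceeded"
            break
        if state.t_sim - config.start_time >= config.t_budget_factor * state.n:
            termination = "time_budget"
            break
        step(state)
    trace = np.array(state.trace) if state.trace else None
    return SimulationResult(
        thetas=state.thetas[: state.n].copy(),
        emergence_times=state.t_em[: state.n].copy(),
        termination=termination,
        params_used=params,
        config=config,
        t_final=state.t_sim,
        initiation_Y=state.init_Y[: state.n].copy(),
        initiation_S=state.init_S[: state.n].copy(),
        schedule=schedule,
        schedule_trace=trace,
    )
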