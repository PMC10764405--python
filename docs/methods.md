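# Methods

## Model

The shoot apex is a cone with apical angle ψ, flatness `N = sin(ψ/2)`
(`N = 1/3` throughout the shipped presets).  Positions are spherical
coordinates `(r, ψ/2, θ)`; new primordia can form only on the SAM periphery,
the circle `M` at slant radius `R0` from the vertex.  Exponential apical
growth carries a primordium of standardized age `t` to radius
`r = R0·e^t`; the standardized plastochron `G = t_m − t_{m+1} =
ln(r_m/r_{m+1})` is the natural log of the plastochron ratio.  All lengths
are expressed in units of `R0`, all times in units of `R0/V0` (the inverse
relative growth rate); neither quantity appears independently anywhere in
the engine.

Distances between points on the cone use the modified metric

    d² = (r₁ − r₂)²/N + 2 N r₁ r₂ (1 − cos(θ₁ − θ₂)),

a smooth surrogate for the unrolled-cone geodesic that avoids the
discontinuity of cutting the cone open.

Dual-field model.  Every primordium emits an inductive and an inhibitory
field.  On `M`:

    Y(θ) = Σ_m Y_th (d_m(θ)/d_Y)^(−α_Y) F(t_m; A_Y, B_Y)
    S(θ) = Σ_m S_th (d_m(θ)/d_S)^(−α_S) F(t_m; A_S, B_S)
    F(t; A, B) = 1 / (1 + e^(−A(t−B)))

A new primordium appears wherever `Y > Y_th` and `S < S_th` (both thresholds
fixed to 1).  Only the adimensional ranges `Γ_Y = d_Y/(R0√N)` and
`Γ_S = d_S/(R0√N)` matter, so the model has nine independent parameters:
`N, Γ_S, α_S, A_S, B_S, Γ_Y, α_Y, A_Y, B_Y`.

EDC2 baseline.  Same geometry, a single inhibitory field with the tanh
kernel `E(x) = E_th(coth(αx) − 1)/(coth(α) − 1)`, initiation where
`I(θ) < E_th`; five parameters `N, Γ, α, A, B`.  The kernels are treated
exactly as their formulas state — the unit length `d_Y/d_S/d_0` is a scale,
not a truncation radius, and the field sum runs over *all* primordia with no
distance cutoff.

SAM enlargement.  Growth of `R0` over developmental time is folded into the
adimensional ranges:

    Γ_S(t_sim) = (Γ_Si + Γ_Sf)/2 − (Γ_Si − Γ_Sf)/2 · tanh((t_sim − t_i)/τ)
    Γ_Y(t_sim) = Γ_S(t_sim) · Γ_Yf / Γ_Sf

with `t_i` the timing and `τ` the slowness of the enlargement.

## Engine numerics

* Peripheral grid of 0.1° (3600 points), time step Δt = 0.001; both
  configurable.  `cos(θ_j − θ_m)` rows are cached per primordium; the field
  accumulation is a numba-compiled double loop (pure-numpy fallback with
  identical semantics, equality-tested).
* A run seeds one primordium (age 0) at `initial_theta` and checks the
  initiation condition after every step.  Admissible grid points are grouped
  into maximal arcs (wrapping at 360°); each disjoint arc contributes one
  candidate at its minimum of `S` (ties to the lowest grid index).
* **Symmetric-tie resolution.**  A single seed is mirror-symmetric, and with
  exact arithmetic every deterministic, symmetry-respecting engine stays on
  the mirror-symmetric orbit forever — spirals, which are asymmetric, could
  never emerge even though they are the attractor and any physical noise
  reaches them immediately.  When simultaneous candidates have inhibitory
  minima equal within `tie_tol` (10⁻⁹ relative), only the candidate nearest
  counterclockwise of the youngest primordium is placed.  This is the
  package's chirality convention (`chirality="cw"` yields the exact mirror
  run; real seedlings show both handednesses at random).  Stable whorls are
  not suppressed: the twin site becomes admissible again within a few steps
  and the pair initiates with a near-zero plastochron; the classifier groups
  primordia closer than `node_gap = 0.02` into one node.
* Stopping rules: primordium count reaching `max_primordia` (default 100); a
  running gap monitor (stop once the time since the last initiation exceeds
  `max_gap_G = 5` — the running-G form of "G < 5", which is undefined until
  the next primordium exists); a time budget (stop once elapsed time reaches
  `t_budget_factor = 2` × primordium count).  For a seed-only run the budget
  (t = 2) fires before the gap monitor (t = 5); both label the same
  phenomenon, failure of primordium formation.
* No randomness anywhere.  `jitter` (tiny seed offset, default 0) exists for
  chirality experiments.  For enlargement runs `start_time` shifts the clock
  so a chosen primordium can emerge near t_sim = 0.

## Theory of the simplified one-primordium situation

A lone primordium's field crosses its threshold at the *effective range*
`ρ(t) = Γ·F(t)^(1/α)` (units `R0√N`).  A new primordium can first form when
the induction range overtakes the inhibition range:

    Γ_Y F_Y(t*)^(1/α_Y) = Γ_S F_S(t*)^(1/α_S),

solved by a 10⁻³ sign-change scan plus Brent refinement on (0, 10] (all
roots reported; identically balanced parameter sets raise a degenerate-
identity error instead of returning roots).  The divergence angle follows by
intersecting the effective induction circle with the periphery in the cone
metric:

    cos θ* = 1 − (Γ_Y² N F_Y^(2/α_Y)/R0² − (e^{t*} − 1)²/N) / (2 e^{t*} N),

raising a no-solution error outside the arccos domain rather than clamping.
`θ*` decreases as `R0` grows with the physical ranges fixed, which is the
mechanistic reading of the falling divergence angle in enlarging seedlings.

Zones along a parameter axis (e.g. `B_Y`): *induction-encompassing* (no
solution; at the first moment `t_S` when the inhibition circle frees a point
of the periphery, the induction range is already the wider one — initiation
is never induction-limited and the patterns are EDC2-like), *solution with
t* below/above `G_S`* (the plastochron of an inhibition-only run with
matched inhibitory parameters), and *inhibition-encompassing* (no solution
on the periphery; includes formal range-balance roots whose θ* violates the
arccos domain, because by the balance time the induction circle no longer
reaches the periphery — nothing forms).  Since `Γ_Y > Γ_S` always produces a
formal root at large t, the domain check is what makes the no-formation zone
exist; the red/grey discrimination via `t_S` reproduces a contiguous
red → yellow → blue → grey partition of the `B_Y` axis.

The theory is validated two independent ways: the engine's *first*
initiation from a single seed reproduces (t*, θ*) to grid precision, and a
geometric oracle (Brent root of the cone-metric circle intersection)
reproduces θ* to 10⁻⁶ degrees on random parameter draws.

The converged multi-primordium pattern deviates from (t*, θ*) by a few
percent and a few degrees — older primordia still contribute to both fields,
delaying initiation and shifting its site.  For the costoid preset the first
interval is (0.648, 52.9°) and the converged pattern (0.682, 55.9°).  This
gap is a property of the model, not a numerical artefact; the one-primordium
theory is an approximation whose quality decays as `G` shrinks.

## Classification

Statistics are taken over the last `window` intervals (default 20; the
transient is dropped).  Decision order: no-formation (≤ 1 primordium) →
whorled (modal node size ≥ 2; divergence measured between node centroids) →
irregular (sd of |divergence| > 5°) → one-sided distichy (strictly
sign-alternating with net drift < 1°/interval) → constant-sign categories by
mean |divergence|: distichous 180 ± 5°, Fibonacci 137.5 ± 5°, Lucas
99.5 ± 5°, costoid < 80° with mean G > 0.3, otherwise other-spiral.  The
bands are declared approximations chosen to separate the named fixed points
and the reported costoid range (~48–73° across species); all are
keyword-configurable.  Chirality is the sign of the mean signed divergence.

## Problem sizes

Default analyses use: costoid-type runs to 26–32 primordia (statistics over
the last 8–10 intervals; the pattern is locked by ~primordium 15), the
Fibonacci-spiral run to 100 primordia (last 20 intervals; locked by
~primordium 25), B_Y sweeps at 9–11 settings with 18 primordia per cell, and
zone scans at 25–41 settings.  These sizes were chosen as the point where
the reported statistics stop changing; larger runs reproduce the same values.

## Known limitations

* The converged divergence of the `fig2c_fibonacci` preset is 142.05°
  (period-2 oscillation 142.2/141.9, sd 0.15°).  This sits on the spiral
  branch a few degrees above the golden angle, as expected for a moderate
  inhibition range (`Γ_S = 1.9`); the branch approaches 137.5° only as the
  range shrinks.  The run is classified `fibonacci_spiral` by the ±5° band.
* The mirror-symmetry of the model is realized through the chirality
  convention: reflecting a run requires flipping `chirality`, not just the
  seed angle.
* Whorled patterns arise as near-simultaneous placements; from a
  single-seed start the shipped presets do not enter whorl-stable regimes,
  so whorl support is exercised by construction in tests rather than by a
  published preset.
* The classifier's category bands are heuristic; patterns near band edges
  (e.g. a 143° spiral) change label under band changes.
* Grid (0.1°) and step (10⁻³) quantize angles and emergence times; reported
  divergences are exact multiples of the grid.
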