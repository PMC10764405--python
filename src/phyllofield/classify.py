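"""Turn a primordium sequence into divergence/plastochron series and a
phyllotaxis category.

Categories follow the field's standard taxonomy: distichous (180), the
Fibonacci (137.5) and Lucas (99.5) spirals, whorled patterns (k primordia per
node), the two Zingiberales oddities — costoid (steep constant-sign spiral
with small divergence and large plastochron) and one-sided distichy
(sign-alternating divergence, two orthostichies on one side) — plus irregular
and no-formation outcomes.  The tolerance bands are declared approximations
chosen to separate the named fixed points; all are keyword-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import signed_angle_difference
from .simulator import SimulationResult

__all__ = ["PatternSummary", "divergence_series", "classify", "CATEGORIES"]

CATEGORIES = (
    "distichous",
    "fibonacci_spiral",
    "lucas_spiral",
    "other_spiral",
    "costoid",
    "one_sided_distichous",
    "whorled",
    "irregular",
    "no_formation",
)


@dataclass(frozen=True)
class PatternSummary:
    """Post-transient summary of a simulated pattern.

    mean_divergence and sd_divergence are statistics of the absolute
    divergence angle over the analysis window; chirality is the sign of the
    mean signed divergence ('none' for distichous/alternating/whorled
    patterns).
    """

    category: str
    mean_divergence: float
    sd_divergence: float
    mean_G: float
    primordia_per_node: int
    chirality: str
    n_primordia: int
    termination: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def divergence_series(thetas) -> np.ndarray:
    """Signed divergence angles between consecutive primordia, in (-180, 180].

    Input is the angular position sequence in emergence order (degrees); a
    half-turn is reported as +180.  Fewer than two positions give an empty
    series.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size < 2:
        return np.empty(0)
    return np.atleast_1d(signed_angle_difference(thetas[1:], thetas[:-1]))


def _group_nodes(thetas: np.ndarray, times: np.ndarray, node_gap: float):
    """Group primordia initiated within node_gap of each other into nodes."""
    nodes = [[0]]
    for i in range(1, len(times)):
        if times[i] - times[nodes[-1][0]] <= node_gap:
            nodes[-1].append(i)
        else:
            nodes.append([i])
    centroids = []
    node_times = []
    for members in nodes:
        ang = np.radians(thetas[members])
        centroids.append(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0)
        node_times.append(times[members[0]])
    return nodes, np.array(centroids), np.array(node_times)


def classify(result: SimulationResult, window: int = 20, *,
             angle_tol: float = 5.0, sd_tol: float = 5.0,
             costoid_max_angle: float = 80.0, costoid_min_G: float = 0.3,
             drift_tol: float = 1.0, node_gap: float = 0.02) -> PatternSummary:
    """Classify a finished simulation into a phyllotaxis category.

    All statistics are computed over the last ``window`` intervals (the
    transient is dropped).  Decision order, mutually exclusive: no_formation
    (seed only) -> whorled (modal node size >= 2) -> irregular (unstable
    divergence) -> one_sided_distichous (sign-alternating, stable magnitude)
    -> constant-sign categories by mean absolute divergence: distichous
    (180 +- angle_tol), Fibonacci (137.5 +- angle_tol), Lucas (99.5 +-
    angle_tol), costoid (< costoid_max_angle with mean G > costoid_min_G),
    other_spiral -> irregular otherwise.
    """
    n = result.n_primordia
    if n <= 1:
        return PatternSummary("no_formation", np.nan, np.nan, np.nan, 0, "none",
                              n, result.termination)

    nodes, centroids, node_times = _group_nodes(result.thetas, result.emergence_times,
                                                node_gap)
    sizes = np.array([len(m) for m in nodes])
    per_node = int(np.bincount(sizes).argmax())
    whorled = per_node >= 2

    if whorled:
        pos, times = centroids, node_times
    else:
        pos, times = result.thetas, result.emergence_times

    dv = divergence_series(pos)
    G = np.diff(times)
    dv_w = dv[-window:]
    G_w = G[-window:]
    if dv_w.size == 0:
        return PatternSummary("no_formation", np.nan, np.nan, np.nan, per_node,
                              "none", n, result.termination)

    mean_abs = float(np.abs(dv_w).mean())
    sd_abs = float(np.abs(dv_w).std())
    mean_G = float(G_w.mean())
    signs = np.sign(dv_w)
    constant_sign = bool(np.all(signs == signs[0]))
    alternating = dv_w.size >= 2 and bool(np.all(signs[1:] * signs[:-1] < 0))
    if constant_sign and signs[0] > 0:
        chirality = "left"
    elif constant_sign:
        chirality = "right"
    else:
        chirality = "none"

    def summary(cat, chir=None):
        return PatternSummary(cat, mean_abs, sd_abs, mean_G, per_node,
                              chir if chir is not None else chirality,
                              n, result.termination)

    if whorled:
        return summary("whorled", "none")
    if sd_abs > sd_tol:
        return summary("irregular", "none")
    if alternating and abs(float(dv_w.mean())) < drift_tol:
        return summary("one_sided_distichous", "none")
    if constant_sign:
        if abs(mean_abs - 180.0) <= angle_tol:
            return summary("distichous", "none")
        if abs(mean_abs - 137.5) <= angle_tol:
            return summary("fibonacci_spiral")
        if abs(mean_abs - 99.5) <= angle_tol:
            return summary("lucas_spiral")
        if mean_abs < costoid_max_angle and mean_G > costoid_min_G:
            return summary("costoid")
        return summary("other_spiral")
    return summary("irregular", "none")
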