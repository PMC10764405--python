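"""Contour-map rendering of the field landscape over the apical disk.

Reproduces the four-region colouring of the dual-field model: at each point of
the apical region the inductive strength Y is either above or below its
threshold and the inhibitory strength S likewise, giving four combinations of
which exactly one (Y above, S below) permits primordium initiation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .simulator import NewModelParams, SimulationResult, gamma_schedule

__all__ = ["field_frame", "REGION_COLORS"]

# (Y > Y_th, S < S_th) -> RGB
REGION_COLORS = {
    (True, True): (0.95, 0.55, 0.55),    # initiation allowed
    (True, False): (0.95, 0.85, 0.55),   # induced but inhibited
    (False, True): (0.60, 0.75, 0.95),   # free of inhibition, not induced
    (False, False): (0.85, 0.85, 0.90),  # neither
}


def field_frame(result: SimulationResult, t_sim: Optional[float] = None,
                r_max: float = 4.0, n_r: int = 160, n_theta: int = 360,
                path: Optional[str] = None) -> np.ndarray:
    """RGB raster of the four-region field landscape at time ``t_sim``.

    The raster is a polar grid (radius up to ``r_max`` in units of R0)
    rendered to a square image; the SAM periphery is the unit circle.  Only
    primordia that have emerged by ``t_sim`` contribute.  Defined for the
    dual-field model.
    """
    p = result.params_used
    if not isinstance(p, NewModelParams):
        raise TypeError("field_frame is defined for the dual-field model")
    if t_sim is None:
        t_sim = result.t_final
    if result.schedule is not None:
        g_S, g_Y = gamma_schedule(t_sim, result.schedule)
    else:
        g_S, g_Y = p.gamma_S, p.gamma_Y
    d_Y2 = g_Y ** 2 * p.N
    d_S2 = g_S ** 2 * p.N

    active = result.emergence_times <= t_sim
    ages = t_sim - result.emergence_times[active]
    th_m = np.radians(result.thetas[active])
    r_m = np.exp(ages)

    rr = np.linspace(1e-3, r_max, n_r)
    tt = np.radians(np.linspace(0.0, 360.0, n_theta, endpoint=False))
    R, T = np.meshgrid(rr, tt, indexing="ij")
    Y = np.zeros_like(R)
    S = np.zeros_like(R)
    with np.errstate(divide="ignore"):
        for rm, thm, age in zip(r_m, th_m, ages):
            d2 = (R - rm) ** 2 / p.N + 2.0 * p.N * R * rm * (1.0 - np.cos(T - thm))
            F_Y = 1.0 / (1.0 + np.exp(-p.A_Y * (age - p.B_Y)))
            F_S = 1.0 / (1.0 + np.exp(-p.A_S * (age - p.B_S)))
            Y += F_Y * (d2 / d_Y2) ** (-0.5 * p.alpha_Y)
            S += F_S * (d2 / d_S2) ** (-0.5 * p.alpha_S)

    img = np.zeros((n_r, n_theta, 3))
    for (y_hi, s_lo), color in REGION_COLORS.items():
        mask = ((Y > p.Y_th) == y_hi) & ((S < p.S_th) == s_lo)
        img[mask] = color
    if path is not None:
        # polar-to-cartesian nearest-neighbour raster, SAM periphery = unit circle
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        side = 2 * n_r
        cart = np.ones((side, side, 3))
        xs = np.linspace(-r_max, r_max, side)
        X, Yc = np.meshgrid(xs, xs)
        Rc = np.hypot(X, Yc)
        Tc = np.arctan2(Yc, X) % (2 * np.pi)
        inside = Rc <= r_max
        ri = np.clip((Rc[inside] / r_max * (n_r - 1)).astype(int), 0, n_r - 1)
        ti = np.clip((Tc[inside] / (2 * np.pi) * n_theta).astype(int), 0, n_theta - 1)
        cart[inside] = img[ri, ti]
        plt.imsave(path, cart, origin="lower")
    return img
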