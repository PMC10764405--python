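"""Parameter-sweep driver and phase-map rendering.

Runs one simulation plus classification per grid cell over one or two swept
parameters, returning a tidy pandas DataFrame.  Cells are pure functions of
their parameters, so results are order-independent and cacheable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify
from .simulator import NewModelParams, SimulationConfig, run

__all__ = ["SweepSpec", "run_sweep", "render_phase_map", "CATEGORY_COLORS"]

_SWEEPABLE = {f.name for f in dataclasses.fields(NewModelParams)}


@dataclass(frozen=True)
class SweepSpec:
    """One or two swept parameter axes over a fixed base parameter set.

    axes maps parameter names (NewModelParams fields, e.g. "A_Y", "B_Y") to
    value sequences; config applies to every cell.
    """

    base: NewModelParams
    axes: dict[str, Sequence[float]]
    config: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 10

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("sweep needs 1 or 2 axes")
        for name, values in self.axes.items():
            if name not in _SWEEPABLE:
                raise ValueError(f"{name!r} is not a model parameter")
            if len(values) < 2:
                raise ValueError(f"axis {name!r} needs at least 2 values")


def run_sweep(spec: SweepSpec, cache: Optional[dict] = None) -> pd.DataFrame:
    """One simulation + classification per cell.

    Returns a DataFrame with the axis values, category, mean/sd divergence,
    mean G, primordium count and termination reason.  Per-cell failures are
    recorded in an ``error`` column and never abort the sweep.  An optional
    dict-valued cache (keyed on the full parameter+config tuple) makes reruns
    bit-identical and free.
    """
    names = list(spec.axes)
    grids = np.meshgrid(*[np.asarray(spec.axes[n], dtype=float) for n in names],
                        indexing="ij")
    rows = []
    for idx in np.ndindex(grids[0].shape):
        cell = {n: float(g[idx]) for n, g in zip(names, grids)}
        row = dict(cell)
        key = (dataclasses.astuple(spec.base), tuple(sorted(cell.items())),
               dataclasses.astuple(spec.config))
        if cache is not None and key in cache:
            rows.append(cache[key])
            continue
        try:
            params = spec.base.replace(**cell)
            result = run(params, spec.config)
            summary = classify(result, window=spec.window)
            row.update(
                category=summary.category,
                mean_divergence=summary.mean_divergence,
                sd_divergence=summary.sd_divergence,
                mean_G=summary.mean_G,
                primordia_per_node=summary.primordia_per_node,
                n_primordia=summary.n_primordia,
                termination=summary.termination,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - per-cell isolation is the contract
            row.update(category="error", mean_divergence=np.nan,
                       sd_divergence=np.nan, mean_G=np.nan, primordia_per_node=0,
                       n_primordia=0, termination="", error=str(exc))
        if cache is not None:
            cache[key] = row
        rows.append(row)
    return pd.DataFrame(rows)


CATEGORY_COLORS = {
    "no_formation": (1.00, 1.00, 1.00),
    "distichous": (0.20, 0.20, 0.20),
    "fibonacci_spiral": (0.85, 0.45, 0.10),
    "lucas_spiral": (0.95, 0.75, 0.20),
    "other_spiral": (0.60, 0.60, 0.90),
    "costoid": (0.80, 0.10, 0.10),
    "one_sided_distichous": (0.10, 0.45, 0.80),
    "whorled": (0.10, 0.65, 0.30),
    "irregular": (0.70, 0.70, 0.70),
    "error": (1.00, 0.00, 1.00),
}


def render_phase_map(df: pd.DataFrame, axes: Sequence[str],
                     path: Optional[str] = None) -> np.ndarray:
    """Category phase map as an RGB raster, one pixel per sweep cell.

    Spiral cells are shaded by their mean divergence angle (darker = steeper).
    With a 1-axis sweep the raster is a single pixel row.  If ``path`` is
    given the raster is also written as a PNG.
    """
    names = list(axes)
    if len(names) == 1:
        xs = np.sort(df[names[0]].unique())
        shape = (1, len(xs))
        index = {(x,): (0, j) for j, x in enumerate(xs)}
        keys = df[names].itertuples(index=False, name=None)
    else:
        ys = np.sort(df[names[0]].unique())
        xs = np.sort(df[names[1]].unique())
        shape = (len(ys), len(xs))
        index = {(y, x): (i, j) for i, y in enumerate(ys) for j, x in enumerate(xs)}
        keys = df[names].itertuples(index=False, name=None)
    img = np.ones(shape + (3,))
    for key, row in zip(keys, df.itertuples()):
        i, j = index[key]
        color = np.array(CATEGORY_COLORS.get(row.category, (0.0, 0.0, 0.0)))
        if row.category in ("fibonacci_spiral", "lucas_spiral", "other_spiral",
                            "costoid") and np.isfinite(row.mean_divergence):
            # steeper spirals darker
            color = color * (0.4 + 0.6 * min(row.mean_divergence, 180.0) / 180.0)
        img[i, j] = color
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        plt.imsave(path, img, origin="lower")
    return img
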