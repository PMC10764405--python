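"""Writers for primordium tables, run metadata and pattern summaries."""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from typing import Union

import numpy as np
import pandas as pd

from .classify import PatternSummary, divergence_series
from .simulator import SimulationResult

__all__ = ["primordium_table", "write_primordium_table", "run_metadata",
           "write_run_metadata", "write_summary"]


def _pkg_version() -> str:
    try:
        return version("phyllofield")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def primordium_table(result: SimulationResult) -> pd.DataFrame:
    """Emergence-ordered table: index, angle, emergence time, divergence, G."""
    dv = divergence_series(result.thetas)
    G = np.diff(result.emergence_times)
    n = result.n_primordia
    return pd.DataFrame({
        "index": np.arange(1, n + 1),
        "theta_deg": result.thetas,
        "t_emergence": result.emergence_times,
        "divergence_deg": np.concatenate([[np.nan], dv]) if n > 1 else [np.nan] * n,
        "G": np.concatenate([[np.nan], G]) if n > 1 else [np.nan] * n,
    })


def write_primordium_table(result: SimulationResult, path) -> None:
    primordium_table(result).to_csv(path, index=False)


def run_metadata(result: SimulationResult) -> dict:
    meta = {
        "model": type(result.params_used).__name__,
        "params": dataclasses.asdict(result.params_used),
        "config": dataclasses.asdict(result.config),
        "schedule": dataclasses.asdict(result.schedule) if result.schedule else None,
        "termination": result.termination,
        "n_primordia": result.n_primordia,
        "t_final": result.t_final,
        "deterministic": True,
        "version": _pkg_version(),
    }
    return meta


def write_run_metadata(result: SimulationResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(run_metadata(result), fh, indent=2)


def write_summary(summary: PatternSummary, path) -> None:
    d = dataclasses.asdict(summary)
    with open(path, "w") as fh:
        json.dump({k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                   for k, v in d.items()}, fh, indent=2)
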