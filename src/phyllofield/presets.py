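"""Registry of the published parameter sets.

Every preset carries its figure provenance so acceptance-style reruns are one
call; values are copied verbatim from the cited captions.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass
from typing import Optional, Union

from .simulator import EDC2Params, EnlargementSchedule, NewModelParams

__all__ = ["Preset", "get_preset", "list_presets", "preset_to_dict", "preset_from_dict"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: Union[NewModelParams, EDC2Params]
    provenance: str
    schedule: Optional[EnlargementSchedule] = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be nonempty")


_REGISTRY: dict[str, Preset] = {}


def _register(preset: Preset) -> None:
    _REGISTRY[preset.name] = preset


_register(Preset(
    name="fig2c_fibonacci",
    params=NewModelParams(N=1 / 3, gamma_S=1.9, alpha_S=3.0, A_S=10.0, B_S=0.0,
                          gamma_Y=3.5, alpha_Y=3.0, A_Y=20.0, B_Y=0.0),
    provenance="Fig. 2c upper right (Fibonacci spiral)",
))

_register(Preset(
    name="fig2c_costoid",
    params=NewModelParams(N=1 / 3, gamma_S=3.0, alpha_S=2.0, A_S=10.0, B_S=0.0,
                          gamma_Y=3.5, alpha_Y=4.0, A_Y=20.0, B_Y=0.64),
    provenance="Fig. 2c lower left (costoid phyllotaxis)",
))

_register(Preset(
    name="fig2c_one_sided_distichous",
    params=NewModelParams(N=1 / 3, gamma_S=3.0, alpha_S=3.0, A_S=10.0, B_S=0.0,
                          gamma_Y=3.5, alpha_Y=3.0, A_Y=20.0, B_Y=0.52),
    provenance="Fig. 2c lower right (one-sided distichous pattern)",
))

_register(Preset(
    name="fig4f_enlargement",
    params=NewModelParams(N=1 / 3, gamma_S=3.2, alpha_S=3.0, A_S=10.0, B_S=0.0,
                          gamma_Y=1.79 * 3.2 / 1.71, alpha_Y=4.0, A_Y=20.0, B_Y=0.3),
    provenance="Fig. 4f (early transition under SAM enlargement)",
    schedule=EnlargementSchedule(gamma_S_i=3.2, gamma_S_f=1.71, t_i=0.82, tau=1.0,
                                 gamma_Y_f=1.79),
))

_register(Preset(
    name="fig2a_fixed_alphaY3",
    params=NewModelParams(N=1 / 3, gamma_S=3.0, alpha_S=3.0, A_S=10.0, B_S=0.0,
                          gamma_Y=3.5, alpha_Y=3.0, A_Y=20.0, B_Y=0.0),
    provenance="Fig. 2a fixed set, alpha_Y = 3 panel (A_Y, B_Y swept)",
))

_register(Preset(
    name="fig2a_fixed_alphaY4",
    params=NewModelParams(N=1 / 3, gamma_S=3.0, alpha_S=3.0, A_S=10.0, B_S=0.0,
                          gamma_Y=3.5, alpha_Y=4.0, A_Y=20.0, B_Y=0.0),
    provenance="Fig. 2a fixed set, alpha_Y = 4 panel (A_Y, B_Y swept)",
))


def list_presets() -> list[str]:
    return sorted(_REGISTRY)


def get_preset(name: str) -> Preset:
    """Look up a preset by name; returns an independent copy."""
    try:
        preset = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
    return copy.deepcopy(preset)


def preset_to_dict(preset: Preset) -> dict:
    """Plain-dict form of a preset (YAML/JSON serializable)."""
    d: dict = {
        "name": preset.name,
        "provenance": preset.provenance,
        "model": "edc2" if isinstance(preset.params, EDC2Params) else "dual_field",
        "params": dataclasses.asdict(preset.params),
    }
    if preset.schedule is not None:
        d["schedule"] = dataclasses.asdict(preset.schedule)
    return d


def preset_from_dict(d: dict) -> Preset:
    cls = EDC2Params if d.get("model") == "edc2" else NewModelParams
    schedule = None
    if "schedule" in d and d["schedule"] is not None:
        schedule = EnlargementSchedule(**d["schedule"])
    return Preset(name=d["name"], params=cls(**d["params"]),
                  provenance=d["provenance"], schedule=schedule)
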