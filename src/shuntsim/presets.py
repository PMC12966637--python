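"""Shipped scenario presets: isolated VSD, isolated ASD, combined
ASD+VSD. Each preset file stores one parameter column verbatim (timings
as fractions of the heartbeat period)."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .params import ChamberParams, ModelParams, ShuntParams, ValveParams, WindkesselParams

PRESET_NAMES = ("vsd", "asd", "asd_vsd")


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    params: ModelParams


def params_from_dict(doc: dict) -> ModelParams:
    """Build a validated :class:`ModelParams` from a preset-style mapping."""
    thb = float(doc["thb"])
    chambers = {}
    for name, ch in doc["chambers"].items():
        tc = float(ch["tc_frac"]) * thb
        dc = float(ch["dc_frac"]) * thb
        chambers[name] = ChamberParams(
            ea=ch["ea"],
            eb=ch["eb"],
            v0=ch.get("v0", 0.0),
            t_contract=tc,
            d_contract=dc,
            t_relax=(tc + dc) % thb,
            d_relax=float(ch["dr_frac"]) * thb,
        )
    valve = ValveParams(**doc["valves"])
    comps = {k: WindkesselParams(**v) for k, v in doc["compartments"].items()}
    return ModelParams(
        thb=thb,
        **chambers,
        mv=valve,
        av=valve,
        tv=valve,
        pv=valve,
        **comps,
        shunts=ShuntParams(**doc.get("shunts", {})),
    )


def load_preset(name_or_path: Union[str, Path]) -> ScenarioPreset:
    """Load a shipped preset by name (``vsd``/``asd``/``asd_vsd``) or any
    preset-format YAML file by path."""
    name = str(name_or_path).replace("-", "_")
    if name in PRESET_NAMES:
        text = (resources.files(__package__) / "presets" / f"{name}.yaml").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown preset {name_or_path!r}; shipped presets are {PRESET_NAMES}"
            )
        text = path.read_text()
    doc = yaml.safe_load(text)
    return ScenarioPreset(name=doc.get("name", name), params=params_from_dict(doc))


def preset_raw(name: str) -> dict:
    """Raw YAML mapping of a shipped preset (values exactly as stored)."""
    name = name.replace("-", "_")
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}")
    text = (resources.files(__package__) / "presets" / f"{name}.yaml").read_text()
    return yaml.safe_load(text)
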