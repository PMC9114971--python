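"""Structured-text (YAML) configuration for the pipelines.

Each section maps onto one of the package's parameter dataclasses; unknown
keys raise, missing keys take the dataclass defaults, so a config
round-trips unchanged.  Angles are radians, lengths micrometres, stresses
kPa, times seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import fields

import yaml

from .growth import GrowthParams
from .poro import LoadProgram, PoroMaterial
from .study import StudyDesign
from .synthetic import BumpSpec, LimbSpec


def _build(cls, data: dict, converters: dict | None = None):
    if data is None:
        return cls()
    converters = converters or {}
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        kwargs[k] = converters[k](v) if k in converters else v
    return cls(**kwargs)


def _bump(data) -> BumpSpec:
    return _build(BumpSpec, data)


def limb_spec_from_dict(data: dict | None) -> LimbSpec:
    return _build(
        LimbSpec,
        data,
        converters={
            "dorsal_condyle": _bump,
            "ventral_condyle": _bump,
            "concavities": lambda lst: tuple(_bump(b) for b in lst),
        },
    )


def load_config(path) -> dict:
    """Parse a run config into the package's parameter objects."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    out = {
        "limb": limb_spec_from_dict(raw.get("limb")),
        "material": _build(PoroMaterial, raw.get("material")),
        "program": _build(LoadProgram, raw.get("program")),
        "growth": _build(GrowthParams, raw.get("growth")),
        "design": _build(
            StudyDesign,
            raw.get("design"),
            converters={
                "base_spec": limb_spec_from_dict,
                "nuclei_stack_shape": tuple,
                "nuclei_spacing": tuple,
            },
        ),
        "seed": int(raw.get("seed", 0)),
    }
    # the study rides on the same limb spec unless overridden explicitly
    if raw.get("design") is None or "base_spec" not in (raw.get("design") or {}):
        out["design"] = dataclasses.replace(out["design"], base_spec=out["limb"])
    return out


def dump_default_config(path) -> None:
    """Write a fully explicit config with all defaults."""
    cfg = {
        "seed": 0,
        "limb": dataclasses.asdict(LimbSpec()),
        "material": dataclasses.asdict(PoroMaterial()),
        "program": dataclasses.asdict(LoadProgram()),
        "growth": dataclasses.asdict(GrowthParams()),
        "design": {
            k: v
            for k, v in dataclasses.asdict(StudyDesign()).items()
            if k != "base_spec"
        },
    }
    cfg["limb"]["concavities"] = [dict(b) if isinstance(b, dict) else b for b in cfg["limb"]["concavities"]]
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
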