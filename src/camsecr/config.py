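"""Run configuration: YAML schema, defaults and validation.

Validation collects every problem (unknown keys — with a close-match
suggestion — and type/domain errors) and reports them together.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .occupancy import OccupancyModelSpec
from .simulate import SimConfig
from .types import ModelSpec

DEFAULT_MODELS = [
    {"name": "Md7", "density": ["d2boundary"], "p0": ["d2river"],
     "sigma": ["array"]},
]

_TOP_KEYS = {"seed", "out_dir", "data_dir", "ci_level", "verbosity",
             "sim", "secr_models", "occupancy", "optimizer"}
_OCC_KEYS = {"boundary_effect", "chains", "iterations", "burn_in", "thin",
             "seed"}
_MODEL_KEYS = {"name", "density", "p0", "sigma"}
_SIM_KEYS = {f.name for f in dc_fields(SimConfig)}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "camsecr-out"
    data_dir: Optional[str] = None
    ci_level: float = 0.85
    verbosity: str = "info"
    sim: SimConfig = field(default_factory=SimConfig)
    secr_models: list[ModelSpec] = field(default_factory=list)
    occupancy: OccupancyModelSpec = field(default_factory=OccupancyModelSpec)
    optimizer: dict = field(default_factory=dict)


def _suggest(key: str, allowed: set[str]) -> str:
    close = difflib.get_close_matches(key, sorted(allowed), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _check_keys(block: dict, allowed: set[str], where: str,
                errors: list[str]) -> None:
    for key in block:
        if key not in allowed:
            errors.append(f"unknown key {key!r} in {where}"
                          f"{_suggest(key, allowed)}")


def validate_config(path_or_dict) -> RunConfig:
    """Load, default-fill and validate a run configuration.

    Accepts a YAML file path or an already-parsed mapping; an empty
    config is valid and yields all defaults (6 km buffer, 500 m pixels,
    85% CI level).
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    errors: list[str] = []
    _check_keys(raw, _TOP_KEYS, "config", errors)

    sim_block = raw.get("sim", {}) or {}
    if not isinstance(sim_block, dict):
        errors.append("'sim' must be a mapping")
        sim_block = {}
    _check_keys(sim_block, _SIM_KEYS, "sim", errors)

    occ_block = raw.get("occupancy", {}) or {}
    if not isinstance(occ_block, dict):
        errors.append("'occupancy' must be a mapping")
        occ_block = {}
    _check_keys(occ_block, _OCC_KEYS, "occupancy", errors)

    models_block = raw.get("secr_models", DEFAULT_MODELS)
    if not isinstance(models_block, list):
        errors.append("'secr_models' must be a list")
        models_block = []
    for i, m in enumerate(models_block):
        if not isinstance(m, dict):
            errors.append(f"secr_models[{i}] must be a mapping")
            continue
        _check_keys(m, _MODEL_KEYS, f"secr_models[{i}]", errors)

    def num(block: dict, key: str, lo=None, where: str = "config"
            ) -> None:
        if key in block:
            v = block[key]
            if not isinstance(v, (int, float)) or isinstance(v, bool) \
                    or not math.isfinite(float(v)):
                errors.append(f"{where}.{key} must be a finite number")
            elif lo is not None and v < lo:
                errors.append(f"{where}.{key} must be >= {lo}")

    num(sim_block, "buffer", 0.0, "sim")
    num(sim_block, "pixel_size", 1e-9, "sim")
    num(sim_block, "trap_spacing", 1e-9, "sim")
    num(raw, "ci_level", 1e-9)
    if "ci_level" in raw and isinstance(raw["ci_level"], (int, float)) \
            and not 0 < raw["ci_level"] < 1:
        errors.append("ci_level must be in (0, 1)")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")

    if errors:
        raise ValueError("invalid configuration:\n  - "
                         + "\n  - ".join(errors))

    # tuples in SimConfig arrive as YAML lists
    sim_kwargs: dict[str, Any] = {}
    for key, val in sim_block.items():
        if isinstance(val, list):
            val = tuple(val)
        sim_kwargs[key] = val
    if "seed" in raw and "rng_seed" not in sim_kwargs:
        sim_kwargs["rng_seed"] = raw["seed"]
    occ_kwargs = dict(occ_block)
    if "seed" in raw and "seed" not in occ_kwargs:
        occ_kwargs["seed"] = raw["seed"]

    specs = [ModelSpec(density=tuple(m.get("density", ())),
                       p0=tuple(m.get("p0", ())),
                       sigma=tuple(m.get("sigma", ())),
                       name=m.get("name", f"m{i + 1}"))
             for i, m in enumerate(models_block)]

    return RunConfig(
        seed=raw.get("seed", 0),
        out_dir=raw.get("out_dir", "camsecr-out"),
        data_dir=raw.get("data_dir"),
        ci_level=raw.get("ci_level", 0.85),
        verbosity=raw.get("verbosity", "info"),
        sim=SimConfig(**sim_kwargs),
        secr_models=specs,
        occupancy=OccupancyModelSpec(**occ_kwargs),
        optimizer=raw.get("optimizer", {}) or {},
    )
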