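"""YAML scenario configuration: loading, validation, round-tripping.

A scenario file fully determines a run: the simulation parameters, the
tumor sites, the injection region, and where the tissue image comes
from (a volume file or a phantom recipe).  Lengths are internally in
pixels; a top-level ``units: um`` block declares that centres, radii
and half-decay distances in the file are micrometres, to be divided by
``pixel_size_um`` on load.  Tumor arrival extents are always
micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _dc_field
from pathlib import Path

import numpy as np
import yaml

from .chemo import ChemoField, TumorSite
from .engine import SimulationConfig

__all__ = ["ConfigError", "ScenarioConfig", "load_config", "dump_config"]

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass
class ScenarioConfig:
    """Resolved contents of a scenario file."""

    config: SimulationConfig
    chemo: ChemoField
    image: str | None = None
    phantom: dict | None = None
    pixel_size_um: float | None = None
    raw: dict = _dc_field(default_factory=dict, repr=False)


def _as_length(value, scale: float, key: str):
    try:
        arr = np.asarray(value, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: not numeric ({value!r})") from exc
    return arr / scale


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario YAML file.

    Unset simulation keys fall back to the package defaults (range
    midpoints, anisotropy threshold 0.4); out-of-range values raise a
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    units = raw.get("units", "pixels")
    if units not in ("pixels", "um"):
        raise ConfigError(f"units: must be 'pixels' or 'um' (got {units!r})")
    pixel_size = raw.get("pixel_size_um")
    if units == "um":
        if pixel_size is None:
            raise ConfigError("pixel_size_um: required when units is 'um'")
        if pixel_size <= 0:
            raise ConfigError(f"pixel_size_um: must be > 0 (got {pixel_size!r})")
    scale = float(pixel_size) if units == "um" else 1.0

    sim_raw = dict(raw.get("simulation", {}))
    unknown = set(sim_raw) - _SIM_KEYS
    if unknown:
        raise ConfigError(
            "simulation: unknown key(s) " + ", ".join(sorted(unknown)))
    if "injection_center" in sim_raw and sim_raw["injection_center"] is not None:
        sim_raw["injection_center"] = tuple(
            _as_length(sim_raw["injection_center"], scale,
                       "simulation.injection_center").tolist())
    if "injection_radius" in sim_raw:
        sim_raw["injection_radius"] = float(
            _as_length(sim_raw["injection_radius"], scale,
                       "simulation.injection_radius"))
    config = SimulationConfig(**sim_raw)
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(f"simulation.{exc}") from exc

    chemo_raw = raw.get("chemo", {})
    sites = []
    for i, t in enumerate(raw.get("tumors", []) or []):
        key = f"tumors[{i}]"
        if "center" not in t:
            raise ConfigError(f"{key}.center: required")
        kwargs = {
            "center": _as_length(t["center"], scale, f"{key}.center"),
            "decay_power": float(t.get("decay_power", 1.0)),
        }
        if "half_decay" in t:
            kwargs["half_decay"] = _as_length(
                t["half_decay"], scale, f"{key}.half_decay")
        elif pixel_size:
            # sigma default = twice the arrival extent, converted to pixels
            d = len(kwargs["center"])
            from .chemo import DEFAULT_EXTENT_UM
            ext = np.asarray(t.get("extent_um", DEFAULT_EXTENT_UM[:d]),
                             dtype=float)[:d]
            kwargs["half_decay"] = 2.0 * ext / float(pixel_size)
        if "extent_um" in t:
            kwargs["extent_um"] = np.asarray(t["extent_um"], dtype=float)
        if "arrival_radius_um" in t:
            kwargs["arrival_radius_um"] = float(t["arrival_radius_um"])
        try:
            sites.append(TumorSite(**kwargs))
        except ValueError as exc:
            raise ConfigError(f"{key}: {exc}") from exc
    try:
        chemo = ChemoField(sites=sites,
                           epsilon_c=float(chemo_raw.get("epsilon_c",
                                                         config.epsilon_c)),
                           combine=chemo_raw.get("combine", "sum"))
    except ValueError as exc:
        raise ConfigError(f"chemo: {exc}") from exc

    return ScenarioConfig(
        config=config, chemo=chemo,
        image=raw.get("image"), phantom=raw.get("phantom"),
        pixel_size_um=float(pixel_size) if pixel_size else None,
        raw=raw)


def dump_config(sc: ScenarioConfig, path) -> None:
    """Write a fully resolved scenario back to YAML (pixels units).

    A dump -> load round trip reproduces the resolved configuration
    exactly.
    """
    doc: dict = {"units": "pixels"}
    if sc.pixel_size_um:
        doc["pixel_size_um"] = sc.pixel_size_um
    if sc.image:
        doc["image"] = sc.image
    if sc.phantom:
        doc["phantom"] = sc.phantom
    doc["simulation"] = sc.config.to_dict()
    doc["chemo"] = {"epsilon_c": sc.chemo.epsilon_c,
                    "combine": sc.chemo.combine}
    doc["tumors"] = [
        {
            "center": [float(v) for v in s.center],
            "half_decay": [float(v) for v in s.half_decay],
            "decay_power": float(s.decay_power),
            "extent_um": [float(v) for v in s.extent_um],
            **({"arrival_radius_um": float(s.arrival_radius_um)}
               if s.arrival_radius_um is not None else {}),
        }
        for s in sc.chemo.sites
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
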