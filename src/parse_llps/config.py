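"""Flat key-value configuration mirroring :class:`ModelConstants`.

A config file is a YAML mapping whose keys are ModelConstants field names
(plus optional ``sector_centroids`` / ``sector_sigmas`` overrides for the
boundary geometry).  CLI flags override config values, which override the
built-in defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .scales import DEFAULT_CONSTANTS, ModelConstants

__all__ = ["load_config", "constants_from_mapping"]

_SCALAR_KEYS = {
    "R0": float,
    "window_size": int,
    "expansion_multiplier": int,
    "min_region_length": int,
    "purity_threshold": float,
}


def constants_from_mapping(
    mapping: dict, base: ModelConstants = DEFAULT_CONSTANTS
) -> ModelConstants:
    """Build constants from a flat mapping, starting from ``base``."""
    unknown = set(mapping) - set(_SCALAR_KEYS) - {
        "rh_coeffs", "vint_coeffs", "sector_centroids", "sector_sigmas",
    }
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, cast in _SCALAR_KEYS.items():
        if key in mapping:
            kwargs[key] = cast(mapping[key])
    for key in ("rh_coeffs", "vint_coeffs", "sector_sigmas"):
        if key in mapping:
            kwargs[key] = tuple(float(x) for x in mapping[key])
    if "sector_centroids" in mapping:
        kwargs["sector_centroids"] = {
            sector: (float(v), float(t))
            for sector, (v, t) in mapping["sector_centroids"].items()
        }
    return base.replace(**kwargs) if kwargs else base


def load_config(path: str | Path) -> ModelConstants:
    """Read a YAML config file into :class:`ModelConstants`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return constants_from_mapping(data)
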