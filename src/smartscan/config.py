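"""Config-file parsing and validation for the CLI.

A config is a flat JSON or YAML mapping.  Workflow parameters use the nine
canonical keys (matching :class:`~smartscan.runtime_model.AcquisitionParams`
field names); alternatively the three per-tile times may be derived from
tile pixel geometry plus dwell times.  Two optional keys select the quality
source.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ValidationError
from .quality import (
    QualityCurve,
    fit_monotone_curve,
    logistic_curve,
    read_quality_samples,
)
from .runtime_model import AcquisitionParams, params_from_tile_geometry

CANONICAL_KEYS = (
    "quality_standard",
    "n_tiles",
    "n_sections",
    "t_trad_s",
    "t_fast_s",
    "t_slow_s",
    "t_compute_s",
    "t_tile_s",
    "t_section_s",
)

GEOMETRY_KEYS = (
    "tile_width_px",
    "tile_height_px",
    "fast_dwell_ns",
    "slow_dwell_ns",
    "trad_dwell_ns",
)

#: Keys that pick the quality source (at most one of the two).
QUALITY_KEYS = ("logistic_k", "quality_samples_csv")

_TIME_FROM_GEOMETRY = ("t_trad_s", "t_fast_s", "t_slow_s")
_INT_KEYS = ("n_tiles", "n_sections", "tile_width_px", "tile_height_px")


def load_config(path) -> dict:
    """Load a JSON (``.json``) or YAML (``.yaml``/``.yml``) config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError:
            cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def _coerce(key: str, value):
    if key in _INT_KEYS:
        if isinstance(value, float) and value.is_integer():
            return int(value)
        if not isinstance(value, int):
            raise ValidationError(f"config key {key!r} must be an integer, got {value!r}")
        return value
    return value


def validate_keys(cfg: dict) -> None:
    """Reject unknown keys and inconsistent geometry/time combinations."""
    known = set(CANONICAL_KEYS) | set(GEOMETRY_KEYS) | set(QUALITY_KEYS)
    for key in cfg:
        if key not in known:
            raise ValidationError(f"unknown config key {key!r}")
    present_geo = [k for k in GEOMETRY_KEYS if k in cfg]
    if present_geo:
        missing = [k for k in GEOMETRY_KEYS if k not in cfg]
        if missing:
            raise ValidationError(
                f"geometry-based config requires all of {GEOMETRY_KEYS}; "
                f"missing {missing}"
            )
        clash = [k for k in _TIME_FROM_GEOMETRY if k in cfg]
        if clash:
            raise ValidationError(
                f"config keys {clash} conflict with tile-geometry keys; "
                "supply per-tile times either directly or via geometry, not both"
            )
    if "logistic_k" in cfg and "quality_samples_csv" in cfg:
        raise ValidationError(
            "config keys 'logistic_k' and 'quality_samples_csv' are mutually "
            "exclusive: exactly one quality source is allowed"
        )


def params_from_config(cfg: dict) -> AcquisitionParams:
    """Build validated :class:`AcquisitionParams` from a config mapping.

    Missing workflow keys fall back to the reference defaults.
    """
    validate_keys(cfg)
    fields = {
        k: _coerce(k, cfg[k]) for k in CANONICAL_KEYS if k in cfg
    }
    if any(k in cfg for k in GEOMETRY_KEYS):
        geo = {k: _coerce(k, cfg[k]) for k in GEOMETRY_KEYS}
        return params_from_tile_geometry(**geo, **fields)
    return AcquisitionParams(**fields)


def curve_from_config(cfg: dict) -> QualityCurve:
    """Build the quality curve selected by the config (logistic by default)."""
    if "logistic_k" in cfg and "quality_samples_csv" in cfg:
        raise ValidationError(
            "config keys 'logistic_k' and 'quality_samples_csv' are mutually "
            "exclusive: exactly one quality source is allowed"
        )
    if "quality_samples_csv" in cfg:
        samples = read_quality_samples(cfg["quality_samples_csv"])
        return fit_monotone_curve(samples)
    k = cfg.get("logistic_k", 4.0)
    if not (isinstance(k, (int, float)) and k > 0):
        raise ValidationError(f"config key 'logistic_k' must be positive, got {k!r}")
    return logistic_curve(float(k))
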