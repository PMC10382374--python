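"""Configuration loading and merging.

A single YAML document holds every model constant (skin, transport,
PK reference tables, PD, variability, therapy policy, numerics,
thresholds).  ``load_config`` returns the packaged defaults, optionally
deep-merged with a user override file, so any constant can be changed
without touching code.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

_REQUIRED_SECTIONS = (
    "skin",
    "patch",
    "transport",
    "pk_reference",
    "pd",
    "variability",
    "policy",
    "numerics",
    "thresholds",
)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """Return the packaged default configuration as a plain dict."""
    text = resources.files("patchtwin.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load defaults, deep-merged with an optional YAML override file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, override)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    """Check that every required section is present; raise naming the gap."""
    for section in _REQUIRED_SECTIONS:
        if section not in cfg:
            raise KeyError(f"configuration is missing required section {section!r}")
    for gender in ("male", "female"):
        if gender not in cfg["pk_reference"]:
            raise KeyError(f"pk_reference configuration is missing the {gender!r} table")


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration, for run manifests."""
    payload = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
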