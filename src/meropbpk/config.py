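"""Packaged-configuration access and YAML helpers."""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """A parameter file is missing keys or cannot be interpreted."""


def packaged_config(name: str) -> Path:
    """Return the path of a YAML file shipped under ``meropbpk/data``."""
    ref = importlib.resources.files("meropbpk").joinpath("data", name)
    path = Path(str(ref))
    if not path.exists():
        raise ConfigurationError(f"no packaged config named {name!r}")
    return path


def load_yaml(source) -> dict:
    """Load a YAML mapping from a path or an already-parsed dict."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} does not contain a mapping")
    return data
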