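"""Default configuration loading.

The packaged ``data/default_config.yaml`` holds the protocol timings,
simulator baselines, drought-severity preset table, segmentation and
classification defaults. User configs are YAML files with the same shape;
missing keys fall back to the defaults.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

__all__ = ["default_config", "load_config"]

_cache: dict | None = None


def default_config() -> dict:
    """Deep copy of the packaged default configuration."""
    global _cache
    if _cache is None:
        text = resources.files("fluorpheno.data").joinpath("default_config.yaml").read_text()
        _cache = yaml.safe_load(text)
    return copy.deepcopy(_cache)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the packaged defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg
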