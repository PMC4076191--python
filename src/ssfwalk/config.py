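"""Run configuration: defaults, YAML overrides, and seed substreams.

All model constants live in a nested dict loaded from ``data/defaults.yaml``.
A user YAML file (or dict) is deep-merged on top.  Every stage of the pipeline
draws its randomness from a named child of the single run seed so that stages
are individually reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Any, Mapping

import numpy as np
import yaml

_STREAMS = ("landscape", "tracks", "replay", "fit-cv", "simulate", "validate")


def load_defaults() -> dict:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("ssfwalk.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path_or_dict: Any = None) -> dict:
    """Defaults merged with a YAML file path or a mapping of overrides."""
    cfg = load_defaults()
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, Mapping):
        return _deep_merge(cfg, path_or_dict)
    with open(path_or_dict) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_merge(cfg, user)


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration for artifact stamping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the run seed.

    Uses SeedSequence spawning keyed on the stream name so that adding a new
    stage never perturbs the draws of existing ones.
    """
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def stream_names() -> tuple[str, ...]:
    return _STREAMS
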