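"""YAML run-configuration loading.

A run config is a plain mapping with optional sections ``acquisition``,
``scene``, ``noise``, ``fit`` plus scalar keys ``te``, ``seed``,
``target_snr`` and ``metabolites``; every section maps onto the keyword
arguments of the corresponding dataclass.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "te": 120.0,
    "seed": 0,
    "target_snr": 27.0,
    "acquisition": {},
    "scene": {},
    "noise": {},
    "fit": {},
    "metabolites": None,
}


def load_config(source: Mapping | str | Path | None) -> dict:
    """Merge a YAML file or mapping over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        loaded = yaml.safe_load(Path(source).read_text()) or {}
    else:
        loaded = dict(source)
    for k, v in loaded.items():
        if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg
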