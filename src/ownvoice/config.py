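"""YAML run-configuration for the simulation and fitting commands.

A config file collects the knobs of a run in one place, e.g.::

    seed: 1            # required
    talkers: 33
    pairs: 13
    reps: 4
    jitter: 0.04
    chains: 4
    iterations: 4000
    warmup: 1000
    target_rms_db: 65
    snr_db: 5
"""

from __future__ import annotations

from pathlib import Path

import yaml

_DEFAULTS = {
    "talkers": 33,
    "pairs": 13,
    "reps": 4,
    "jitter": 0.04,
    "chains": 4,
    "iterations": 4000,
    "warmup": 1000,
    "target_rms_db": 65.0,
    "snr_db": 5.0,
}


def load_config(path) -> dict:
    """Load a YAML run config; ``seed`` is required, other keys default."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    unknown = set(raw) - set(_DEFAULTS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    cfg["seed"] = int(cfg["seed"])
    return cfg
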