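"""Flat YAML configuration mirroring the neuron, phase and optimizer settings.

The file is a single flat mapping; keys are grouped by prefix (``neuron.``,
``phase.``) when converting to :class:`~spikedream.phases.ExperimentConfig`.
``default_config()`` carries the published defaults: N = 500 neurons,
τ_m = 20 ms, τ_s = 2 ms, τ_* = 10 ms, input scale σ = 5, reset amplitude 20,
γ = 0.99, c_ξ = 1.0, c_r = 0.1, Adam learning rate 0.001, horizons 100
(awake) and 50 (dream).
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .lif import NeuronParams
from .phases import ExperimentConfig, PhaseConfig

__all__ = ["default_config", "config_to_dict", "config_from_dict", "load_config", "save_config"]


def default_config() -> ExperimentConfig:
    return ExperimentConfig()


def config_to_dict(config: ExperimentConfig) -> dict:
    """Flatten an experiment configuration into one key-value mapping."""
    flat: dict = {}
    for k, v in asdict(config.neuron).items():
        flat[f"neuron.{k}"] = v
    for k, v in asdict(config.phase).items():
        flat[f"phase.{k}"] = v
    for f in fields(config):
        if f.name in ("neuron", "phase"):
            continue
        flat[f.name] = getattr(config, f.name)
    return flat


def config_from_dict(flat: dict) -> ExperimentConfig:
    neuron_kwargs = {
        k[len("neuron."):]: v for k, v in flat.items() if k.startswith("neuron.")
    }
    phase_kwargs = {
        k[len("phase."):]: v for k, v in flat.items() if k.startswith("phase.")
    }
    top = {
        k: v
        for k, v in flat.items()
        if not (k.startswith("neuron.") or k.startswith("phase."))
    }
    known = {f.name for f in fields(ExperimentConfig)} - {"neuron", "phase"}
    unknown = set(top) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return ExperimentConfig(
        neuron=NeuronParams(**neuron_kwargs),
        phase=PhaseConfig(**phase_kwargs),
        **top,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    return config_from_dict(flat)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
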