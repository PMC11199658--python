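"""Self-describing checkpoint container for module state and weights.

Checkpoints are NumPy ``.npz`` archives: each entry carries its own name,
shape and dtype, and round-trips bit-exactly.  Scalars (step counters,
learning rates, hyper-parameters) are stored as 0-d arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .lif import ModuleState
from .policy import Agent
from .worldmodel import WorldModel

__all__ = [
    "save_arrays",
    "load_arrays",
    "save_module_state",
    "load_module_state",
    "save_agent_model",
    "load_into_agent_model",
]


def save_arrays(path: str | Path, arrays: dict[str, np.ndarray]) -> None:
    """Write a flat name → array mapping as an ``.npz`` archive."""
    np.savez(path, **arrays)


def load_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {name: data[name] for name in data.files}


def save_module_state(path: str | Path, state: ModuleState) -> None:
    save_arrays(
        path,
        {
            "v": state.v,
            "s": state.s,
            "s_hat": state.s_hat,
            "s_bar": state.s_bar,
            "e": state.e,
            "t": np.asarray(state.t),
        },
    )


def load_module_state(path: str | Path) -> ModuleState:
    d = load_arrays(path)
    return ModuleState(
        v=d["v"], s=d["s"], s_hat=d["s_hat"], s_bar=d["s_bar"], e=d["e"], t=int(d["t"])
    )


def _flatten(prefix: str, arrays: dict) -> dict[str, np.ndarray]:
    return {f"{prefix}.{k}": np.asarray(v) for k, v in arrays.items()}


def save_agent_model(path: str | Path, agent: Agent, model: WorldModel | None) -> None:
    """Checkpoint trainable parameters and optimizer state of both modules."""
    arrays: dict[str, np.ndarray] = {}
    arrays.update(_flatten("agent", agent.parameters()))
    arrays.update(_flatten("agent.opt", agent.opt.state_dict()))
    arrays["agent.w_in_state"] = agent.net.weights.w_in_state
    if model is not None:
        arrays.update(_flatten("model", model.parameters()))
        arrays.update(_flatten("model.opt", model.opt.state_dict()))
        arrays["model.w_in_state"] = model.net.weights.w_in_state
        if model.net.weights.w_in_action is not None:
            arrays["model.w_in_action"] = model.net.weights.w_in_action
    save_arrays(path, arrays)


def load_into_agent_model(path: str | Path, agent: Agent, model: WorldModel | None) -> None:
    """Restore a checkpoint into already-constructed modules, in place."""
    d = load_arrays(path)
    agent.net.weights.w_rec[:] = d["agent.w_rec"]
    agent.readout.r_pi[:] = d["agent.r_pi"]
    agent.net.weights.w_in_state[:] = d["agent.w_in_state"]
    agent.opt.load_state_dict(
        {k[len("agent.opt."):]: v for k, v in d.items() if k.startswith("agent.opt.")}
    )
    if model is not None and "model.w_rec" in d:
        model.net.weights.w_rec[:] = d["model.w_rec"]
        model.readout.r_xi[:] = d["model.r_xi"]
        model.readout.r_r[:] = d["model.r_r"]
        model.net.weights.w_in_state[:] = d["model.w_in_state"]
        if model.net.weights.w_in_action is not None:
            model.net.weights.w_in_action[:] = d["model.w_in_action"]
        model.opt.load_state_dict(
            {k[len("model.opt."):]: v for k, v in d.items() if k.startswith("model.opt.")}
        )
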