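"""Online world-model learning in the model sub-network.

The model module receives the current world state ξ and the agent's one-hot
action, and predicts the next world state and reward as *linear readouts*
of its slow-filtered spiking activity s̄:

    ξ̂_k = Σ_i R^ξ_{ki} s̄_i,      r̂ = Σ_i R^r_i s̄_i .

Training minimises the squared prediction error

    E^M = c_ξ Σ_{t,k} (ξ*_k − ξ̂_k)² + c_r Σ_t (r* − r̂)²

online: each time step contributes one additive update, local in space and
time.  The readout updates are the exact (rescaled) gradient of E^M; the
recurrent update routes the readout-weighted error back through the
surrogate threshold derivative p and the per-presynaptic eligibility trace
e, giving the three-factor rule

    Δw^M_{ij} ∝ [c_ξ Σ_k R^ξ_{ki} ε^ξ_k + c_r R^r_i ε^r] · p_i · e_j .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import NeuronParams, SpikingModule
from .optim import Adam

__all__ = [
    "ModelReadout",
    "ModelGradients",
    "predict",
    "model_loss",
    "model_update_step",
    "WorldModel",
]


@dataclass
class ModelReadout:
    """Linear readouts of the model module and the loss weights.

    ``r_xi`` has shape (D, N), ``r_r`` shape (N,).  ``c_xi`` and ``c_r``
    weight the state and reward terms of the prediction loss (defaults 1.0
    and 0.1).
    """

    r_xi: np.ndarray
    r_r: np.ndarray
    c_xi: float = 1.0
    c_r: float = 0.1

    def __post_init__(self) -> None:
        if self.c_xi < 0 or self.c_r < 0:
            raise ValueError("loss weights must be non-negative")
        if self.r_xi.shape[1] != self.r_r.shape[0]:
            raise ValueError(
                f"readout shapes disagree: r_xi {self.r_xi.shape}, r_r {self.r_r.shape}"
            )

    @classmethod
    def zeros(cls, d_state: int, n: int, c_xi: float = 1.0, c_r: float = 0.1) -> "ModelReadout":
        return cls(r_xi=np.zeros((d_state, n)), r_r=np.zeros(n), c_xi=c_xi, c_r=c_r)


@dataclass
class ModelGradients:
    """Per-step (or accumulated) update directions for the model parameters."""

    d_w: np.ndarray
    d_r_xi: np.ndarray
    d_r_r: np.ndarray


def predict(s_bar: np.ndarray, readout: ModelReadout) -> tuple[np.ndarray, float]:
    """Read the predicted next world state and reward from filtered activity."""
    return readout.r_xi @ s_bar, float(readout.r_r @ s_bar)


def model_loss(
    targets: list[tuple[np.ndarray, float]],
    predictions: list[tuple[np.ndarray, float]],
    c_xi: float = 1.0,
    c_r: float = 0.1,
) -> float:
    """Weighted squared-error loss E^M over a sequence of steps."""
    if len(targets) != len(predictions):
        raise ValueError("targets and predictions must have equal length")
    total = 0.0
    for (xi_star, r_star), (xi_hat, r_hat) in zip(targets, predictions):
        diff = np.asarray(xi_star, dtype=float) - np.asarray(xi_hat, dtype=float)
        total += c_xi * float(diff @ diff) + c_r * (r_star - r_hat) ** 2
    return total


def model_update_step(
    p: np.ndarray,
    e: np.ndarray,
    s_bar: np.ndarray,
    readout: ModelReadout,
    err_xi: np.ndarray,
    err_r: float,
) -> ModelGradients:
    """One additive contribution of the local model plasticity rule.

    Parameters are the surrogate derivative ``p`` and eligibility ``e`` of
    the model module at the step that produced the prediction, the filtered
    activity ``s_bar`` the prediction was read from, and the prediction
    errors ``err_xi = ξ* − ξ̂`` and ``err_r = r* − r̂``.
    """
    c_xi, c_r = readout.c_xi, readout.c_r
    # learning signal broadcast to each postsynaptic neuron
    learn_sig = c_xi * (readout.r_xi.T @ err_xi) + c_r * readout.r_r * err_r
    d_w = np.outer(learn_sig * p, e)
    d_r_xi = c_xi * np.outer(err_xi, s_bar)
    d_r_r = c_r * err_r * s_bar
    return ModelGradients(d_w=d_w, d_r_xi=d_r_xi, d_r_r=d_r_r)


class WorldModel:
    """Model sub-network with its readouts and online optimizer.

    The usage pattern per environment step is ``predict_next(xi, action)``
    followed — when the true next observation arrives and learning is
    enabled — by ``learn(xi_next, r_next)``, which consumes the traces of
    the step that produced the prediction.
    """

    def __init__(
        self,
        params: NeuronParams,
        d_state: int,
        n_actions: int,
        seed: int | np.random.Generator = 0,
        c_xi: float = 1.0,
        c_r: float = 0.1,
        lr: float = 0.001,
    ) -> None:
        self.net = SpikingModule(params, d_state, n_actions, seed)
        self.readout = ModelReadout.zeros(d_state, params.n, c_xi=c_xi, c_r=c_r)
        self.opt = Adam(lr=lr)
        self.trainable = True
        self._last_pred: tuple[np.ndarray, float] | None = None
        self._last_traces: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def d_state(self) -> int:
        return self.net.d_state

    def reset(self) -> None:
        """Reset the dynamic state at a phase boundary; weights persist."""
        self.net.reset()
        self._last_pred = None
        self._last_traces = None

    def predict_next(self, xi: np.ndarray, action_onehot: np.ndarray) -> tuple[np.ndarray, float]:
        """Drive the module with (ξ, action) and read (ξ̂, r̂) for the next step."""
        state = self.net.step(xi, action_onehot)
        xi_hat, r_hat = predict(state.s_bar, self.readout)
        self._last_pred = (xi_hat, r_hat)
        self._last_traces = (self.net.pseudo_deriv(), state.e.copy(), state.s_bar.copy())
        return xi_hat, r_hat

    def learn(self, xi_target: np.ndarray, r_target: float) -> None:
        """One online plasticity step against the realised (ξ*, r*)."""
        if not self.trainable:
            return
        if self._last_pred is None or self._last_traces is None:
            raise RuntimeError("learn() called before predict_next()")
        xi_hat, r_hat = self._last_pred
        p, e, s_bar = self._last_traces
        err_xi = np.asarray(xi_target, dtype=float) - xi_hat
        err_r = float(r_target) - r_hat
        ro = self.readout
        learn_sig = ro.c_xi * (ro.r_xi.T @ err_xi) + ro.c_r * ro.r_r * err_r
        # same math as model_update_step, with rank-1 gradients left unformed
        self.opt.step(
            {"w": self.net.weights.w_rec, "r_xi": ro.r_xi, "r_r": ro.r_r},
            {
                "w": (learn_sig * p, e),
                "r_xi": (ro.c_xi * err_xi, s_bar),
                "r_r": ro.c_r * err_r * s_bar,
            },
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "w_rec": self.net.weights.w_rec,
            "r_xi": self.readout.r_xi,
            "r_r": self.readout.r_r,
        }
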