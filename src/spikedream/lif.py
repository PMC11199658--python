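"""Discrete-time leaky integrate-and-fire dynamics with filtered traces.

Both sub-networks (the agent and the world model) are recurrent networks of
``N`` leaky integrate-and-fire neurons simulated on a fixed grid of step
``dt``.  One simulation step advances, in order,

1. the spike ``s^t = Θ[v^{t-1} - v_th]`` emitted from the stored potential,
2. the fast-filtered spike trace ``ŝ`` (time constant ``tau_s``) that feeds
   the recurrent synapses,
3. the membrane potential ``v`` — a leaky integrator of the recurrent
   filtered input, the external current and the rest potential, with an
   amplitude-``w_reset`` reset subtracted after each spike,
4. the slow readout trace ``s̄`` (time constant ``tau_star``) from which all
   linear readouts (policy logits, predicted state, predicted reward) are
   computed, and
5. the spike-response (eligibility) trace ``e`` — a low-pass memory of the
   presynaptic filtered spikes, maintained one trace per presynaptic neuron,
   which approximates ``∂v_i/∂w_ij`` for the linearised membrane recursion.

The membrane update uses forward-Euler leak factors ``(1 - dt/τ)`` while the
readout and eligibility filters use exponential factors ``exp(-dt/τ)``; the
two agree to O(dt²) and are kept exactly as each trace is defined.

Spiking is non-differentiable; gradients through the threshold use the
surrogate :func:`pseudo_derivative`, a logistic-derivative bump of width
``dv`` peaked at the firing threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "NeuronParams",
    "ModuleState",
    "NetworkWeights",
    "init_module",
    "step_dynamics",
    "pseudo_derivative",
    "update_spike_response",
    "SpikingModule",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one recurrent LIF module.

    All time constants are in milliseconds and must exceed the integration
    step ``dt`` (default 1 ms, one environment frame per network step).
    Potentials are dimensionless; ``v_th`` and ``v_rest`` set the scale.
    """

    n: int = 500
    dt: float = 1.0
    tau_m: float = 20.0
    tau_s: float = 2.0
    tau_star: float = 10.0
    v_th: float = 0.0
    v_rest: float = -4.0
    w_reset: float = 20.0
    dv: float = 1.0
    sigma_in: float = 5.0
    sigma_rec: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"neuron count must be >= 1, got {self.n}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        for name in ("tau_m", "tau_s", "tau_star"):
            tau = getattr(self, name)
            if tau <= self.dt:
                raise ValueError(f"{name}={tau} must exceed dt={self.dt}")
        if self.w_reset <= 0:
            raise ValueError(f"w_reset must be positive, got {self.w_reset}")
        if self.dv <= 0:
            raise ValueError(f"dv must be positive, got {self.dv}")

    # Cached per-step filter factors.
    @property
    def alpha_m(self) -> float:
        """Forward-Euler membrane leak factor, 1 - dt/tau_m."""
        return 1.0 - self.dt / self.tau_m

    @property
    def alpha_s(self) -> float:
        """Forward-Euler spike-filter leak factor, 1 - dt/tau_s."""
        return 1.0 - self.dt / self.tau_s

    @property
    def rho_m(self) -> float:
        """Exponential eligibility decay, exp(-dt/tau_m)."""
        return float(np.exp(-self.dt / self.tau_m))

    @property
    def rho_star(self) -> float:
        """Exponential readout-filter decay, exp(-dt/tau_star)."""
        return float(np.exp(-self.dt / self.tau_star))


@dataclass
class ModuleState:
    """Dynamical variables of one module at one time step.

    ``v`` membrane potentials; ``s`` binary spikes; ``s_hat`` fast filtered
    spikes feeding the recurrent synapses; ``s_bar`` slow filtered spikes
    feeding the readouts; ``e`` per-presynaptic-neuron spike-response traces;
    ``t`` the step index.  ``e`` is advanced with the same one-step-lagged
    filtered spikes that drive the membrane, so after a step ``e`` is the
    trace paired with the new ``v`` in all learning rules.
    """

    v: np.ndarray
    s: np.ndarray
    s_hat: np.ndarray
    s_bar: np.ndarray
    e: np.ndarray
    t: int = 0

    def copy(self) -> "ModuleState":
        return ModuleState(
            v=self.v.copy(),
            s=self.s.copy(),
            s_hat=self.s_hat.copy(),
            s_bar=self.s_bar.copy(),
            e=self.e.copy(),
            t=self.t,
        )


@dataclass
class NetworkWeights:
    """Synaptic weights of one module.

    ``w_rec[i, j]`` connects presynaptic neuron ``j`` to postsynaptic neuron
    ``i`` and is the only trainable matrix here (readouts live with their
    modules).  The input projections are drawn once from zero-mean Gaussians
    of scale ``sigma_in`` and stay frozen.  ``w_in_action`` is ``None`` for
    the agent module, which receives no action input.
    """

    w_rec: np.ndarray
    w_in_state: np.ndarray
    w_in_action: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]


def init_module(
    params: NeuronParams,
    d_state: int,
    n_actions: int,
    seed: int | np.random.Generator,
) -> tuple[ModuleState, NetworkWeights]:
    """Allocate a zeroed state (``v = v_rest``) and freshly drawn weights.

    Parameters
    ----------
    d_state
        Dimension D of the world-state vector projected into the module.
    n_actions
        Size A of the one-hot action input; pass 0 for the agent module,
        which receives no action projection.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`; the
        same seed always yields bit-identical weights.
    """
    if d_state < 1:
        raise ValueError(f"world-state dimension must be >= 1, got {d_state}")
    if n_actions < 0:
        raise ValueError(f"action count must be >= 0, got {n_actions}")
    rng = np.random.default_rng(seed)
    n = params.n
    w_rec = rng.normal(0.0, params.sigma_rec / np.sqrt(n), size=(n, n))
    w_in_state = rng.normal(0.0, params.sigma_in, size=(n, d_state))
    w_in_action = None
    if n_actions > 0:
        w_in_action = rng.normal(0.0, params.sigma_in, size=(n, n_actions))
    state = zero_state(params)
    return state, NetworkWeights(w_rec=w_rec, w_in_state=w_in_state, w_in_action=w_in_action)


def zero_state(params: NeuronParams) -> ModuleState:
    """All-zero state with the membrane at rest."""
    n = params.n
    return ModuleState(
        v=np.full(n, params.v_rest, dtype=float),
        s=np.zeros(n),
        s_hat=np.zeros(n),
        s_bar=np.zeros(n),
        e=np.zeros(n),
        t=0,
    )


def step_dynamics(
    state: ModuleState,
    weights: NetworkWeights,
    i_ext: np.ndarray,
    params: NeuronParams,
) -> ModuleState:
    """Advance one module by one integration step.

    Implements the three-line threshold/filter/integrate update together
    with the readout filter and the eligibility trace.  The threshold is
    crossed strictly (``v > v_th``), so a membrane sitting exactly at
    threshold does not fire.  Returns a new state; the input state is not
    modified.
    """
    p = params
    s_new = np.where(state.v - p.v_th > 0.0, 1.0, 0.0)
    s_hat_new = p.alpha_s * state.s_hat + (p.dt / p.tau_s) * s_new
    v_new = (
        p.alpha_m * state.v
        + (p.dt / p.tau_m) * (weights.w_rec @ state.s_hat + i_ext + p.v_rest)
        - p.w_reset * state.s
    )
    if not np.all(np.isfinite(v_new)):
        raise FloatingPointError(
            f"membrane potential diverged (NaN/Inf) at step {state.t + 1}"
        )
    s_bar_new = p.rho_star * state.s_bar + (1.0 - p.rho_star) * s_new
    e_new = update_spike_response(state.e, state.s_hat, p)
    return ModuleState(v=v_new, s=s_new, s_hat=s_hat_new, s_bar=s_bar_new, e=e_new, t=state.t + 1)


def pseudo_derivative(v: np.ndarray, dv: float) -> np.ndarray:
    """Surrogate derivative of the spike threshold.

    ``p(v) = exp(v/dv) / (dv (exp(v/dv) + 1)^2)``, evaluated through the
    logistic function as ``σ(v/dv) (1 - σ(v/dv)) / dv`` so that large
    ``|v|/dv`` underflows smoothly to 0 instead of overflowing.  Peaks at
    the threshold with value ``1/(4 dv)``.
    """
    if dv <= 0:
        raise ValueError(f"dv must be positive, got {dv}")
    sig = expit(np.asarray(v, dtype=float) / dv)
    return sig * (1.0 - sig) / dv


def update_spike_response(
    e: np.ndarray, s_hat_pre: np.ndarray, params: NeuronParams
) -> np.ndarray:
    """One step of the eligibility filter: low-pass of presynaptic ŝ.

    ``e ← exp(-dt/τ_m) e + (1 - exp(-dt/τ_m)) ŝ``; the fixed point under a
    constant drive ``ŝ = c`` is ``c``, so traces of binary spike trains stay
    in [0, 1].
    """
    rho = params.rho_m
    return rho * e + (1.0 - rho) * s_hat_pre


class SpikingModule:
    """Stateful convenience wrapper: one LIF module plus its input pathway.

    ``step`` maps a world-state vector (and, for the model module, a one-hot
    action) to input currents through the frozen projections and advances
    the dynamics.  The recurrent matrix ``weights.w_rec`` is trainable.
    """

    def __init__(
        self,
        params: NeuronParams,
        d_state: int,
        n_actions: int = 0,
        seed: int | np.random.Generator = 0,
    ) -> None:
        self.params = params
        self.d_state = d_state
        self.n_actions = n_actions
        self.state, self.weights = init_module(params, d_state, n_actions, seed)

    def reset(self) -> None:
        """Zero the dynamic state (membranes at rest); weights untouched."""
        self.state = zero_state(self.params)

    def input_current(
        self, xi: np.ndarray, action_onehot: np.ndarray | None = None
    ) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (self.d_state,):
            raise ValueError(
                f"world-state vector has shape {xi.shape}, expected ({self.d_state},)"
            )
        i_ext = self.weights.w_in_state @ xi
        if self.weights.w_in_action is not None:
            if action_onehot is None:
                raise ValueError("this module expects a one-hot action input")
            i_ext = i_ext + self.weights.w_in_action @ np.asarray(action_onehot, dtype=float)
        return i_ext

    def step(self, xi: np.ndarray, action_onehot: np.ndarray | None = None) -> ModuleState:
        self.state = step_dynamics(
            self.state, self.weights, self.input_current(xi, action_onehot), self.params
        )
        return self.state

    def pseudo_deriv(self) -> np.ndarray:
        """Surrogate threshold derivative at the current potentials."""
        return pseudo_derivative(self.state.v, self.params.dv)
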