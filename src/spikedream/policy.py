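"""Policy computation and reward-gated discounted-eligibility plasticity.

The agent sub-network exposes a softmax policy over A discrete actions,

    y_k = Σ_i R^π_{ki} s̄_{A,i},     π_k = e^{y_k} / Σ_j e^{y_j} ,

and follows a policy-gradient rule that maximises the discounted return
R^t = Σ_{t'≥t} γ^{t'−t} r^{t'}.  Written online, the rule keeps two
γ-discounted eligibility accumulators, advanced once per step,

    G_{ij} ← γ G_{ij} + δ_i p_i e_j ,   δ_i = Σ_k R^π_{ki} (1_{a=k} − π_k)
    H_{ki} ← γ H_{ki} + (1_{a=k} − π_k) s̄_i ,

and gates them with the instantaneous reward: step ``t`` contributes
``r^t·G`` to the recurrent update and ``r^t·H`` to the readout update.
Summed over an episode this reproduces the nested sum
Σ_t r^t Σ_{t'≤t} γ^{t−t'}(·) while needing only quantities local in space
and time.  The summed contribution is a policy-gradient estimator for the
whole episode, so the optimizer applies it once per episode (or per
planning burst); the traces themselves are maintained online, one cheap
update per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lif import NeuronParams, SpikingModule
from .optim import Adam

__all__ = [
    "PolicyReadout",
    "EligibilityAccumulators",
    "compute_policy",
    "sample_action",
    "discounted_return",
    "policy_update_step",
    "Agent",
]


@dataclass
class PolicyReadout:
    """Policy readout matrix (A × N) and discount factor."""

    r_pi: np.ndarray
    gamma: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"discount factor must be in (0, 1], got {self.gamma}")
        if not np.all(np.isfinite(self.r_pi)):
            raise ValueError("policy readout contains non-finite entries")

    @property
    def n_actions(self) -> int:
        return self.r_pi.shape[0]

    @classmethod
    def zeros(cls, n_actions: int, n: int, gamma: float = 0.99) -> "PolicyReadout":
        return cls(r_pi=np.zeros((n_actions, n)), gamma=gamma)


@dataclass
class EligibilityAccumulators:
    """γ-discounted eligibility traces for the policy rule.

    ``g`` (N × N) feeds the recurrent update, ``h`` (A × N) the readout
    update.  Zeroed at every episode start.
    """

    g: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, n: int, n_actions: int) -> "EligibilityAccumulators":
        return cls(g=np.zeros((n, n)), h=np.zeros((n_actions, n)))

    def reset(self) -> None:
        self.g[:] = 0.0
        self.h[:] = 0.0


def compute_policy(s_bar: np.ndarray, readout: PolicyReadout) -> np.ndarray:
    """Softmax action distribution from filtered agent activity.

    Stabilised by subtracting the maximal logit, which leaves the
    distribution unchanged.
    """
    y = readout.r_pi @ s_bar
    y = y - np.max(y)
    ey = np.exp(y)
    return ey / ey.sum()


def sample_action(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one action from π; returns its one-hot encoding."""
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isfinite(pi)):
        raise ValueError("action distribution contains NaN/Inf")
    k = rng.choice(pi.shape[0], p=pi)
    onehot = np.zeros(pi.shape[0])
    onehot[k] = 1.0
    return onehot


def discounted_return(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """Backward recursion R^t = r^t + γ R^{t+1} over a finite episode."""
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty_like(rewards)
    acc = 0.0
    for t in range(rewards.shape[0] - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def policy_update_step(
    acc: EligibilityAccumulators,
    p: np.ndarray,
    e: np.ndarray,
    s_bar: np.ndarray,
    pi: np.ndarray,
    action_onehot: np.ndarray,
    reward: float,
    readout: PolicyReadout,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the eligibility accumulators and return this step's updates.

    Mutates ``acc`` in place (one advance per time step) and returns the
    reward-gated contributions ``(r·G, r·H)`` for the recurrent weights and
    the policy readout.  With zero reward the contribution vanishes but the
    traces still decay and accumulate.
    """
    adv = action_onehot - pi
    delta = readout.r_pi.T @ adv
    _kernels.rank1_discount(acc.g, readout.gamma, delta * p, e)
    _kernels.rank1_discount(acc.h, readout.gamma, adv, s_bar)
    return reward * acc.g, reward * acc.h


class Agent:
    """Agent sub-network with softmax policy readout and online learning."""

    def __init__(
        self,
        params: NeuronParams,
        d_state: int,
        n_actions: int,
        seed: int | np.random.Generator = 0,
        gamma: float = 0.99,
        lr: float = 0.001,
    ) -> None:
        self.net = SpikingModule(params, d_state, n_actions=0, seed=seed)
        self.readout = PolicyReadout.zeros(n_actions, params.n, gamma=gamma)
        self.acc = EligibilityAccumulators.zeros(params.n, n_actions)
        self.opt = Adam(lr=lr)
        self._last: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None
        self._d_w = np.zeros((params.n, params.n))
        self._d_r = np.zeros((n_actions, params.n))
        self._grad_live = False

    @property
    def n_actions(self) -> int:
        return self.readout.n_actions

    def reset(self) -> None:
        """Episode boundary: zero dynamic state, traces and pending gradients."""
        self.net.reset()
        self.acc.reset()
        self._last = None
        self.clear_gradient()

    def act(self, xi: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Step the dynamics on ξ, compute π and sample a one-hot action."""
        state = self.net.step(xi)
        pi = compute_policy(state.s_bar, self.readout)
        action = sample_action(pi, rng)
        self._last = (self.net.pseudo_deriv(), state.e.copy(), state.s_bar.copy(), pi)
        return action, pi

    def learn(self, action_onehot: np.ndarray, reward: float) -> None:
        """Accumulate one reward-gated plasticity contribution.

        Advances the discounted eligibility traces and adds ``r^t·G`` and
        ``r^t·H`` into the episode gradient.  The summed gradient is a valid
        policy-gradient estimator only over a whole episode, so the weight
        change itself is applied by :meth:`end_episode`.  On zero-reward
        steps only the traces advance.
        """
        if self._last is None:
            raise RuntimeError("learn() called before act()")
        p, e, s_bar, pi = self._last
        reward = float(reward)
        adv = action_onehot - pi
        delta = self.readout.r_pi.T @ adv
        _kernels.rank1_discount(self.acc.g, self.readout.gamma, delta * p, e)
        _kernels.rank1_discount(self.acc.h, self.readout.gamma, adv, s_bar)
        if reward != 0.0:
            self._d_w += reward * self.acc.g
            self._d_r += reward * self.acc.h
            self._grad_live = True

    def end_episode(self) -> None:
        """Apply one Adam step on the episode-accumulated policy gradient."""
        grads = (
            {"w": self._d_w, "r_pi": self._d_r}
            if self._grad_live
            else {"w": None, "r_pi": None}
        )
        self.opt.step({"w": self.net.weights.w_rec, "r_pi": self.readout.r_pi}, grads)
        self.clear_gradient()

    def clear_gradient(self) -> None:
        self._d_w[:] = 0.0
        self._d_r[:] = 0.0
        self._grad_live = False

    def pending_gradient(self) -> tuple[np.ndarray, np.ndarray]:
        """The episode gradient accumulated so far (copies)."""
        return self._d_w.copy(), self._d_r.copy()

    def advance_traces(self, action_onehot: np.ndarray) -> None:
        """Advance eligibility traces without applying any weight update.

        Used when behaving with plasticity switched off, so that trace
        dynamics (and hence trajectories) match the learning condition.
        """
        if self._last is None:
            raise RuntimeError("advance_traces() called before act()")
        p, e, s_bar, pi = self._last
        policy_update_step(self.acc, p, e, s_bar, pi, action_onehot, 0.0, self.readout)

    def parameters(self) -> dict[str, np.ndarray]:
        return {"w_rec": self.net.weights.w_rec, "r_pi": self.readout.r_pi}
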