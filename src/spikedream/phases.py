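"""Awake, dreaming and planning training regimes and their alternation.

Three ways the agent gathers experience:

* **awake** — the closed loop with the real environment: the agent samples an
  action from its policy, the environment returns the next world state and
  reward, the world model trains online on that transition, and the agent's
  policy trains online on the reward.
* **dreaming** — an offline episode in which the world model *replaces* the
  environment: starting from a randomly drawn world state, next states and
  rewards come from the model's readouts in closed loop.  Only the policy
  learns; the model is untouched.
* **planning** — an online augmentation of awake behaviour: every
  ``dt_pred = 2·n_fut`` real steps, the current real state seeds an
  ``n_fut``-step simulated rollout whose policy gradients are applied, while
  the dynamic network state is snapshotted and restored around the burst.

Only awake steps count as interactions with the environment; learning curves
are indexed by that counter.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lif import NeuronParams
from .policy import Agent
from .pong import PongEnv
from .worldmodel import WorldModel

__all__ = [
    "PhaseConfig",
    "ExperimentConfig",
    "EpisodeLog",
    "run_awake_episode",
    "run_dream_episode",
    "run_planning_episode",
    "train",
]


@dataclass(frozen=True)
class PhaseConfig:
    """Schedule and mode flags for the training regimes.

    ``t_awake`` and ``t_dream`` are the awake and dream horizons in steps
    (defaults 100 and 50).  ``n_fut > 0`` enables planning with period
    ``dt_pred = 2·n_fut``.  ``model_freeze_after`` stops world-model updates
    from that game index on (``None`` = never).
    """

    t_awake: int = 100
    t_dream: int = 50
    n_fut: int = 0
    dreams_per_game: int = 1
    learn_policy_awake: bool = True
    learn_policy_dream: bool = True
    learn_model_awake: bool = True
    model_freeze_after: int | None = None
    clip_dream_reward: bool = False
    dream_divergence_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.t_awake < 1 or self.t_dream < 1:
            raise ValueError("phase horizons must be >= 1")
        if self.n_fut < 0:
            raise ValueError(f"n_fut must be >= 0, got {self.n_fut}")
        if self.dreams_per_game < 0:
            raise ValueError("dreams_per_game must be >= 0")
        if self.learn_policy_dream and not self.learn_policy_awake and self.dreams_per_game == 0:
            raise ValueError(
                "policy learning restricted to dreams but dreams_per_game=0: "
                "no phase would ever train the policy"
            )

    @property
    def dt_pred(self) -> int:
        """Planning period in real steps (2·n_fut)."""
        return 2 * self.n_fut


@dataclass
class EpisodeLog:
    """Time-indexed record of one rollout (awake, dream or planning).

    ``xi[t]`` is the world state the agent acted on at step ``t``;
    ``pred_xi[t]``/``pred_r[t]`` the model's one-step prediction made at
    step ``t`` (NaN when no model ran).  ``real_steps`` counts environment
    interactions, ``sim_steps`` model-simulated steps.
    """

    phase: str
    xi: np.ndarray
    actions: np.ndarray
    pi: np.ndarray
    rewards: np.ndarray
    pred_xi: np.ndarray
    pred_r: np.ndarray
    real_steps: int
    sim_steps: int = 0

    def __len__(self) -> int:
        return self.rewards.shape[0]

    @property
    def total_reward(self) -> float:
        return float(self.rewards.sum())

    def prediction_mse(self) -> float:
        """Mean squared one-step world-state prediction error over the episode."""
        diff = self.pred_xi - self.xi[1:]
        return float(np.mean(diff**2))


def _empty_log(phase: str, horizon: int, d: int, a: int) -> EpisodeLog:
    return EpisodeLog(
        phase=phase,
        xi=np.zeros((horizon + 1, d)),
        actions=np.zeros((horizon, a)),
        pi=np.zeros((horizon, a)),
        rewards=np.zeros(horizon),
        pred_xi=np.full((horizon, d), np.nan),
        pred_r=np.full(horizon, np.nan),
        real_steps=0,
    )


def run_awake_episode(
    agent: Agent,
    model: WorldModel | None,
    env,
    cfg: PhaseConfig,
    rng: np.random.Generator,
) -> EpisodeLog:
    """One game against the real environment, with online learning.

    The model (when present) is driven by the real (ξ, action) stream and,
    when ``learn_model_awake`` and the model is trainable, updates its
    weights against the realised next state and reward.
    """
    agent.reset()
    if model is not None:
        model.reset()
    xi = np.asarray(env.reset(), dtype=float)
    if xi.shape != (agent.net.d_state,):
        raise ValueError(
            f"environment emits D={xi.shape}, agent expects D={agent.net.d_state}"
        )
    log = _empty_log("awake", cfg.t_awake, xi.shape[0], agent.n_actions)
    log.xi[0] = xi
    for t in range(cfg.t_awake):
        action, pi = agent.act(xi, rng)
        if model is not None:
            xi_hat, r_hat = model.predict_next(xi, action)
            log.pred_xi[t] = xi_hat
            log.pred_r[t] = r_hat
        xi_next, r = env.step(action)
        xi_next = np.asarray(xi_next, dtype=float)
        if model is not None and cfg.learn_model_awake:
            model.learn(xi_next, r)
        if cfg.learn_policy_awake:
            agent.learn(action, r)
        else:
            agent.advance_traces(action)
        log.actions[t] = action
        log.pi[t] = pi
        log.rewards[t] = r
        log.xi[t + 1] = xi_next
        xi = xi_next
    if cfg.learn_policy_awake:
        agent.end_episode()
    log.real_steps = cfg.t_awake
    return log


def run_dream_episode(
    agent: Agent,
    model: WorldModel,
    cfg: PhaseConfig,
    rng: np.random.Generator,
    xi_bounds: tuple[float, float] = (0.0, 1.0),
) -> EpisodeLog:
    """One offline game inside the learned world model.

    The initial world state is drawn uniformly from the environment's valid
    coordinate box; thereafter states and rewards are the model's closed-loop
    predictions.  Only the policy learns.  If a predicted state leaves the
    box by more than ``dream_divergence_factor`` times its width, the dream
    is aborted with a warning and the partial log returned.
    """
    agent.reset()
    model.reset()
    d = model.d_state
    lo, hi = xi_bounds
    xi = rng.uniform(lo, hi, size=d)
    log = _empty_log("dream", cfg.t_dream, d, agent.n_actions)
    log.xi[0] = xi
    limit = cfg.dream_divergence_factor * (hi - lo)
    steps = cfg.t_dream
    for t in range(cfg.t_dream):
        action, pi = agent.act(xi, rng)
        xi_next, r = model.predict_next(xi, action)
        if cfg.clip_dream_reward:
            r = float(np.clip(r, -1.0, 1.0))
        if np.any(xi_next < lo - limit) or np.any(xi_next > hi + limit):
            warnings.warn(
                f"dream diverged at step {t}: predicted state left the "
                f"{cfg.dream_divergence_factor}x environment box; aborting dream",
                RuntimeWarning,
                stacklevel=2,
            )
            steps = t
            break
        if cfg.learn_policy_dream:
            agent.learn(action, r)
        else:
            agent.advance_traces(action)
        log.actions[t] = action
        log.pi[t] = pi
        log.rewards[t] = r
        log.pred_xi[t] = xi_next
        log.pred_r[t] = r
        log.xi[t + 1] = xi_next
        xi = xi_next
    if cfg.learn_policy_dream:
        agent.end_episode()
    if steps < cfg.t_dream:
        log = EpisodeLog(
            phase="dream",
            xi=log.xi[: steps + 1],
            actions=log.actions[:steps],
            pi=log.pi[:steps],
            rewards=log.rewards[:steps],
            pred_xi=log.pred_xi[:steps],
            pred_r=log.pred_r[:steps],
            real_steps=0,
            sim_steps=steps,
        )
        return log
    log.sim_steps = steps
    log.real_steps = 0
    return log


def _snapshot(agent: Agent, model: WorldModel):
    return (
        agent.net.state.copy(),
        agent.acc.g.copy(),
        agent.acc.h.copy(),
        agent._last,
        model.net.state.copy(),
        model._last_pred,
        model._last_traces,
    )


def _restore(agent: Agent, model: WorldModel, snap) -> None:
    (agent.net.state, g, h, agent._last, model.net.state, model._last_pred,
     model._last_traces) = snap
    agent.acc.g = g
    agent.acc.h = h


def run_planning_episode(
    agent: Agent,
    model: WorldModel,
    env,
    cfg: PhaseConfig,
    rng: np.random.Generator,
) -> EpisodeLog:
    """One awake game augmented with short simulated look-aheads.

    Every ``dt_pred`` real steps, the current real world state seeds an
    ``n_fut``-step rollout in the model; the policy gradients of the
    simulated steps are applied, then the dynamic state of both modules
    (and the eligibility traces) is restored, so the burst changes only the
    weights.  Real-step learning proceeds exactly as in the awake phase.
    """
    if cfg.n_fut < 1:
        return run_awake_episode(agent, model, env, cfg, rng)
    agent.reset()
    model.reset()
    xi = np.asarray(env.reset(), dtype=float)
    log = _empty_log("plan", cfg.t_awake, xi.shape[0], agent.n_actions)
    log.xi[0] = xi
    sim_steps = 0
    for t in range(cfg.t_awake):
        action, pi = agent.act(xi, rng)
        xi_hat, r_hat = model.predict_next(xi, action)
        log.pred_xi[t] = xi_hat
        log.pred_r[t] = r_hat
        xi_next, r = env.step(action)
        xi_next = np.asarray(xi_next, dtype=float)
        if cfg.learn_model_awake:
            model.learn(xi_next, r)
        if cfg.learn_policy_awake:
            agent.learn(action, r)
        else:
            agent.advance_traces(action)
        log.actions[t] = action
        log.pi[t] = pi
        log.rewards[t] = r
        log.xi[t + 1] = xi_next
        xi = xi_next
        if (t + 1) % cfg.dt_pred == 0:
            snap = _snapshot(agent, model)
            awake_grad = agent.pending_gradient(), agent._grad_live
            agent.clear_gradient()
            xi_sim = xi
            for _ in range(cfg.n_fut):
                a_sim, _ = agent.act(xi_sim, rng)
                xi_sim, r_sim = model.predict_next(xi_sim, a_sim)
                if cfg.clip_dream_reward:
                    r_sim = float(np.clip(r_sim, -1.0, 1.0))
                agent.learn(a_sim, r_sim)
                sim_steps += 1
            agent.end_episode()  # the burst is its own short episode
            _restore(agent, model, snap)
            (agent._d_w, agent._d_r), agent._grad_live = awake_grad
    log.real_steps = cfg.t_awake
    log.sim_steps = sim_steps
    if cfg.learn_policy_awake:
        agent.end_episode()
    return log


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one training experiment."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    n_games: int = 300
    n_actions: int = 3
    d_state: int = 4
    gamma: float = 0.99
    lr: float = 0.001
    c_xi: float = 1.0
    c_r: float = 0.1

    @property
    def uses_model(self) -> bool:
        return (
            self.phase.dreams_per_game > 0
            or self.phase.n_fut > 0
            or self.phase.learn_model_awake
        )


def train(
    config: ExperimentConfig,
    seeds: list[int] | tuple[int, ...],
    env_factory=PongEnv,
    out_dir: str | Path | None = None,
    condition: str | None = None,
    callback=None,
) -> pd.DataFrame:
    """Run the awake/dream alternation schedule for each seed.

    Each game is one awake (or planning) episode followed by
    ``dreams_per_game`` dreams.  Returns a learning-curve table with one row
    per (seed, game): total game reward, cumulative real interactions, and
    the model's one-step prediction MSE for that game.  With ``out_dir``,
    writes ``curves.csv``, a JSON run manifest, and a final checkpoint per
    seed.  ``callback(seed, game, agent, model)``, when given, runs after
    every game (used for ablation probes).
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    if condition is None:
        condition = _condition_name(config.phase)
    rows = []
    final_state: dict[int, tuple[Agent, WorldModel | None]] = {}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        agent = Agent(
            config.neuron, config.d_state, config.n_actions,
            seed=rng.integers(2**31), gamma=config.gamma, lr=config.lr,
        )
        model = None
        if config.uses_model:
            model = WorldModel(
                config.neuron, config.d_state, config.n_actions,
                seed=rng.integers(2**31), c_xi=config.c_xi, c_r=config.c_r,
                lr=config.lr,
            )
        env = env_factory()
        interactions = 0
        for game in range(config.n_games):
            if (
                model is not None
                and config.phase.model_freeze_after is not None
                and game >= config.phase.model_freeze_after
            ):
                model.trainable = False
            if config.phase.n_fut > 0:
                log = run_planning_episode(agent, model, env, config.phase, rng)
            else:
                log = run_awake_episode(agent, model, env, config.phase, rng)
            interactions += log.real_steps
            if model is not None:
                for _ in range(config.phase.dreams_per_game):
                    run_dream_episode(agent, model, config.phase, rng)
            rows.append(
                {
                    "condition": condition,
                    "seed": seed,
                    "game": game,
                    "reward": log.total_reward,
                    "interactions": interactions,
                    "pred_mse": log.prediction_mse() if model is not None else np.nan,
                }
            )
            if callback is not None:
                callback(seed, game, agent, model)
        final_state[seed] = (agent, model)
    curves = pd.DataFrame(rows)
    if out_dir is not None:
        _write_outputs(Path(out_dir), config, seeds, condition, curves, final_state)
    return curves


def interactions_to_reach(
    curve: pd.DataFrame, threshold: float = 0.0, window: int = 20
) -> float:
    """Environment interactions needed for the running mean reward to reach a level.

    ``curve`` is the learning-curve table of a single seed (columns ``game``,
    ``reward``, ``interactions``).  Returns the cumulative interaction count
    at the first game where the trailing ``window``-game mean reward is at
    least ``threshold``, or ``inf`` if never reached.
    """
    curve = curve.sort_values("game")
    running = curve["reward"].rolling(window).mean()
    hit = running >= threshold
    if not hit.any():
        return float("inf")
    return float(curve["interactions"][hit.idxmax()])


def _condition_name(phase: PhaseConfig) -> str:
    if phase.n_fut > 0:
        return f"planning(n_fut={phase.n_fut})"
    if phase.dreams_per_game > 0:
        if not phase.learn_policy_awake:
            return "dream-only-policy"
        return "awake+dream"
    return "awake-only"


def _write_outputs(out_dir, config, seeds, condition, curves, final_state) -> None:
    from . import __version__
    from .checkpoint import save_agent_model

    out_dir.mkdir(parents=True, exist_ok=True)
    curves.to_csv(out_dir / "curves.csv", index=False)
    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "condition": condition,
        "seeds": list(map(int, seeds)),
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "package_version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    for seed, (agent, model) in final_state.items():
        save_agent_model(out_dir / f"checkpoint_seed{seed}.npz", agent, model)
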