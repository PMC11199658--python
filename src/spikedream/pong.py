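"""Minimal limited-horizon Pong-like environment, renderer, and env adapter.

A desk-scale two-paddle game on the unit square.  The agent's paddle sits on
the right edge, a fixed imperfect ball-tracking opponent on the left.  The
observation is the 4-vector

    ξ = (agent paddle y, opponent paddle y, ball x, ball y) ∈ [0, 1]^4

and the reward is +1 when the opponent misses the ball, −1 when the agent
misses, 0 otherwise.  Dynamics are deterministic; after a point the ball
re-serves from the centre after a short delay.  Speeds and delays default to
a calibration under which, over a 100-frame episode, a perfect ball-tracking
agent scores exactly one point and a stationary worst-case agent concedes
exactly two — so episode returns are bounded in [−2, +1].

Three actions: 0 moves the paddle up (+y), 1 stays, 2 moves down (−y).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

__all__ = [
    "PongConfig",
    "PongState",
    "PongEnv",
    "perfect_tracker_policy",
    "stationary_policy",
    "render_frame",
    "write_pgm",
    "EnvContractError",
    "validate_env",
    "GymEnvAdapter",
    "N_ACTIONS",
    "D_STATE",
]

N_ACTIONS = 3
D_STATE = 4


@dataclass(frozen=True)
class PongConfig:
    """Geometry and kinematics of the built-in game (unit-square units/frame)."""

    paddle_half: float = 0.1      # paddle half-height
    agent_speed: float = 0.02     # agent paddle speed per frame
    opponent_speed: float = 0.002  # opponent tracking speed per frame
    ball_vx: float = 1.0 / 60.0   # horizontal ball speed per frame
    ball_vy: float = 0.005        # vertical ball speed per frame at serve
    serve_x: float = 0.5
    serve_y: float = 0.5
    initial_delay: int = 5        # frames before the first serve moves
    serve_delay: int = 10         # frames between a point and the next serve
    paddle_start: float = 0.5


@dataclass
class PongState:
    """Full internal game state; the observation ξ is a 4-slice of it."""

    paddle_agent: float
    paddle_opponent: float
    ball_x: float
    ball_y: float
    vx: float
    vy: float
    serve_timer: int

    def observation(self) -> np.ndarray:
        return np.array([self.paddle_agent, self.paddle_opponent, self.ball_x, self.ball_y])


class PongEnv:
    """Step/reset environment over :class:`PongState`.

    ``reset(seed)`` accepts a seed for interface compatibility; the built-in
    dynamics are fully deterministic.
    """

    d_state = D_STATE
    n_actions = N_ACTIONS

    def __init__(self, config: PongConfig | None = None) -> None:
        self.config = config or PongConfig()
        self.state: PongState | None = None

    def reset(self, seed: int | None = None) -> np.ndarray:
        c = self.config
        self.state = PongState(
            paddle_agent=c.paddle_start,
            paddle_opponent=c.paddle_start,
            ball_x=c.serve_x,
            ball_y=c.serve_y,
            vx=c.ball_vx,
            vy=c.ball_vy,
            serve_timer=c.initial_delay,
        )
        return self.state.observation()

    def _serve(self) -> None:
        c = self.config
        st = self.state
        st.ball_x = c.serve_x
        st.ball_y = c.serve_y
        st.vx = c.ball_vx      # serves always travel toward the agent
        st.vy = c.ball_vy
        st.serve_timer = c.serve_delay

    def step(self, action: int | np.ndarray) -> tuple[np.ndarray, float]:
        if self.state is None:
            raise RuntimeError("step() called before reset()")
        a = _action_index(action)
        c = self.config
        st = self.state

        # paddles
        if a == 0:
            st.paddle_agent += c.agent_speed
        elif a == 2:
            st.paddle_agent -= c.agent_speed
        st.paddle_agent = float(np.clip(st.paddle_agent, 0.0, 1.0))
        gap = st.ball_y - st.paddle_opponent
        st.paddle_opponent += float(np.clip(gap, -c.opponent_speed, c.opponent_speed))
        st.paddle_opponent = float(np.clip(st.paddle_opponent, 0.0, 1.0))

        reward = 0.0
        if st.serve_timer > 0:
            st.serve_timer -= 1
            return st.observation(), reward

        # ball flight with wall bounces
        st.ball_x += st.vx
        st.ball_y += st.vy
        if st.ball_y > 1.0:
            st.ball_y = 2.0 - st.ball_y
            st.vy = -st.vy
        elif st.ball_y < 0.0:
            st.ball_y = -st.ball_y
            st.vy = -st.vy

        if st.ball_x >= 1.0:
            if abs(st.ball_y - st.paddle_agent) <= c.paddle_half:
                st.ball_x = 2.0 - st.ball_x
                st.vx = -st.vx
            else:
                reward = -1.0
                self._serve()
        elif st.ball_x <= 0.0:
            if abs(st.ball_y - st.paddle_opponent) <= c.paddle_half:
                st.ball_x = -st.ball_x
                st.vx = -st.vx
            else:
                reward = 1.0
                self._serve()
        return st.observation(), reward


def _action_index(action: int | np.ndarray) -> int:
    if isinstance(action, (int, np.integer)):
        a = int(action)
    else:
        arr = np.asarray(action)
        if arr.ndim != 1 or arr.sum() != 1 or not np.all((arr == 0) | (arr == 1)):
            raise ValueError(f"action must be an index or a one-hot vector, got {action!r}")
        a = int(np.argmax(arr))
    if not 0 <= a < N_ACTIONS:
        raise ValueError(f"action index {a} outside 0..{N_ACTIONS - 1}")
    return a


def perfect_tracker_policy(xi: np.ndarray) -> int:
    """Scripted best-case policy: always move the paddle toward the ball."""
    paddle_y, ball_y = xi[0], xi[3]
    if ball_y > paddle_y:
        return 0
    if ball_y < paddle_y:
        return 2
    return 1


def stationary_policy(xi: np.ndarray) -> int:
    """Scripted worst-case policy: drive the paddle into the bottom corner."""
    return 2


# ---------------------------------------------------------------------------
# rendering

def render_frame(
    state: PongState,
    shape: tuple[int, int] = (210, 160),
    paddle_px_width: int = 4,
    ball_px: int = 4,
    paddle_half: float = 0.1,
) -> np.ndarray:
    """Binary frame (rows × cols, uint8) with paddles and ball as rectangles.

    The default 210 × 160 shape gives the full 33,600-pixel frame; smaller
    shapes (e.g. 52 × 40) render the same scene at reduced resolution.
    Deterministic: identical states produce identical frames.
    """
    h, w = shape
    frame = np.zeros((h, w), dtype=np.uint8)
    pad_h = max(1, int(round(2 * paddle_half * h)))

    def vrect(col0: int, center_y: float, height: int, width: int) -> None:
        r0 = int(round(center_y * (h - 1))) - height // 2
        r0 = min(max(r0, 0), h - height)
        frame[r0 : r0 + height, col0 : col0 + width] = 1

    vrect(0, state.paddle_opponent, pad_h, paddle_px_width)
    vrect(w - paddle_px_width, state.paddle_agent, pad_h, paddle_px_width)
    # ball
    r0 = int(round(state.ball_y * (h - 1))) - ball_px // 2
    c0 = int(round(state.ball_x * (w - 1))) - ball_px // 2
    r0 = min(max(r0, 0), h - ball_px)
    c0 = min(max(c0, 0), w - ball_px)
    frame[r0 : r0 + ball_px, c0 : c0 + ball_px] = 1
    return frame


def write_pgm(frame: np.ndarray, path) -> None:
    """Write a binary frame as a plain-text (P2) PGM image."""
    h, w = frame.shape
    lines = [f"P2\n{w} {h}\n1\n"]
    for row in frame:
        lines.append(" ".join(str(int(v)) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# environment adapter contract

class EnvContractError(ValueError):
    """An environment object does not satisfy the step/reset contract."""


def validate_env(env, d_state: int, n_actions: int):
    """Check the reset/step contract of an environment and return it.

    The contract: ``reset(seed)`` returns a length-``d_state`` observation;
    ``step(action)`` accepts a one-hot action of length ``n_actions`` and
    returns an ``(observation, reward)`` pair with scalar reward.
    """
    if not hasattr(env, "reset") or not hasattr(env, "step"):
        raise EnvContractError("environment must expose reset() and step()")
    xi = env.reset(seed=0)
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (d_state,):
        raise EnvContractError(
            f"reset() observation has shape {xi.shape}, expected ({d_state},)"
        )
    onehot = np.zeros(n_actions)
    onehot[0] = 1.0
    out = env.step(onehot)
    if not (isinstance(out, tuple) and len(out) == 2):
        raise EnvContractError("step() must return an (observation, reward) pair")
    xi2, r = out
    xi2 = np.asarray(xi2, dtype=float)
    if xi2.shape != (d_state,):
        raise EnvContractError(
            f"step() observation has shape {xi2.shape}, expected ({d_state},)"
        )
    try:
        float(r)
    except (TypeError, ValueError) as exc:
        raise EnvContractError(f"step() reward is not scalar: {r!r}") from exc
    env.reset(seed=0)
    return env


class GymEnvAdapter:
    """Wrap a gym/gymnasium-style environment into the step/reset contract.

    The wrapped object's ``reset`` may return ``obs`` or ``(obs, info)``;
    ``step`` may return 4- or 5-tuples.  An optional ``encode`` callable maps
    raw observations (e.g. pixel frames) to the D-dimensional world vector.
    """

    def __init__(self, env, d_state: int, n_actions: int, encode=None) -> None:
        self._env = env
        self.d_state = d_state
        self.n_actions = n_actions
        self._encode = encode or (lambda obs: np.asarray(obs, dtype=float))

    def reset(self, seed: int | None = None) -> np.ndarray:
        try:
            out = self._env.reset(seed=seed)
        except TypeError:
            out = self._env.reset()
        obs = out[0] if isinstance(out, tuple) else out
        return self._check(self._encode(obs))

    def step(self, action: int | np.ndarray) -> tuple[np.ndarray, float]:
        out = self._env.step(_action_index(action))
        obs, reward = out[0], out[1]
        return self._check(self._encode(obs)), float(reward)

    def _check(self, xi: np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (self.d_state,):
            raise EnvContractError(
                f"encoded observation has shape {xi.shape}, expected ({self.d_state},)"
            )
        return xi
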