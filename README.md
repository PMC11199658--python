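# spikedream

Model-based reinforcement learning in recurrent spiking neural networks:
an *agent* network learns a behaviour policy while a *model* network learns,
fully online, to predict how the world responds to the agent's actions. The
learned world model is then used to generate extra training experience —
offline ("**dreaming**": whole episodes simulated with the environment
disconnected) or online ("**planning**": short look-aheads interleaved with
real play) — which reduces the number of real environment interactions
needed to learn a task.

The package is aimed at computational-neuroscience and neuromorphic-learning
researchers: every learning rule is **local in space and time** (each synapse
uses only its pre/post-synaptic traces plus a broadcast error or reward), so
no experience buffer, no backpropagation through time, and no offline replay
storage is required.

## The model

Each module α ∈ {A (agent), M (model)} is a recurrent network of N leaky
integrate-and-fire neurons on a discrete grid (Δt = 1 ms):

```
ŝ_i^t   = (1 − Δt/τ_s) ŝ_i^{t−1} + (Δt/τ_s) s_i^t            fast spike filter
v_i^t   = (1 − Δt/τ_m) v_i^{t−1}
          + (Δt/τ_m) (Σ_j w_ij ŝ_j^{t−1} + I_i^t + v_rest)
          − w_res s_i^{t−1}                                    membrane + reset
s_i^{t+1} = Θ[v_i^t − v_th]                                    spike
```

with τ_m = 20 ms, τ_s = 2 ms, v_th = 0, v_rest = −4, w_res = 20. A slower
filter s̄ (τ\* = 10 ms) feeds all linear readouts. Gradients pass through
the spike threshold via the surrogate `p(v) = e^{v/δv} / (δv (e^{v/δv}+1)²)`,
and each synapse keeps an eligibility trace `e_j`, a low-pass memory of the
presynaptic filtered spikes.

The agent receives the world vector ξ ∈ R^D through a frozen random
projection (σ = 5) and exposes a softmax policy
π_k ∝ exp(Σ_i R^π_{ki} s̄_{A,i}). The model receives (ξ, one-hot action) and
predicts the next world state and reward as linear readouts
ξ̂_k = Σ_i R^ξ_{ki} s̄_{M,i}, r̂ = Σ_i R^r_i s̄_{M,i}, trained to minimise

```
E^M = c_ξ Σ_{t,k} (ξ*_k − ξ̂_k)² + c_r Σ_t (r* − r̂)²,   c_ξ = 1.0, c_r = 0.1
```

via the three-factor rule Δw^M_{ij} ∝ [c_ξ Σ_k R^ξ_{ki} ε^ξ_k + c_r R^r_i ε^r]
p_i e_j. The policy follows a reward-gated discounted-eligibility rule
(γ = 0.99): per step, accumulators advance as G ← γG + δ_i p_i e_j and
H ← γH + (1_{a=k} − π_k) s̄_i, and the episode update is Σ_t r^t G^t (and
r^t H^t), applied with Adam (lr = 0.001).

## Quick start

The built-in environment is a limited-horizon (T = 100 frames) Pong-like
game on the unit square with D = 4 world coordinates (two paddle heights,
ball x, ball y) and three actions (up/stay/down). It is calibrated so that a
perfect agent scores exactly +1 per game and a worst-case agent concedes
exactly 2, bounding episode returns in [−2, +1].

```python
from spikedream import ExperimentConfig, NeuronParams, PhaseConfig, train

config = ExperimentConfig(
    neuron=NeuronParams(n=150),
    phase=PhaseConfig(dreams_per_game=1),   # one dream per real game
    n_games=300,
)
curves = train(config, seeds=[0, 1])        # DataFrame: game, reward, interactions, ...
```

Running `python examples/03_dreaming_vs_awake.py` (two seeds, 150 neurons)
prints:

```
awake+dream  interactions to reach mean reward >= 0: [19600.0, 16100.0]
awake+dream  mean reward over final 30 games:        ['+0.43', '-0.07']
awake only   interactions to reach mean reward >= 0: [inf, 17800.0]
awake only   mean reward over final 30 games:        ['-0.30', '-0.37']
```

i.e. with one dream per game both seeds reach break-even performance within
the budget and end with better play, while the pure policy-gradient baseline
reaches it in one seed only, later — dreamed experience substitutes for real
interactions. `examples/02_world_model_online.py` shows the world model
itself at work; on one seed the one-step prediction error falls from 0.156
to 0.035 (mean squared error on the 4 world coordinates) within 40 games,
with no stored trajectories. The other examples cover the spiking dynamics,
planning, and learning the world vector from raw 210×160 pixel frames
(random projection or a small autoencoder).

A thin CLI wraps the same entry point:

```bash
spikedream train --games 300 --seeds 0 1 2 --out runs/dream
spikedream train --no-dreaming --games 300 --seeds 0 1 2 --out runs/baseline
spikedream dream-only --games 300 --seeds 0 --out runs/fig2d
spikedream plan --n-fut 1 --games 300 --seeds 0 --out runs/planning
spikedream eval --checkpoint runs/dream/checkpoint_seed0.npz --neurons 500
```

Each run writes a learning-curve CSV, a JSON manifest (config hash, seeds,
version) and per-seed checkpoints.

## Layout

```
src/spikedream/
  lif.py         leaky integrate-and-fire dynamics, traces, surrogate gradient
  worldmodel.py  next-state/reward readouts and the local model learning rule
  policy.py      softmax policy and reward-gated discounted-eligibility rule
  phases.py      awake / dreaming / planning orchestration and train()
  pong.py        built-in environment, renderer, env adapter contract
  encoders.py    pixels -> world-vector encoders (projection, autoencoder)
  optim.py       Adam over named parameter arrays
  checkpoint.py  self-describing .npz checkpoints
  config.py      flat YAML configs with published defaults
  cli.py         train / dream-only / plan / eval subcommands
docs/methods.md  model, assumptions, parameter choices, limitations
examples/        one narrative script per capability
```
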