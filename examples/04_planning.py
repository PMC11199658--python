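"""Planning: short model-simulated look-aheads during awake play.

Every dt_pred = 2*n_fut real steps, the current world state seeds an
n_fut-step rollout inside the learned model; the policy gradient from the
simulated burst is applied and the network state is restored.  The
simulated-to-real data ratio is therefore 1/2 for any n_fut — the same
augmentation a 50-step dream per 100-step game provides.
"""

import numpy as np

from spikedream import (
    Agent,
    ExperimentConfig,
    NeuronParams,
    PhaseConfig,
    PongEnv,
    WorldModel,
    run_planning_episode,
    train,
)

neuron = NeuronParams(n=150)
agent = Agent(neuron, d_state=4, n_actions=3, seed=1)
model = WorldModel(neuron, d_state=4, n_actions=3, seed=2)
log = run_planning_episode(
    agent, model, PongEnv(), PhaseConfig(n_fut=1), np.random.default_rng(0)
)
print(f"one planning episode: {log.real_steps} real steps, "
      f"{log.sim_steps} simulated steps (ratio {log.sim_steps / log.real_steps:.2f})")

config = ExperimentConfig(
    neuron=neuron, phase=PhaseConfig(n_fut=1, dreams_per_game=0), n_games=150
)
curves = train(config, seeds=[0])
print(f"reward, first 30 games: {curves.head(30).reward.mean():+.2f}")
print(f"reward, last 30 games:  {curves.tail(30).reward.mean():+.2f}")
# Short look-aheads bound the compounding of one-step model errors, at the
# cost of simulating while the network is busy acting.
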