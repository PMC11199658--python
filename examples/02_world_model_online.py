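"""Learn a world model online from awake play, with no stored experience.

Runs 40 awake games on the built-in Pong-like task with a learning agent
and a learning model, and prints the model's one-step prediction error as
it improves.  Every update uses only quantities local in space and time —
no trajectory is ever stored.
"""

import numpy as np

from spikedream import ExperimentConfig, NeuronParams, PhaseConfig, train

config = ExperimentConfig(
    neuron=NeuronParams(n=150),
    phase=PhaseConfig(dreams_per_game=0),  # awake only: isolate model learning
    n_games=40,
)
curves = train(config, seeds=[0])

print("game  reward  one-step prediction MSE")
for _, row in curves.iloc[::5].iterrows():
    print(f"{int(row.game):4d}  {row.reward:+.0f}     {row.pred_mse:.4f}")

early = curves.head(5).pred_mse.mean()
late = curves.tail(5).pred_mse.mean()
print(f"\nmean MSE, first 5 games: {early:.4f}")
print(f"mean MSE, last 5 games:  {late:.4f}  ({late / early:.1%} of initial)")
# The MSE is the squared error between the model's predicted next world
# vector (paddles and ball coordinates) and what the environment produced.
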