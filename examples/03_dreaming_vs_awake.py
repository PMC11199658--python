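"""Dreaming boosts sample efficiency: one dream per game vs. none.

Trains two agents on the built-in limited-horizon Pong task.  The first
alternates one real game with one dreamed game (50 steps simulated by the
learned world model); the second learns from real games only (pure
policy-gradient baseline).  Learning curves are indexed by the number of
REAL environment interactions — dreamed steps are free.
"""

import numpy as np

from spikedream import ExperimentConfig, NeuronParams, PhaseConfig, train
from spikedream.phases import interactions_to_reach

seeds = [0, 1]
neuron = NeuronParams(n=150)

results = {}
for label, dreams in [("awake+dream", 1), ("awake only", 0)]:
    config = ExperimentConfig(
        neuron=neuron, phase=PhaseConfig(dreams_per_game=dreams), n_games=300
    )
    curves = train(config, seeds=seeds)
    reach = [
        interactions_to_reach(curves[curves.seed == s], threshold=0.0, window=20)
        for s in seeds
    ]
    final = [curves[curves.seed == s].tail(30).reward.mean() for s in seeds]
    results[label] = (reach, final)
    print(f"{label:12s} interactions to reach mean reward >= 0: {reach}")
    print(f"{label:12s} mean reward over final 30 games:        "
          f"{[f'{x:+.2f}' for x in final]}")

# Rewards per game lie in [-2, +1]: -1 per ball the agent misses, +1 when
# the slow opponent misses.  Fewer interactions-to-threshold with dreaming
# means the world model converted offline simulated play into real skill.
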