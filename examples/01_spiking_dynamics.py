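"""Simulate one recurrent LIF module and inspect its dynamics.

Builds a 100-neuron module, drives it with a frozen random world vector,
and prints population statistics: firing rate, trace ranges, and the
surrogate-gradient (pseudo-derivative) values that the learning rules use
in place of the non-differentiable spike threshold.
"""

import numpy as np

from spikedream import NeuronParams, pseudo_derivative
from spikedream.lif import SpikingModule

params = NeuronParams(n=100)
module = SpikingModule(params, d_state=4, seed=42)
rng = np.random.default_rng(0)
xi = rng.uniform(0, 1, size=4)  # a fixed world state, projected with scale sigma_in=5

spikes = []
for t in range(500):
    state = module.step(xi)
    spikes.append(state.s.copy())
spikes = np.array(spikes)

rate = spikes[100:].mean()  # discard the onset transient
print(f"population firing rate: {rate:.3f} spikes/step "
      f"({1000 * rate / params.dt:.0f} Hz at dt={params.dt} ms)")
print(f"fraction of neurons active: {(spikes.sum(axis=0) > 0).mean():.2f}")
print(f"fast trace  s_hat in [{state.s_hat.min():.3f}, {state.s_hat.max():.3f}]")
print(f"slow trace  s_bar in [{state.s_bar.min():.3f}, {state.s_bar.max():.3f}]")
print(f"eligibility e     in [{state.e.min():.3f}, {state.e.max():.3f}]")

p = pseudo_derivative(state.v, params.dv)
print(f"pseudo-derivative: max {p.max():.3f} (theoretical peak 1/(4*dv) = "
      f"{1 / (4 * params.dv):.3f} at threshold)")
# The filters of binary spike trains stay in [0,1]; the pseudo-derivative is
# largest for neurons hovering near threshold, which carry the gradient.
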