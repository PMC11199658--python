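# Methods

This note documents the model implemented by `spikedream`, the choices made
where the design was genuinely open, the synthetic task the package ships,
and what the included experiments do and do not show.

## Network dynamics

Both sub-networks (agent and world model) are recurrent leaky
integrate-and-fire modules simulated at a fixed step Δt = 1 ms, one
environment frame per network step. One step advances, in order: the binary
spike from the stored membrane potential (strict threshold crossing,
`v > v_th`; a membrane exactly at threshold does not fire), the fast
synaptic filter ŝ (τ_s), the membrane potential (leak toward `v_rest`,
recurrent drive through the one-step-lagged ŝ, external current, and a
fixed-amplitude reset `w_res·s^{t−1}`), the slow readout filter s̄ (τ\*),
and the per-presynaptic-neuron eligibility trace e (τ_m). The membrane and
fast filter use forward-Euler factors `(1 − Δt/τ)` while the readout and
eligibility filters use exponential factors `exp(−Δt/τ)`; the two agree to
O(Δt²) and each trace is implemented exactly as defined. A vectorised step
is verified against a scalar per-neuron reference to machine precision.

Because the reset acts one step after the spike, a tonically driven neuron
fires in doublets (the membrane is still suprathreshold on the step after a
spike); this is a property of the printed update order, preserved as such.

Default parameters (all exposed in the flat config):

| parameter | value | meaning |
|---|---|---|
| N | 500 (200 in desk-scale experiments) | neurons per module |
| Δt | 1 ms | integration step = one frame |
| τ_m, τ_s, τ\* | 20, 2, 10 ms | membrane, synaptic, readout filters |
| v_th, v_rest, w_res | 0, −4, 20 | threshold, rest, reset amplitude |
| σ (input projections) | 5 | scale of the frozen Gaussian input weights |
| σ_rec | 1 (std σ_rec/√N) | recurrent initialisation scale |
| δv | 1 | surrogate-gradient width |
| γ | 0.99 | reward discount |
| c_ξ, c_r | 1.0, 0.1 | state/reward loss weights |
| lr | 0.001 | Adam learning rate (all trainable arrays) |

Open values fixed here: Δt = 1 ms (simplest frame↔step mapping given the
millisecond time constants); δv = 1 (order of the rest-to-threshold gap;
the surrogate peak 1/(4δv) then equals 0.25); recurrent weights initialised
zero-mean Gaussian with std σ_rec/√N so the recurrent drive is O(1);
readout matrices (R^π, R^ξ, R^r) start at zero, so policies start uniform,
predictions start at zero, and the recurrent learning signal (which is
routed through the readout weights) switches on as the readouts train.

The eligibility trace is driven by the *presynaptic* filtered spike ŝ_j —
one trace per presynaptic neuron — which is the dimensionally consistent
reading of the spike-response recursion (e_j approximates ∂v_i/∂w_ij, and
v_i is driven by ŝ_j).

## Learning rules and their application

**World model.** The model module is driven by the current world vector and
the agent's one-hot action and predicts the next world vector and reward
linearly from s̄. The readout updates are the exact gradient of the
quadratic prediction loss (up to the constant factor absorbed into the
learning rate; the update pairs the output-indexed error with the
neuron-indexed activity). The recurrent update is a three-factor rule:
readout-weighted error × surrogate derivative (post) × eligibility trace
(pre). Each time step's term is itself the exact gradient of that step's
squared error, so the model applies one Adam update **per step** — standard
online stochastic gradient descent, and the sense in which training needs no
stored experience.

**Policy.** The policy rule gates two γ-discounted eligibility accumulators
(G for the recurrent weights, H for the readout) with the instantaneous
reward. An individual step's contribution `r^t·G^t` is not by itself an
unbiased gradient estimate — only the episode sum `Σ_t r^t G^t` is a
policy-gradient (REINFORCE-style) estimator. Since Adam is scale-invariant,
applying it to each per-step term would renormalise every contribution to
roughly learning-rate magnitude, erasing the relative weighting between
steps and amplifying small rewards into full-size parameter noise (this
visibly destabilised learning driven by weak model-predicted rewards). The
policy gradient is therefore accumulated across each episode — awake game,
dream, or planning burst — and applied with **one Adam step at the episode
boundary**. The traces themselves are still maintained strictly online, one
cheap local update per step. Both accumulation orders are verified against
direct evaluation of the nested discounted sums on frozen traces.

No baseline subtraction and no entropy regularisation are used. Rewards
enter the policy rule as instantaneous r^t gating the internally discounted
traces; the discounted return R^t is provided as a utility but is not part
of the update.

**Optimisation.** All trainable arrays (w^A, R^π, w^M, R^ξ, R^r) use Adam
with default moments (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) and lr = 0.001.
Updates are written in the "error × trace" (ascent) convention and Adam adds
them. The inner loops exploit the three structural gradient forms (dense,
rank-1 outer product, exact zero) with fused kernels; all three are tested
to agree with the dense reference path.

## Phases

* **Awake** (horizon 100 steps): closed loop with the environment; both
  modules learn online; every step increments the real-interaction counter
  that indexes all learning curves.
* **Dreaming** (horizon 50 steps): the model replaces the environment; the
  initial world vector is drawn uniformly from the environment's valid
  coordinate box; states and rewards are the model's closed-loop
  predictions; only the policy learns. Predicted rewards are used raw by
  default (a config flag clips them to [−1, 1]). A dream whose predicted
  state leaves the box by more than 10× its width aborts with a warning and
  a partial log. The default schedule alternates one real game with one
  dream.
* **Planning**: during awake play, every `Δt_pred = 2·n_fut` real steps the
  current real state seeds an `n_fut`-step model rollout; the burst's policy
  gradient is applied at its end, and the dynamic state of both modules
  (membranes, filters, eligibility traces, pending awake gradient) is
  snapshotted and restored around the burst, so only the weights carry its
  effect. The simulated-to-real data ratio is 1/2 for any `n_fut`, matching
  the 50-dream-steps-per-100-real-steps ratio of dreaming. Real-step
  learning (policy and model) proceeds as in the awake phase.

Dynamic state is reset at every phase boundary: games are independent.
Dreams and planning bursts never advance the interaction counter.

## The built-in task

The environment is the package's own miniature stand-in for a
limited-horizon Atari-Pong-style game: a unit square, the agent's paddle on
the right, a slow ball-tracking opponent on the left, three actions
(up/stay/down), ξ = (agent paddle y, opponent paddle y, ball x, ball y) ∈
[0,1]⁴, reward ±1 when a side misses. Kinematics (ball speed 1/60 per frame
horizontally, 0.005 vertically; paddle speeds 0.02 and 0.002; paddle
half-height 0.1; serve delays 5/10 frames; serves from the centre with the
arrival point at y = 0.65, away from the paddle start) are calibrated so
that over the 100-frame horizon a perfect tracking agent scores exactly +1
(opponent miss at frame 95) and a stationary agent concedes exactly 2
(misses at frames 35 and 75, the third arrival falling beyond the horizon).
Episode returns are therefore bounded in [−2, +1], and an untrained
(uniform-policy) agent averages ≈ −0.9, leaving headroom in both
directions. The calibration is asserted in tests, and the two scripted
returns are the quantities `scripts/acceptance.py` recomputes.

What the synthetic task does *not* emulate: frame-skip and sticky actions,
pixel noise, a reactive opponent, serve variability (serves are
deterministic, so the task rewards reliable positioning more than general
tracking), and long-horizon credit assignment beyond ~100 steps. Passing
the included experiments shows the learning machinery works end-to-end at
desk scale; it does not certify performance on real Atari environments.

Pixel observations are available through a deterministic binary renderer
(210×160 by default, 33,600 pixels; reduced shapes supported) with two
encoders: a frozen Gaussian random projection (zero mean, variance 0.1 per
weight) and a feed-forward autoencoder (full-scale layout
33600-128-64-36-64-128-33600, fit on random-policy frames with
scikit-learn's multilayer-perceptron regressor; the encoder half defines
the latent world space, the decoder is kept only for reconstruction
checks).

## Desk-scale experiments

The end-to-end comparisons in `tests/test_acceptance.py` use 200 neurons
per module, 300 games, seeds {0..4} — sizes chosen so the full suite runs
on a single CPU in minutes while leaving the published protocol otherwise
intact (the original experiments use 500 neurons and thousands of games).
Under these conditions:

* world-model one-step prediction error falls to ≈ 0.3× its initial level
  by games 190–200 in every seed;
* one dream per game roughly halves the median number of real interactions
  needed to reach break-even play (≈ 10,000 vs ≈ 17,000);
* planning with `n_fut = 1` and dreaming reach statistically comparable
  final performance (difference of medians well inside the seed IQR);
* freezing the model mid-training leaves its weights bit-identical
  thereafter (ablation mechanism for the model-staleness experiment).

## Known limitations

* **Dream-only policy learning saturates at this scale.** With the policy
  gradient active only during dreams, all seeds improve substantially
  (final-50-game mean reward rises from ≈ −1.9 to ≈ −0.9, with winning
  games appearing) but plateau below break-even: the median game still
  loses, and doubling the game budget does not change this. Purely
  model-mediated reward appears insufficient, at 200 neurons, to push the
  policy past saturation; the corresponding published experiment uses the
  full-size network and a far longer run. The test encoding this protocol
  is kept at the shared desk-scale conditions and currently fails, by
  design rather than be weakened.
* One-step model errors compound over the 50-step dreams; divergence is
  guarded, not prevented. Dream initial states are drawn from the whole
  coordinate box, including states the real dynamics cannot reach, so part
  of each dream trains the policy on off-manifold experience.
* The world model is deterministic and point-estimating: no transition
  noise, ensembles, or uncertainty; predicted rewards are smoothed versions
  of the sparse ±1 impulses.
* No synaptic delays, Dale's law, or conductance-based dynamics; the reset
  is a fixed-amplitude subtraction.
* Checkpoints store weights, readouts and optimizer moments, not RNG
  streams; training resumed from a checkpoint is statistically, not
  bitwise, continuous.
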