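"""World vectors from raw pixels: random projection and autoencoder.

Instead of reading the 4 game coordinates directly, the world state can be
defined from binary frames: either a frozen Gaussian random projection of
all pixels, or the bottleneck of a small feed-forward autoencoder trained
on random-policy frames (the decoder is kept only to inspect
reconstructions).  Both define a low-dimensional latent space the world
model can learn in.
"""

import dataclasses

import numpy as np

from spikedream import PongEnv, render_frame
from spikedream.encoders import (
    AutoencoderSpec,
    PixelEncoderSpec,
    RandomProjectionEncoder,
    train_autoencoder,
)

env = PongEnv()
env.reset()
full = render_frame(env.state)  # 210 x 160 binary frame
print(f"full frame: {full.shape[0]}x{full.shape[1]} = {full.size} pixels, "
      f"{int(full.sum())} lit")

proj = RandomProjectionEncoder(PixelEncoderSpec(n_pixels=full.size, d=4), seed=0)
print(f"random projection of the frame: xi = {np.round(proj.encode(full), 3)}")

# reduced-resolution frames keep the autoencoder demonstration quick
rng = np.random.default_rng(0)
frames = []
for _ in range(300):
    env.step(int(rng.integers(3)))
    frames.append(render_frame(env.state, shape=(52, 40)))
frames = np.array(frames, dtype=float)

spec = AutoencoderSpec(input_size=52 * 40, hidden=(64, 32), latent=8, max_iter=20)
near_init = train_autoencoder(frames[:270], dataclasses.replace(spec, max_iter=1), seed=0)
trained = train_autoencoder(frames[:270], spec, seed=0)
held = frames[270:]
print(f"autoencoder latent dimension: {trained.latent_dim}")
print(f"held-out reconstruction MSE, near-initialization: {near_init.reconstruction_mse(held):.4f}")
print(f"held-out reconstruction MSE, trained:             {trained.reconstruction_mse(held):.4f}")
# At full scale the published layout is 33600-128-64-36-64-128-33600 with a
# 36-dimensional latent, trained on 10,000 random-policy frames.
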