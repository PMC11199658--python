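"""Observation encoders: pixels → low-dimensional world state.

Two ways to obtain the world vector ξ from raw binary frames instead of the
environment's coordinate readout:

* a frozen **random projection** — ξ_k = Σ_h F_kh x_h with Gaussian weights
  of zero mean and variance 0.1 over all pixels (33,600 at the full
  160 × 210 frame size);
* a small feed-forward **autoencoder** whose bottleneck defines the latent
  world space (full-scale layout 33600-128-64-36-64-128-33600, trained on
  10,000 random-policy frames).  The decoder half is kept only for
  reconstruction checks and visual inspection of dreamed frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

__all__ = [
    "PixelEncoderSpec",
    "RandomProjectionEncoder",
    "AutoencoderSpec",
    "PixelAutoencoder",
    "train_autoencoder",
]


@dataclass(frozen=True)
class PixelEncoderSpec:
    """Random-projection encoder specification.

    ``variance`` is the per-weight variance of the Gaussian entries of the
    D × n_pixels projection matrix (default 0.1).
    """

    n_pixels: int = 160 * 210
    d: int = 4
    variance: float = 0.1


class RandomProjectionEncoder:
    """Frozen Gaussian projection of a flattened binary frame onto R^D."""

    def __init__(self, spec: PixelEncoderSpec | None = None, seed: int = 0) -> None:
        self.spec = spec or PixelEncoderSpec()
        rng = np.random.default_rng(seed)
        self.f = rng.normal(
            0.0, np.sqrt(self.spec.variance), size=(self.spec.d, self.spec.n_pixels)
        )

    def encode(self, frame: np.ndarray) -> np.ndarray:
        flat = np.asarray(frame, dtype=float).reshape(-1)
        if flat.shape[0] != self.spec.n_pixels:
            raise ValueError(
                f"frame has {flat.shape[0]} pixels, encoder expects {self.spec.n_pixels}"
            )
        return self.f @ flat

    __call__ = encode


@dataclass(frozen=True)
class AutoencoderSpec:
    """Feed-forward autoencoder layout and training budget.

    Full-scale defaults mirror the 33600-128-64-36-64-128-33600 layout; for
    fast experiments pass a reduced ``input_size`` (e.g. 52 × 40 frames).
    """

    input_size: int = 160 * 210
    hidden: tuple[int, int] = (128, 64)
    latent: int = 36
    max_iter: int = 200
    learning_rate: float = 1e-3

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (
            self.input_size,
            *self.hidden,
            self.latent,
            *reversed(self.hidden),
            self.input_size,
        )


class PixelAutoencoder:
    """Trained encoder/decoder pair; ``encode`` maps frames to the latent."""

    def __init__(self, spec: AutoencoderSpec, mlp: MLPRegressor) -> None:
        self.spec = spec
        self._mlp = mlp
        n_enc = len(spec.hidden) + 1  # hidden layers up to and including the bottleneck
        self._enc_w = mlp.coefs_[:n_enc]
        self._enc_b = mlp.intercepts_[:n_enc]

    @property
    def latent_dim(self) -> int:
        return self.spec.latent

    def encode(self, frame: np.ndarray) -> np.ndarray:
        x = np.asarray(frame, dtype=float).reshape(-1)
        if x.shape[0] != self.spec.input_size:
            raise ValueError(
                f"frame has {x.shape[0]} pixels, autoencoder expects {self.spec.input_size}"
            )
        for w, b in zip(self._enc_w, self._enc_b):
            x = np.maximum(x @ w + b, 0.0)
        return x

    __call__ = encode

    def reconstruct(self, frame: np.ndarray) -> np.ndarray:
        """Full forward pass; used only for reconstruction checks/plots."""
        x = np.asarray(frame, dtype=float).reshape(1, -1)
        return self._mlp.predict(x)[0]

    def reconstruction_mse(self, frames: np.ndarray) -> float:
        x = np.asarray(frames, dtype=float).reshape(len(frames), -1)
        return float(np.mean((self._mlp.predict(x) - x) ** 2))


def train_autoencoder(
    frames: np.ndarray, spec: AutoencoderSpec, seed: int = 0
) -> PixelAutoencoder:
    """Fit the autoencoder on a corpus of frames (frames → frames).

    ``frames`` is (n_samples, …) and is flattened per sample.  A corpus of
    identical frames is degenerate (nothing to encode) and triggers a
    warning.  Same seed and corpus give identical parameters.
    """
    x = np.asarray(frames, dtype=float).reshape(len(frames), -1)
    if x.shape[0] < 2:
        raise ValueError("autoencoder training needs at least 2 frames")
    if x.shape[1] != spec.input_size:
        raise ValueError(
            f"frames have {x.shape[1]} pixels, spec expects {spec.input_size}"
        )
    if np.all(x == x[0]):
        warnings.warn(
            "autoencoder corpus is degenerate: all frames identical",
            UserWarning,
            stacklevel=2,
        )
    hidden_layers = (*spec.hidden, spec.latent, *reversed(spec.hidden))
    mlp = MLPRegressor(
        hidden_layer_sizes=hidden_layers,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.max_iter,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=spec.max_iter,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit(x, x)
    return PixelAutoencoder(spec, mlp)
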