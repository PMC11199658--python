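"""Adaptive-moment (Adam) updates for the online plasticity rules.

Every trainable array (recurrent matrices and linear readouts) gets its own
moment accumulators.  The plasticity rules of this package are written in
the "Δ ∝ error × trace" convention — the direction that decreases the model
loss or increases the expected return — so :meth:`Adam.step` *adds*
``lr · m̂ / (√v̂ + ε)`` to the parameter.  Defaults are the standard
β₁ = 0.9, β₂ = 0.999, ε = 1e-8 with learning rate 0.001.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = ["Adam"]


class Adam:
    """Adaptive-moment estimator for one named set of parameter arrays."""

    def __init__(
        self,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr < 0:
            raise ValueError(f"learning rate must be >= 0, got {lr}")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict) -> None:
        """Apply one bias-corrected moment update, in place, to each array.

        ``grads`` holds the update directions; parameters move *along* them.
        A gradient may be given as a dense array, as ``None`` for an exact
        zero (only the moment decay acts), or as an ``(a, b)`` pair denoting
        the rank-1 outer product ``a ⊗ b`` — the three forms the local
        plasticity rules produce.  Arrays first seen here get
        zero-initialised moments of their shape.
        """
        self.t += 1
        args = (
            self.lr,
            self.beta1,
            self.beta2,
            self.eps,
            1.0 - self.beta1**self.t,
            1.0 - self.beta2**self.t,
        )
        for name, g in grads.items():
            p = params[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            m, v = self.m[name], self.v[name]
            if g is None:
                _kernels.adam_zero(p, m, v, *args)
            elif isinstance(g, tuple):
                a, b = g
                if p.ndim != 2 or (a.shape[0], b.shape[0]) != p.shape:
                    raise ValueError(
                        f"rank-1 gradient factors {a.shape} x {b.shape} do not "
                        f"match parameter '{name}' shape {p.shape}"
                    )
                _kernels.adam_rank1(p, a, b, m, v, *args)
            else:
                if g.shape != p.shape:
                    raise ValueError(
                        f"gradient shape {g.shape} does not match parameter "
                        f"'{name}' shape {p.shape}"
                    )
                _kernels.adam_dense(p, g, m, v, *args)

    def state_dict(self) -> dict[str, np.ndarray | int | float]:
        out: dict[str, np.ndarray | int | float] = {"t": self.t, "lr": self.lr}
        for name, arr in self.m.items():
            out[f"m.{name}"] = arr
        for name, arr in self.v.items():
            out[f"v.{name}"] = arr
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = {k[2:]: np.array(v) for k, v in state.items() if k.startswith("m.")}
        self.v = {k[2:]: np.array(v) for k, v in state.items() if k.startswith("v.")}
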