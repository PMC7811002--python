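"""Per-element feed-forward networks: input -> tanh(15) -> tanh(15) -> linear(1).

Everything here is plain numpy with analytic derivatives:

* ``forward`` / ``forward_batch``      y(x)
* ``gradients``                        dy/dx and dy/dtheta
* ``input_grad_batch``                 dy/dx for a batch
* ``param_grad_weighted``              sum_b w_b dy_b/dtheta
* ``mixed_param_grad``                 d(c . dy/dx)/dtheta   (force-loss term)

Parameters live in a flat vector with layout
[W1.ravel, b1, W2.ravel, b2, w3, b3] so optimizers are network-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParams",
    "init_network",
    "forward",
    "gradients",
    "forward_batch",
    "hidden_cache",
    "input_grad_batch",
    "param_grad_weighted",
    "mixed_param_grad",
]


@dataclass
class NetworkParams:
    """Weights/biases of one atomic network (two tanh hidden layers, linear out)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: float

    def __post_init__(self):
        for arr in (self.W1, self.b1, self.W2, self.b2, self.w3):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")
        if not np.isfinite(self.b3):
            raise ValueError("network parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (self.W1.shape[1], self.W1.shape[0], self.W2.shape[0], 1)

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size + self.w3.size + 1

    def to_flat(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2, self.w3, [self.b3]]
        )

    @classmethod
    def from_flat(cls, flat: np.ndarray, layer_sizes) -> "NetworkParams":
        n, h1, h2, _ = layer_sizes
        c = 0
        W1 = flat[c : c + h1 * n].reshape(h1, n); c += h1 * n
        b1 = flat[c : c + h1]; c += h1
        W2 = flat[c : c + h2 * h1].reshape(h2, h1); c += h2 * h1
        b2 = flat[c : c + h2]; c += h2
        w3 = flat[c : c + h2]; c += h2
        b3 = float(flat[c]); c += 1
        assert c == len(flat)
        return cls(W1.copy(), b1.copy(), W2.copy(), b2.copy(), w3.copy(), b3)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.w3.copy(), self.b3,
        )


def init_network(n_inputs: int, seed: int, hidden: tuple[int, int] = (15, 15)) -> NetworkParams:
    """Scaled-uniform init (bound 1/sqrt(fan_in)), zero biases, seed-deterministic."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    h1, h2 = hidden
    def u(fan_in, shape):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)
    return NetworkParams(
        W1=u(n_inputs, (h1, n_inputs)),
        b1=np.zeros(h1),
        W2=u(h1, (h2, h1)),
        b2=np.zeros(h2),
        w3=u(h2, h2),
        b3=0.0,
    )


def forward(params: NetworkParams, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_inputs,):
        raise ValueError(f"expected input of length {params.n_inputs}, got {x.shape}")
    h1 = np.tanh(params.W1 @ x + params.b1)
    h2 = np.tanh(params.W2 @ h1 + params.b2)
    return float(params.w3 @ h2 + params.b3)


def gradients(params: NetworkParams, x: np.ndarray):
    """(dy/dx, dy/dtheta-flat), both analytic."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_inputs,):
        raise ValueError(f"expected input of length {params.n_inputs}, got {x.shape}")
    h1 = np.tanh(params.W1 @ x + params.b1)
    t1 = 1.0 - h1**2
    h2 = np.tanh(params.W2 @ h1 + params.b2)
    t2 = 1.0 - h2**2
    d2 = t2 * params.w3                       # dy/da2
    d1 = t1 * (params.W2.T @ d2)              # dy/da1
    dydx = params.W1.T @ d1
    dtheta = np.concatenate(
        [np.outer(d1, x).ravel(), d1, np.outer(d2, h1).ravel(), d2, h2, [1.0]]
    )
    return dydx, dtheta


# ---------------------------------------------------------------------------
# batched evaluation (X has shape (B, n_inputs))
# ---------------------------------------------------------------------------

def _hidden(params: NetworkParams, X: np.ndarray):
    H1 = np.tanh(X @ params.W1.T + params.b1)
    H2 = np.tanh(H1 @ params.W2.T + params.b2)
    return H1, H2


def forward_batch(params: NetworkParams, X: np.ndarray, cache=None) -> np.ndarray:
    """Batched evaluation; pass ``cache`` (from ``hidden_cache``) to reuse
    the tanh activations across the gradient routines below."""
    H1, H2 = cache if cache is not None else _hidden(params, X)
    return H2 @ params.w3 + params.b3


def hidden_cache(params: NetworkParams, X: np.ndarray):
    """Activations (H1, H2) reusable by every batched routine for this X."""
    return _hidden(params, X)


def input_grad_batch(params: NetworkParams, X: np.ndarray, cache=None) -> np.ndarray:
    """(B, n_inputs) array of dy/dx."""
    H1, H2 = cache if cache is not None else _hidden(params, X)
    D2 = (1.0 - H2**2) * params.w3
    D1 = (1.0 - H1**2) * (D2 @ params.W2)
    return D1 @ params.W1


def param_grad_weighted(params: NetworkParams, X: np.ndarray, w: np.ndarray,
                        cache=None) -> np.ndarray:
    """Flat gradient of sum_b w_b y(x_b) with respect to the parameters."""
    H1, H2 = cache if cache is not None else _hidden(params, X)
    D2 = (1.0 - H2**2) * params.w3            # (B, h2)
    D1 = (1.0 - H1**2) * (D2 @ params.W2)     # (B, h1)
    wD1 = D1 * w[:, None]
    wD2 = D2 * w[:, None]
    gW1 = wD1.T @ X
    gb1 = wD1.sum(axis=0)
    gW2 = wD2.T @ H1
    gb2 = wD2.sum(axis=0)
    gw3 = (H2 * w[:, None]).sum(axis=0)
    gb3 = float(w.sum())
    return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2, gw3, [gb3]])


def mixed_param_grad(params: NetworkParams, X: np.ndarray, C: np.ndarray,
                     cache=None) -> np.ndarray:
    """Flat gradient of s = sum_b c_b . (dy/dx)(x_b) with respect to theta.

    C has shape (B, n_inputs).  This is the second-derivative contraction that
    the force loss needs (forward-over-reverse, fully closed form).
    """
    W1, W2, w3 = params.W1, params.W2, params.w3
    H1, H2 = cache if cache is not None else _hidden(params, X)
    T1 = 1.0 - H1**2
    T2 = 1.0 - H2**2
    D2 = T2 * w3                              # (B, h2)
    M = D2 @ W2                               # (B, h1): W2^T d2
    U = C @ W1.T                              # (B, h1): u = W1 c
    Q = U * T1                                # (B, h1)
    R = Q @ W2.T                              # (B, h2): r = W2 q
    Z2 = -2.0 * H2 * D2 * R                   # (B, h2)
    Z1 = -2.0 * U * M * H1 * T1 + T1 * (Z2 @ W2)   # (B, h1)

    gw3 = (T2 * R).sum(axis=0)
    gb2 = Z2.sum(axis=0)
    gW2 = D2.T @ Q + Z2.T @ H1
    gb1 = Z1.sum(axis=0)
    gW1 = (T1 * M).T @ C + Z1.T @ X
    gb3 = 0.0
    return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2, gw3, [gb3]])
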