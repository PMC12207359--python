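"""Feed-forward feature extractors with manual backpropagation.

The extractor maps a reaction feature vector x to a latent embedding
z = f(x; w) consumed by the GP base kernel.  Weights live in a single
flat parameter vector so that optimisers, the Gaussian weight prior of
the ADKF-prior method, and checkpointing all operate on plain ndarrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPExtractor", "IdentityExtractor", "make_extractor"]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "relu": (lambda a: np.maximum(a, 0.0), lambda h: (h > 0).astype(float)),
}


class MLPExtractor:
    """Fully connected net, nonlinear hidden layers, linear output.

    Parameters
    ----------
    in_dim : input dimensionality.
    hidden_sizes : widths of the hidden layers.
    out_dim : latent dimensionality d of the embedding z.
    activation : 'tanh' (default; smooth, convenient for gradient
        checking) or 'relu'.
    """

    def __init__(self, in_dim: int, hidden_sizes=(256, 128), out_dim: int = 64,
                 activation: str = "tanh"):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.in_dim = int(in_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.out_dim = int(out_dim)
        self.activation = activation
        self._sizes = (self.in_dim, *self.hidden_sizes, self.out_dim)
        self._shapes = []
        for a, b in zip(self._sizes[:-1], self._sizes[1:]):
            self._shapes.append((a, b))   # weight
            self._shapes.append((b,))     # bias
        self.n_params = sum(int(np.prod(s)) for s in self._shapes)

    # -- parameter plumbing -------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        """Glorot-normal weights, zero biases, as one flat vector."""
        chunks = []
        for shape in self._shapes:
            if len(shape) == 2:
                fan_in, fan_out = shape
                scale = np.sqrt(2.0 / (fan_in + fan_out))
                chunks.append(rng.normal(0.0, scale, size=shape).ravel())
            else:
                chunks.append(np.zeros(shape))
        return np.concatenate(chunks)

    def unpack(self, w: np.ndarray):
        w = np.asarray(w, dtype=float).ravel()
        if w.shape[0] != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {w.shape[0]}")
        out, i = [], 0
        for shape in self._shapes:
            size = int(np.prod(shape))
            out.append(w[i:i + size].reshape(shape))
            i += size
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        return self.forward_with_cache(w, X)[0]

    def forward_with_cache(self, w: np.ndarray, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input to extractor")
        act, _ = _ACTIVATIONS[self.activation]
        layers = self.unpack(w)
        h = X
        hiddens = [h]
        n_layers = len(self._sizes) - 1
        for li in range(n_layers):
            W, b = layers[2 * li], layers[2 * li + 1]
            a = h @ W + b
            h = a if li == n_layers - 1 else act(a)
            hiddens.append(h)
        return h, (layers, hiddens)

    def backward(self, cache, dZ: np.ndarray):
        """Given dL/dZ, return (dL/dw flat, dL/dX)."""
        layers, hiddens = cache
        _, dact = _ACTIVATIONS[self.activation]
        n_layers = len(self._sizes) - 1
        grads = [None] * len(layers)
        delta = np.asarray(dZ, dtype=float)
        for li in range(n_layers - 1, -1, -1):
            W = layers[2 * li]
            h_in, h_out = hiddens[li], hiddens[li + 1]
            if li != n_layers - 1:
                delta = delta * dact(h_out)
            grads[2 * li] = h_in.T @ delta
            grads[2 * li + 1] = delta.sum(axis=0)
            delta = delta @ W.T
        dw = np.concatenate([g.ravel() for g in grads])
        return dw, delta


class IdentityExtractor:
    """Pass-through embedding (z = x); zero trainable parameters."""

    def __init__(self, in_dim: int):
        self.in_dim = int(in_dim)
        self.out_dim = int(in_dim)
        self.n_params = 0

    def init_params(self, rng=None) -> np.ndarray:
        return np.zeros(0)

    def forward(self, w, X):
        return np.atleast_2d(np.asarray(X, dtype=float))

    def forward_with_cache(self, w, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X, None

    def backward(self, cache, dZ):
        return np.zeros(0), np.asarray(dZ, dtype=float)


def make_extractor(name: str, in_dim: int, hidden_sizes=(256, 128),
                   out_dim: int = 64, activation: str = "tanh"):
    """Factory used by the estimators; ``name`` is 'mlp' or 'identity'."""
    if name == "identity":
        return IdentityExtractor(in_dim)
    if name == "mlp":
        return MLPExtractor(in_dim, hidden_sizes=hidden_sizes,
                            out_dim=out_dim, activation=activation)
    raise ValueError(f"unknown extractor {name!r}")
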