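"""The feature extractor G: a fully connected net mapping cells to latent space.

The encoder maps a v-dimensional expression profile to a d-dimensional
embedding z = G(x) with d << v.  Default architecture: two ReLU hidden
layers of 1024 and 256 units and a linear 100-unit output, no projection
head, no batch-norm or dropout.  Implemented directly on numpy arrays with
analytic backpropagation; the training loops in :mod:`crossclust.pretrain`
and :mod:`crossclust.clustering` drive it through :class:`Adam`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["EncoderConfig", "Encoder", "Adam", "Embedding"]


@dataclass
class EncoderConfig:
    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [1024, 256])
    latent_dim: int = 100
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        dims = [self.input_dim, *self.hidden_dims, self.latent_dim]
        if any(d < 1 for d in dims):
            raise ValueError("all layer dimensions must be >= 1")
        if self.latent_dim >= self.input_dim:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be smaller than "
                f"input_dim ({self.input_dim})"
            )
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__)

    @classmethod
    def from_yaml(cls, text: str) -> "EncoderConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class Embedding:
    """Latent vectors (m x d) with provenance back to (domain_id, row)."""

    vectors: np.ndarray
    source_rows: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise FloatingPointError("non-finite embedding values")


class Encoder:
    """Deterministically initialized MLP with explicit forward/backward.

    Parameters live in ``self.params`` as ``W0, b0, W1, b1, ...``; He
    initialization under ``config.seed``.  ``forward`` optionally returns a
    cache consumed by ``backward`` to produce parameter gradients and the
    gradient with respect to the input.
    """

    def __init__(self, config: EncoderConfig):
        self.config = config
        dims = [config.input_dim, *config.hidden_dims, config.latent_dim]
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))
            self.params[f"b{i}"] = np.zeros(dout)
        self.n_layers = len(dims) - 1

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray, return_cache: bool = False):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (m, {self.config.input_dim}) input, got {X.shape}"
            )
        hs = [X]
        h = X
        for i in range(self.n_layers):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                h = np.maximum(h, 0.0)
            hs.append(h)
        if return_cache:
            return h, hs
        return h

    def backward(self, cache: list[np.ndarray], dZ: np.ndarray):
        """Backprop ``dZ = dL/dz`` through the cached forward pass.

        Returns ``(grads, dX)`` where ``grads`` maps parameter names to
        gradients and ``dX`` is the loss gradient at the input.
        """
        grads: dict[str, np.ndarray] = {}
        delta = np.asarray(dZ, dtype=np.float64)
        for i in range(self.n_layers - 1, -1, -1):
            h_in = cache[i]
            if i < self.n_layers - 1:
                # cache[i+1] stores post-ReLU activations of layer i
                delta = delta * (cache[i + 1] > 0)
            grads[f"W{i}"] = h_in.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            delta = delta @ self.params[f"W{i}"].T
        return grads, delta

    def embed(self, dataset, batch_size: int = 2048) -> Embedding:
        """Embed every cell of an :class:`~crossclust.data.ExpressionDataset`."""
        X = dataset.dense()
        out = np.empty((X.shape[0], self.config.latent_dim))
        for start in range(0, X.shape[0], batch_size):
            out[start : start + batch_size] = self.forward(X[start : start + batch_size])
        rows = [(dataset.domain_id, i) for i in range(X.shape[0])]
        return Embedding(out, rows)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, __config__=self.config.to_yaml(), **self.params)

    @classmethod
    def load(cls, path) -> "Encoder":
        with np.load(path, allow_pickle=False) as f:
            config = EncoderConfig.from_yaml(str(f["__config__"]))
            enc = cls(config)
            for k in enc.params:
                enc.params[k] = f[k]
        return enc

    def copy(self) -> "Encoder":
        enc = Encoder(self.config)
        enc.params = {k: v.copy() for k, v in self.params.items()}
        return enc


class Adam:
    """Adam optimizer over a dict of numpy parameter arrays (in-place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
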