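"""Stage 1: contrastive pre-training of the encoder on all cells.

Source and target cells are pooled and the encoder is trained with the
InfoNCE objective: each cell in a minibatch of N is paired with an
augmented view of itself (random zeroing of non-zero genes with
probability P), giving 2N views; the loss pulls each view toward its
partner and away from the other 2N-2 views.  Similarity is the plain dot
product of the (unnormalized, head-less) encoder outputs, with
temperature tau = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import Adam, Encoder

__all__ = [
    "AugmentationConfig",
    "augment_cell",
    "augment",
    "infonce_pair_loss",
    "infonce_batch",
    "pretrain_encoder",
]


@dataclass
class AugmentationConfig:
    zero_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")


def augment(X: np.ndarray, zero_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Dropout-style augmentation: zero each non-zero entry with prob P.

    Zeros in the input are never touched, so the augmented view differs
    from the original only on the original's support.
    """
    X = np.asarray(X, dtype=np.float64)
    mask = rng.random(X.shape) < zero_prob
    return np.where(mask & (X != 0), 0.0, X)


def augment_cell(x: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Augment a single v-dimensional cell (see :func:`augment`)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return augment(np.atleast_2d(x), config.zero_prob, rng)[0]


def infonce_pair_loss(i: int, j: int, all_z: np.ndarray, tau: float = 1.0) -> float:
    """InfoNCE loss of the ordered positive pair (i, j) within 2N views.

    ``-log exp(z_i.z_j / tau) / sum_{k != i} exp(z_i.z_k / tau)``; the
    denominator runs over every view except the anchor itself (the
    positive j is included).  Log-sum-exp guarded.
    """
    all_z = np.asarray(all_z, dtype=np.float64)
    if not np.all(np.isfinite(all_z)):
        raise FloatingPointError("non-finite embeddings in InfoNCE loss")
    if tau <= 0:
        raise ValueError("tau must be positive")
    sims = all_z @ all_z[i] / tau
    mask = np.ones(len(all_z), dtype=bool)
    mask[i] = False
    m = sims[mask].max()
    lse = m + np.log(np.exp(sims[mask] - m).sum())
    return float(lse - sims[j])


def infonce_batch(Z: np.ndarray, tau: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean InfoNCE loss over both orderings of all N positive pairs.

    ``Z`` stacks the N originals then their N augmented views, so the
    positive partner of row i is row (i + N) mod 2N.  Returns the scalar
    loss and its gradient with respect to ``Z``.
    """
    Z = np.asarray(Z, dtype=np.float64)
    two_n = Z.shape[0]
    if two_n % 2 or two_n < 4:
        raise ValueError("Z must stack N >= 2 originals and N augmented views")
    n = two_n // 2
    S = Z @ Z.T / tau
    np.fill_diagonal(S, -np.inf)  # k != i: the anchor never appears as negative
    m = S.max(axis=1, keepdims=True)
    expS = np.exp(S - m)
    denom = expS.sum(axis=1, keepdims=True)
    logp = S - (m + np.log(denom))  # log softmax over k != i
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    loss = -logp[np.arange(two_n), pos].mean()

    P = expS / denom
    P[np.arange(two_n), pos] -= 1.0
    D = P / two_n
    dZ = (D + D.T) @ Z / tau
    return float(loss), dZ


def pretrain_encoder(
    encoder: Encoder,
    datasets,
    batch_size: int = 256,
    epochs: int = 30,
    aug: AugmentationConfig | None = None,
    lr: float = 1e-3,
    tau: float = 1.0,
    seed: int = 0,
    stratify_by_domain: bool = False,
) -> tuple[Encoder, list[float]]:
    """Train the encoder with InfoNCE over the pooled source+target cells.

    Returns the encoder (updated in place) and the per-epoch mean loss
    trace.  ``epochs=0`` is a no-op.  Minibatches are drawn from a single
    pooled shuffle of all domains unless ``stratify_by_domain`` cycles the
    domains instead.
    """
    aug = aug or AugmentationConfig()
    X = np.vstack([ds.dense() for ds in datasets])
    if batch_size > X.shape[0]:
        raise ValueError(
            f"batch size {batch_size} exceeds total cell count {X.shape[0]}"
        )
    if batch_size < 2:
        raise ValueError("batch size must be >= 2")
    rng = np.random.default_rng(seed)
    opt = Adam(encoder.params, lr=lr)
    trace: list[float] = []
    if stratify_by_domain:
        domain_of = np.concatenate(
            [np.full(ds.n_cells, i) for i, ds in enumerate(datasets)]
        )
    for _ in range(epochs):
        order = rng.permutation(X.shape[0])
        if stratify_by_domain:
            order = order[np.argsort(domain_of[order], kind="stable")]
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue
            orig = X[idx]
            views = np.vstack([orig, augment(orig, aug.zero_prob, rng)])
            Z, cache = encoder.forward(views, return_cache=True)
            loss, dZ = infonce_batch(Z, tau=tau)
            grads, _ = encoder.backward(cache, dZ)
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return encoder, trace
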