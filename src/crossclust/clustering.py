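"""Stages 2-3: centroid initialization, alignment losses, fine-tuning, pruning.

Two paired sets of cluster representatives are maintained in latent
space: ``Cs`` (one centroid per unique cell type pooled over all
annotated source datasets) and ``Ct`` (the target-side counterparts,
initialized as an exact copy of ``Cs``).  Fine-tuning alternates between

* encoder updates on the cell-alignment losses — each source cell is
  pulled toward the centroid of its annotated type, each target cell
  toward its nearest target centroid — and
* centroid updates on the same losses plus the cluster-alignment loss,
  the mean row entropy of a masked softmax over pairwise centroid
  similarities ``1/(dist + eps)``; only cross-domain (source, target)
  pairs carry similarity, so matched centroids attract across domains
  while same-domain centroids repel, which also blocks the collapse of
  all representatives onto one point.

Target centroids that end up attracting no cells are pruned; the number
of survivors is the estimate of the number of clusters in the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import ExpressionDataset, LabelError
from .encoder import Adam, Encoder

__all__ = [
    "CentroidSet",
    "Assignment",
    "ClusterSimilarity",
    "TrainingError",
    "init_centroids",
    "assign_targets",
    "cell_alignment_loss_source",
    "cell_alignment_loss_target",
    "similarity_matrix",
    "cluster_alignment_loss",
    "total_loss",
    "finetune",
    "prune_and_estimate",
]

_TINY = 1e-12  # guards 0/0 in unit vectors of the distance gradient


class TrainingError(RuntimeError):
    """Raised when fine-tuning produces a non-finite loss."""


@dataclass
class CentroidSet:
    Cs: np.ndarray
    Ct: np.ndarray
    type_names: list[str]
    alive_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.Cs = np.asarray(self.Cs, dtype=np.float64)
        self.Ct = np.asarray(self.Ct, dtype=np.float64)
        if self.Cs.shape != self.Ct.shape or self.Cs.shape[0] != len(self.type_names):
            raise ValueError("Cs, Ct and type_names must agree on n")
        if self.alive_mask is None:
            self.alive_mask = np.ones(self.n, dtype=bool)

    @property
    def n(self) -> int:
        return self.Cs.shape[0]

    def type_index(self, labels) -> np.ndarray:
        lookup = {t: k for k, t in enumerate(self.type_names)}
        try:
            return np.asarray([lookup[str(l).strip()] for l in labels], dtype=int)
        except KeyError as exc:
            raise LabelError(f"unknown cell-type label {exc.args[0]!r}") from None


@dataclass
class Assignment:
    nearest: np.ndarray

    def __post_init__(self) -> None:
        self.nearest = np.asarray(self.nearest, dtype=int)

    def member_sets(self, n: int) -> list[np.ndarray]:
        return [np.flatnonzero(self.nearest == k) for k in range(n)]

    def counts(self, n: int) -> np.ndarray:
        return np.bincount(self.nearest, minlength=n)


@dataclass
class ClusterSimilarity:
    F: np.ndarray
    P: np.ndarray
    sim: np.ndarray
    cross_mask: np.ndarray
    epsilon: float
    tau_c: float


def init_centroids(encoder: Encoder, sources: list[ExpressionDataset]) -> CentroidSet:
    """Mean latent embedding per cell type, pooled across all sources.

    ``Ct`` starts as an exact copy of ``Cs``; type names are sorted
    lexicographically so the centroid order is reproducible.
    """
    if not sources or not all(ds.is_source for ds in sources):
        raise ValueError("init_centroids needs annotated source datasets")
    type_names = sorted({l for ds in sources for l in ds.labels})
    d = encoder.config.latent_dim
    sums = np.zeros((len(type_names), d))
    counts = np.zeros(len(type_names))
    lookup = {t: k for k, t in enumerate(type_names)}
    for ds in sources:
        Z = encoder.embed(ds).vectors
        idx = np.asarray([lookup[l] for l in ds.labels])
        np.add.at(sums, idx, Z)
        counts += np.bincount(idx, minlength=len(type_names))
    Cs = sums / counts[:, None]
    if not np.all(np.isfinite(Cs)):
        raise FloatingPointError("non-finite centroid after initialization")
    return CentroidSet(Cs, Cs.copy(), type_names)


def nearest_centroids(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Index of the closest centroid per row (Euclidean, ties -> lowest index)."""
    return np.argmin(cdist(Z, C), axis=1)


def assign_targets(
    encoder: Encoder,
    target: ExpressionDataset,
    centroids: CentroidSet,
    alive_only: bool = False,
) -> Assignment:
    """Assign every target cell to its nearest target centroid."""
    Z = encoder.embed(target).vectors
    if alive_only:
        alive = np.flatnonzero(centroids.alive_mask)
        return Assignment(alive[nearest_centroids(Z, centroids.Ct[alive])])
    return Assignment(nearest_centroids(Z, centroids.Ct))


# ---------------------------------------------------------------------------
# losses (public scalar surface + internal gradient helpers)
# ---------------------------------------------------------------------------

def _centroid_pull(Z, C, idx, inv_count, scale):
    """Loss and gradients of scale * sum_k inv_count[k] * sum_{i in k} ||z_i - C_k||."""
    diff = Z - C[idx]
    dist = np.linalg.norm(diff, axis=1)
    w = scale * inv_count[idx]
    loss = float(np.sum(w * dist))
    unit = diff / np.maximum(dist, _TINY)[:, None]
    dZ = w[:, None] * unit
    dC = np.zeros_like(C)
    np.add.at(dC, idx, -dZ)
    return loss, dZ, dC


def _per_type_weights(idx: np.ndarray, n: int, n_sources: int) -> np.ndarray:
    """inv_count[k] = 1/((|S|+1) * K * count_k), 0 for absent types."""
    counts = np.bincount(idx, minlength=n).astype(float)
    inv = np.divide(1.0, counts, out=np.zeros(n), where=counts > 0)
    return inv / ((n_sources + 1) * n)


def cell_alignment_loss_source(
    Z: np.ndarray, labels, centroids: CentroidSet, n_sources: int,
) -> float:
    """Mean distance of one source's cells to their annotated centroids.

    ``(1/((|S|+1) K)) sum_k (1/n_k) sum_{y_i=k} ||z_i - Cs_k||`` with
    K = n; cell types absent from this particular source contribute 0.
    """
    idx = centroids.type_index(labels)
    inv = _per_type_weights(idx, centroids.n, n_sources)
    loss, _, _ = _centroid_pull(np.asarray(Z, float), centroids.Cs, idx, inv, 1.0)
    return loss


def cell_alignment_loss_target(
    Z: np.ndarray, assignment: Assignment, centroids: CentroidSet, n_sources: int,
) -> float:
    """Mean distance of target cells to their nearest target centroid.

    Empty clusters contribute 0; assignments are constants here (no
    gradient flows through the argmin that produced them).
    """
    idx = assignment.nearest
    inv = _per_type_weights(idx, centroids.n, n_sources)
    loss, _, _ = _centroid_pull(np.asarray(Z, float), centroids.Ct, idx, inv, 1.0)
    return loss


def similarity_matrix(
    centroids: CentroidSet,
    epsilon: float = 1e-8,
    tau_c: float = 1.0,
    exclude_masked: bool = False,
) -> ClusterSimilarity:
    """Row-stochastic similarity P over the stacked centroids F = [Cs; Ct].

    Similarity is ``1/(dist + eps)`` for cross-domain pairs and 0 within a
    domain (including the diagonal).  By default the softmax normalizer
    keeps the masked entries' exp(0)=1 terms; ``exclude_masked`` drops
    them instead.
    """
    if epsilon <= 0 or tau_c <= 0:
        raise ValueError("epsilon and tau_c must be positive")
    n = centroids.n
    F = np.vstack([centroids.Cs, centroids.Ct])
    D = cdist(F, F)
    cross = np.zeros((2 * n, 2 * n), dtype=bool)
    cross[:n, n:] = True
    cross[n:, :n] = True
    sim = np.where(cross, 1.0 / (D + epsilon), 0.0)
    logits = sim / tau_c
    if exclude_masked:
        logits = np.where(cross, logits, -np.inf)
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    P = e / e.sum(axis=1, keepdims=True)
    return ClusterSimilarity(F, P, sim, cross, epsilon, tau_c)


def cluster_alignment_loss(simmat: ClusterSimilarity) -> float:
    """Mean Shannon entropy (nats) of the rows of P."""
    P = simmat.P
    H = -np.sum(np.where(P > 0, P * np.log(np.maximum(P, _TINY)), 0.0), axis=1)
    return float(H.mean())


def _cluster_alignment_grad(
    centroids: CentroidSet, epsilon: float, tau_c: float, exclude_masked: bool = False,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients with respect to Cs and Ct."""
    simmat = similarity_matrix(centroids, epsilon, tau_c, exclude_masked)
    P, cross, F = simmat.P, simmat.cross_mask, simmat.F
    two_n = P.shape[0]
    logP = np.log(np.maximum(P, _TINY))
    H = -np.sum(P * logP, axis=1)
    # dH_i/d logits_ij for a softmax row: -p_ij (log p_ij + H_i)
    dlogits = -P * (logP + H[:, None]) / two_n
    dsim = np.where(cross, dlogits / tau_c, 0.0)
    D = cdist(F, F)
    ddist = -dsim / (D + epsilon) ** 2  # d(1/(d+eps))/dd
    # distances are symmetric: entry (i,j) of sim and (j,i) both depend on d_ij
    W = ddist + ddist.T
    # dL/dF_i = sum_j W_ij * (F_i - F_j)/d_ij   (upper/lower handled via W)
    invD = 1.0 / np.maximum(D, _TINY)
    np.fill_diagonal(invD, 0.0)
    A = W * invD
    dF = F * A.sum(axis=1)[:, None] - A @ F
    n = centroids.n
    return float(H.mean()), dF[:n], dF[n:]


def total_loss(source_losses, target_loss: float, cluster_loss: float) -> float:
    """Plain unweighted sum of all loss terms."""
    return float(np.sum(source_losses) + target_loss + cluster_loss)


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def finetune(
    encoder: Encoder,
    centroids: CentroidSet,
    sources: list[ExpressionDataset],
    target: ExpressionDataset,
    epochs: int = 50,
    lr: float = 1e-3,
    batch_size: int = 256,
    centroid_steps: int = 10,
    epsilon: float = 1e-8,
    tau_c: float = 1.0,
    seed: int = 0,
    use_cluster_loss: bool = True,
    recompute_source_means: bool = False,
    exclude_masked: bool = False,
) -> tuple[Encoder, CentroidSet, Assignment, list[float]]:
    """Alternating optimization of the encoder and the centroid matrices.

    Per epoch: target assignments are refreshed once and held fixed; the
    encoder takes one minibatch pass over all cells on the cell-alignment
    losses (the cluster loss does not depend on the encoder, the
    centroids being free parameters); then the centroids take
    ``centroid_steps`` full-batch Adam steps on the complete loss.  With
    ``recompute_source_means`` the source centroids are instead reset to
    the current per-type embedding means each epoch.  Returns the updated
    encoder and centroids, the final assignment, and the per-epoch total
    loss trace.
    """
    n_sources = len(sources)
    n = centroids.n
    rng = np.random.default_rng(seed)
    Xs = [ds.dense() for ds in sources]
    Xt = target.dense()
    src_idx = [centroids.type_index(ds.labels) for ds in sources]
    X_all = np.vstack([*Xs, Xt])
    n_src_cells = sum(x.shape[0] for x in Xs)

    enc_opt = Adam(encoder.params, lr=lr)
    cparams = {"Cs": centroids.Cs, "Ct": centroids.Ct}
    c_opt = Adam(cparams, lr=lr)

    def embed_all():
        Z = encoder.forward(X_all) if X_all.shape[0] <= 4096 else np.vstack(
            [encoder.forward(X_all[s : s + 4096]) for s in range(0, X_all.shape[0], 4096)]
        )
        offs, zs = 0, []
        for x in Xs:
            zs.append(Z[offs : offs + x.shape[0]])
            offs += x.shape[0]
        return zs, Z[offs:], Z

    def losses(Zs, Zt, assign):
        src = [
            cell_alignment_loss_source(z, ds.labels, centroids, n_sources)
            for z, ds in zip(Zs, sources)
        ]
        tgt = cell_alignment_loss_target(Zt, assign, centroids, n_sources)
        clus = (
            cluster_alignment_loss(similarity_matrix(centroids, epsilon, tau_c, exclude_masked))
            if use_cluster_loss
            else 0.0
        )
        return total_loss(src, tgt, clus)

    assignment = Assignment(nearest_centroids(encoder.forward(Xt) if Xt.shape[0] <= 4096
                                              else embed_all()[1], centroids.Ct))
    trace: list[float] = []
    for epoch in range(epochs):
        Zs, Zt, _ = embed_all()
        assignment = Assignment(nearest_centroids(Zt, centroids.Ct))
        trace.append(losses(Zs, Zt, assignment))
        if not np.isfinite(trace[-1]):
            raise TrainingError(f"non-finite loss at epoch {epoch}")

        # per-cell weights and per-cell pull centroid, fixed for the epoch
        weights = np.concatenate(
            [_per_type_weights(idx, n, n_sources)[idx] for idx in src_idx]
            + [_per_type_weights(assignment.nearest, n, n_sources)[assignment.nearest]]
        )
        pull = np.vstack(
            [centroids.Cs[idx] for idx in src_idx] + [centroids.Ct[assignment.nearest]]
        )

        # (b) encoder pass, centroids frozen
        order = rng.permutation(X_all.shape[0])
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            Z, cache = encoder.forward(X_all[sel], return_cache=True)
            diff = Z - pull[sel]
            dist = np.maximum(np.linalg.norm(diff, axis=1), _TINY)
            dZ = weights[sel, None] * diff / dist[:, None]
            grads, _ = encoder.backward(cache, dZ)
            enc_opt.step(grads)

        # (c) centroid pass, encoder frozen
        Zs, Zt, _ = embed_all()
        for _ in range(centroid_steps):
            dCs = np.zeros_like(centroids.Cs)
            dCt = np.zeros_like(centroids.Ct)
            for z, idx in zip(Zs, src_idx):
                inv = _per_type_weights(idx, n, n_sources)
                _, _, g = _centroid_pull(z, centroids.Cs, idx, inv, 1.0)
                dCs += g
            inv = _per_type_weights(assignment.nearest, n, n_sources)
            _, _, g = _centroid_pull(Zt, centroids.Ct, assignment.nearest, inv, 1.0)
            dCt += g
            if use_cluster_loss:
                _, gs, gt = _cluster_alignment_grad(centroids, epsilon, tau_c, exclude_masked)
                dCs += gs
                dCt += gt
            c_opt.step({"Cs": dCs, "Ct": dCt})
        if recompute_source_means:
            sums = np.zeros_like(centroids.Cs)
            counts = np.zeros(n)
            for z, idx in zip(Zs, src_idx):
                np.add.at(sums, idx, z)
                counts += np.bincount(idx, minlength=n)
            nonzero = counts > 0
            centroids.Cs[nonzero] = sums[nonzero] / counts[nonzero, None]

    _, Zt, _ = embed_all()
    assignment = Assignment(nearest_centroids(Zt, centroids.Ct))
    return encoder, centroids, assignment, trace


def prune_and_estimate(
    assignment: Assignment,
    centroids: CentroidSet,
    min_cells: int = 1,
    target_embedding: np.ndarray | None = None,
) -> tuple[int, np.ndarray, Assignment]:
    """Drop target centroids attracting fewer than ``min_cells`` cells.

    Returns the estimated number of target clusters, the alive mask (also
    stored on ``centroids``), and the final assignment.  When pruning
    orphans cells (only possible for ``min_cells > 1``) they are
    reassigned to the nearest surviving centroid, which requires
    ``target_embedding``.
    """
    counts = assignment.counts(centroids.n)
    alive = counts >= min_cells
    estimated_k = int(alive.sum())
    if estimated_k == 0:
        raise TrainingError("every target centroid was pruned (degenerate result)")
    centroids.alive_mask = alive
    if np.all(alive[assignment.nearest]):
        return estimated_k, alive, assignment
    if target_embedding is None:
        raise ValueError("reassignment after pruning requires target_embedding")
    alive_idx = np.flatnonzero(alive)
    new = assignment.nearest.copy()
    orphans = ~alive[assignment.nearest]
    new[orphans] = alive_idx[
        nearest_centroids(np.asarray(target_embedding)[orphans], centroids.Ct[alive_idx])
    ]
    return estimated_k, alive, Assignment(new)
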