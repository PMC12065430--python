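"""End-to-end orchestration: normalize -> pretrain -> init -> fine-tune -> prune.

:func:`run_pipeline` is the one-call entry point used by the CLI, the
examples and the acceptance script.  It takes in-memory datasets (read
or simulated upstream), applies the preprocessing recipe, runs the three
training stages, prunes empty target clusters and returns a
:class:`PipelineResult` bundling labels, centroids, traces and the
estimated number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    Assignment,
    CentroidSet,
    finetune,
    init_centroids,
    prune_and_estimate,
)
from .data import ExpressionDataset, harmonize_genes, normalize
from .encoder import Encoder, EncoderConfig
from .pretrain import AugmentationConfig, pretrain_encoder

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunables of the three-stage pipeline, with the defaults used throughout."""

    hidden_dims: list[int] = field(default_factory=lambda: [1024, 256])
    latent_dim: int = 100
    normalize_total: float = 1e4
    log_transform: bool = True
    zero_prob: float = 0.2
    pretrain_epochs: int = 30
    pretrain_batch_size: int = 256
    pretrain_lr: float = 1e-3
    infonce_tau: float = 1.0
    finetune_epochs: int = 50
    finetune_batch_size: int = 256
    finetune_lr: float = 1e-3
    centroid_steps: int = 10
    cluster_tau: float = 1.0
    cluster_epsilon: float = 1e-8
    min_cells: int = 1
    use_pretraining: bool = True
    use_cluster_loss: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    encoder: Encoder
    centroids: CentroidSet
    assignment: Assignment
    estimated_k: int
    labels: list[str]
    cell_ids: list[str]
    pretrain_trace: list[float]
    finetune_trace: list[float]
    target_embedding: np.ndarray

    def labels_frame(self):
        import pandas as pd

        alive_rank = {k: r for r, k in enumerate(np.flatnonzero(self.centroids.alive_mask))}
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cluster_index": [alive_rank[k] for k in self.assignment.nearest],
                "matched_type_name": self.labels,
            }
        )


def run_pipeline(
    sources: list[ExpressionDataset],
    target: ExpressionDataset,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Cluster the target dataset against the annotated sources.

    The returned per-cell ``labels`` name each cell's surviving target
    centroid by the source cell type the centroid was initialized from
    (clusters captured by an unseen type keep the name of their origin,
    which is the closest annotation the method can offer).
    """
    cfg = config or RunConfig()
    datasets = harmonize_genes([*sources, target])
    datasets = [
        normalize(ds, total=cfg.normalize_total, log_transform=cfg.log_transform)
        for ds in datasets
    ]
    sources_n, target_n = datasets[:-1], datasets[-1]

    encoder = Encoder(
        EncoderConfig(
            input_dim=target_n.n_genes,
            hidden_dims=list(cfg.hidden_dims),
            latent_dim=cfg.latent_dim,
            seed=cfg.seed,
        )
    )
    pretrain_trace: list[float] = []
    if cfg.use_pretraining and cfg.pretrain_epochs > 0:
        total_cells = sum(ds.n_cells for ds in datasets)
        encoder, pretrain_trace = pretrain_encoder(
            encoder,
            datasets,
            batch_size=min(cfg.pretrain_batch_size, total_cells),
            epochs=cfg.pretrain_epochs,
            aug=AugmentationConfig(zero_prob=cfg.zero_prob, seed=cfg.seed),
            lr=cfg.pretrain_lr,
            tau=cfg.infonce_tau,
            seed=cfg.seed,
        )

    centroids = init_centroids(encoder, sources_n)
    encoder, centroids, assignment, finetune_trace = finetune(
        encoder,
        centroids,
        sources_n,
        target_n,
        epochs=cfg.finetune_epochs,
        lr=cfg.finetune_lr,
        batch_size=cfg.finetune_batch_size,
        centroid_steps=cfg.centroid_steps,
        epsilon=cfg.cluster_epsilon,
        tau_c=cfg.cluster_tau,
        seed=cfg.seed + 1,
        use_cluster_loss=cfg.use_cluster_loss,
    )
    Zt = encoder.embed(target_n).vectors
    estimated_k, _, assignment = prune_and_estimate(
        assignment, centroids, min_cells=cfg.min_cells, target_embedding=Zt
    )
    labels = [centroids.type_names[k] for k in assignment.nearest]
    return PipelineResult(
        encoder=encoder,
        centroids=centroids,
        assignment=assignment,
        estimated_k=estimated_k,
        labels=labels,
        cell_ids=list(target_n.cell_ids),
        pretrain_trace=pretrain_trace,
        finetune_trace=finetune_trace,
        target_embedding=Zt,
    )
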