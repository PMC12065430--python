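"""Synthetic multi-source scRNA-seq generator with known ground truth.

Emulates the data regime the method targets: several annotated reference
experiments ("sources") and one unannotated target that share cell types
but differ by technical batch effects, plus cell types present only in
the target.  The generative model per count is a gamma-Poisson
(negative binomial):

* each cell type owns a disjoint block of marker genes whose mean is
  shifted up by ``exp(program_strength)``;
* each domain (every source and the target) multiplies every gene's mean
  by an independent log-normal batch factor with log-sd
  ``batch_effect_sd``;
* each cell carries a gamma library-size factor (mean 1);
* optional extra Bernoulli dropout zeroes entries independently.

Labels are attached to the sources; the target's truth labels are
returned separately for evaluation only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .data import ExpressionDataset, write_dataset

__all__ = ["SimulationConfig", "simulate", "write_fixture"]


@dataclass
class SimulationConfig:
    n_genes: int = 500
    n_types: int = 5
    n_sources: int = 3
    cells_per_type_per_domain: int = 100
    target_only_types: int = 1
    program_strength: float = 2.0
    markers_per_type: int = 10
    batch_effect_sd: float = 0.5
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.0
    library_size_shape: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.target_only_types < 0:
            raise ValueError("n_types >= 1 and target_only_types >= 0 required")
        if self.target_only_types >= self.n_types:
            raise ValueError("at least one cell type must be shared with the sources")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                f"{self.n_types} disjoint marker blocks of {self.markers_per_type} "
                f"genes do not fit in {self.n_genes} genes"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.program_strength <= 0:
            raise ValueError("nb_dispersion and program_strength must be positive")


def simulate(config: SimulationConfig):
    """Generate the sources, the target, and the target's truth labels.

    Returns ``(sources, target, target_truth)`` where ``sources`` is a
    list of labeled :class:`~crossclust.data.ExpressionDataset`, the
    target is unlabeled, and ``target_truth`` is the per-cell type list
    held out for evaluation.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    type_names = [f"type_{k:02d}" for k in range(cfg.n_types)]
    shared = type_names[: cfg.n_types - cfg.target_only_types]
    gene_names = [f"gene_{g:04d}" for g in range(cfg.n_genes)]

    # per-gene baseline mean and per-type marker programs (shared by all domains)
    base = rng.lognormal(mean=np.log(0.5), sigma=0.5, size=cfg.n_genes)
    type_mean = np.tile(base, (cfg.n_types, 1))
    for k in range(cfg.n_types):
        block = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        type_mean[k, block] *= np.exp(cfg.program_strength)

    def sample_domain(domain_id: str, types: list[str]) -> tuple[np.ndarray, list[str]]:
        batch = np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_genes))
        blocks, labels = [], []
        for t in types:
            k = type_names.index(t)
            m = cfg.cells_per_type_per_domain
            lib = rng.gamma(cfg.library_size_shape, 1.0 / cfg.library_size_shape, size=m)
            mu = lib[:, None] * (type_mean[k] * batch)[None, :]
            lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
            counts = rng.poisson(lam).astype(np.float64)
            if cfg.dropout_rate > 0:
                counts *= rng.random(counts.shape) >= cfg.dropout_rate
            blocks.append(counts)
            labels.extend([t] * m)
        return np.vstack(blocks), labels

    sources = []
    for s in range(cfg.n_sources):
        mat, labels = sample_domain(f"source:{s}", shared)
        cells = [f"s{s}_cell_{i:05d}" for i in range(mat.shape[0])]
        sources.append(ExpressionDataset(mat, gene_names, cells, f"source:{s}", labels))
    mat, truth = sample_domain("target", type_names)
    cells = [f"t_cell_{i:05d}" for i in range(mat.shape[0])]
    target = ExpressionDataset(mat, gene_names, cells, "target")
    return sources, target, truth


def write_fixture(config: SimulationConfig, directory: str | Path) -> Path:
    """Write a simulated fixture as MTX triplets plus a YAML manifest.

    Layout: one subdirectory per domain (``source_0`` ... ``target``),
    each holding matrix.mtx/genes.tsv/barcodes.tsv and, for sources,
    labels.csv; the target truth goes into ``target_truth.csv`` at the
    top level and ``manifest.yaml`` records the domains and the config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sources, target, truth = simulate(config)
    domains = []
    for i, ds in enumerate(sources):
        write_dataset(ds, directory / f"source_{i}")
        domains.append({"name": f"source_{i}", "domain_id": ds.domain_id, "n_cells": ds.n_cells})
    write_dataset(target, directory / "target")
    domains.append({"name": "target", "domain_id": "target", "n_cells": target.n_cells})
    import pandas as pd

    pd.DataFrame({"cell_id": target.cell_ids, "label": truth}).to_csv(
        directory / "target_truth.csv", index=False
    )
    manifest = directory / "manifest.yaml"
    manifest.write_text(
        yaml.safe_dump({"domains": domains, "config": asdict(config), "truth": "target_truth.csv"})
    )
    return manifest
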