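"""Expression-matrix containers, readers, gene harmonization and normalization.

A :class:`ExpressionDataset` is the common currency of the pipeline: a
cells x genes non-negative matrix with gene names, cell barcodes, an
optional per-cell label vector (mandatory for annotated reference
("source") datasets) and a domain tag.  Datasets from different
experiments are made comparable by intersecting their gene vocabularies
(:func:`harmonize_genes`) and library-size normalizing each cell
(:func:`normalize`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "FormatError",
    "HarmonizationError",
    "LabelError",
    "read_dataset",
    "harmonize_genes",
    "normalize",
    "write_dataset",
]


class FormatError(ValueError):
    """Raised for malformed expression input (negative, non-numeric, ...)."""


class HarmonizationError(ValueError):
    """Raised when two datasets share no genes."""


class LabelError(ValueError):
    """Raised when required cell annotations are missing or inconsistent."""


@dataclass
class ExpressionDataset:
    """One expression experiment: cells are rows, genes are columns.

    ``matrix`` may be dense ``ndarray`` or any scipy sparse matrix; sparse
    inputs are kept sparse.  ``labels`` holds per-cell cell-type strings
    and is required whenever ``domain_id`` starts with ``"source"``.
    """

    matrix: np.ndarray | sp.spmatrix
    gene_names: list[str]
    cell_ids: list[str]
    domain_id: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.matrix.shape != (len(self.cell_ids), len(self.gene_names)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        data = self.matrix.data if sp.issparse(self.matrix) else self.matrix
        if not np.all(np.isfinite(data)):
            raise FormatError("expression matrix contains non-finite values")
        if data.size and data.min() < 0:
            raise FormatError("expression matrix contains negative values")
        if self.is_source:
            if self.labels is None or len(self.labels) != self.n_cells:
                raise LabelError(
                    f"source dataset {self.domain_id!r} requires one label per cell"
                )
            self.labels = [str(l).strip() for l in self.labels]
            if any(l == "" or l == "nan" for l in self.labels):
                raise LabelError(
                    f"source dataset {self.domain_id!r} has empty labels"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_source(self) -> bool:
        return self.domain_id.startswith("source")

    def dense(self) -> np.ndarray:
        """Matrix as a dense float64 array (copy for sparse input)."""
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=np.float64)
        return np.asarray(self.matrix, dtype=np.float64)

    def subset_genes(self, index: np.ndarray, gene_names: list[str]) -> "ExpressionDataset":
        mat = self.matrix.tocsc()[:, index].tocsr() if sp.issparse(self.matrix) else self.matrix[:, index]
        return replace(self, matrix=mat, gene_names=list(gene_names))


def _dedupe_genes(names: Sequence[str], strict: bool) -> tuple[list[str], np.ndarray]:
    """Return unique gene names (first occurrence kept) and kept column index."""
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, g in enumerate(names):
        if g in seen:
            if strict:
                raise FormatError(f"duplicate gene name {g!r} in strict mode")
            continue
        seen[g] = i
        keep.append(i)
    if len(keep) < len(names):
        warnings.warn(
            f"{len(names) - len(keep)} duplicate gene name(s) dropped (first kept)",
            stacklevel=3,
        )
    return [names[i] for i in keep], np.asarray(keep, dtype=int)


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    label_column: str | None = None,
    labels_file: str | Path | None = None,
    domain_id: str = "target",
    strict: bool = False,
) -> ExpressionDataset:
    """Read an expression dataset from CSV/TSV, MTX triplet, or h5ad.

    Parameters
    ----------
    path
        For ``csv``/``tsv``: a cells x genes table with a header row of gene
        names and cell barcodes in the first column (an optional label column
        named by ``label_column`` is split off).  For ``mtx``: the matrix file,
        with ``genes.tsv`` and ``barcodes.tsv`` alongside (cells x genes or
        genes x cells orientation resolved from the companion file lengths).
        For ``h5ad``: an AnnData container; labels come from the obs column
        named by ``label_column``.
    labels_file
        Alternative two-column CSV (cell_id, label) for MTX layouts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "csv", ".txt": "csv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer format from {path.name!r}")

    labels: list[str] | None = None
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        # pandas mangles duplicate header names (g1 -> g1.1); restore originals
        with open(path) as fh:
            raw_header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(raw_header) == len(df.columns):
            df.columns = raw_header
        if label_column is not None:
            if label_column not in df.columns:
                raise LabelError(f"label column {label_column!r} not in {path.name}")
            labels = df.pop(label_column).astype(str).tolist()
        try:
            mat = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric entries in {path.name}: {exc}") from None
        genes = [str(c) for c in df.columns]
        cells = [str(i) for i in df.index]
    elif fmt == "mtx":
        mat = sp.csr_matrix(scipy.io.mmread(path), dtype=np.float64)
        gene_file = path.parent / "genes.tsv"
        bc_file = path.parent / "barcodes.tsv"
        for f in (gene_file, bc_file):
            if not f.exists():
                raise FileNotFoundError(f)
        genes = gene_file.read_text().split()
        cells = bc_file.read_text().split()
        if mat.shape == (len(genes), len(cells)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T.tocsr()  # genes x cells on disk (CellRanger layout)
        if mat.shape != (len(cells), len(genes)):
            raise FormatError(
                f"MTX shape {mat.shape} matches neither orientation for "
                f"{len(cells)} barcodes x {len(genes)} genes"
            )
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        mat = adata.X
        mat = sp.csr_matrix(mat, dtype=np.float64) if sp.issparse(mat) else np.asarray(mat, dtype=np.float64)
        genes = [str(g) for g in adata.var_names]
        cells = [str(c) for c in adata.obs_names]
        if label_column is not None:
            if label_column not in adata.obs.columns:
                raise LabelError(f"obs column {label_column!r} not in {path.name}")
            labels = adata.obs[label_column].astype(str).tolist()
    else:
        raise FormatError(f"unknown format {fmt!r}")

    if labels_file is not None:
        ldf = pd.read_csv(labels_file)
        lmap = dict(zip(ldf.iloc[:, 0].astype(str), ldf.iloc[:, 1].astype(str)))
        missing = [c for c in cells if c not in lmap]
        if missing:
            raise LabelError(f"labels file lacks {len(missing)} cell id(s), e.g. {missing[0]!r}")
        labels = [lmap[c] for c in cells]

    genes, keep = _dedupe_genes(genes, strict)
    if len(keep) < mat.shape[1]:
        mat = mat.tocsc()[:, keep].tocsr() if sp.issparse(mat) else mat[:, keep]

    if domain_id.startswith("source") and labels is None:
        raise LabelError(f"source dataset {path.name} read without labels")
    return ExpressionDataset(mat, genes, cells, domain_id, labels)


def harmonize_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict all datasets to their shared genes, in a common column order.

    Gene symbols are matched case-insensitively (canonical form: uppercase);
    the output column order is the order of the shared genes in the first
    dataset.  Idempotent.
    """
    if len(datasets) < 2:
        raise ValueError("harmonization needs at least two datasets")
    canon_sets = []
    for ds in datasets:
        canon_sets.append({g.upper() for g in ds.gene_names})
    shared = set(canon_sets[0])
    for i, s in enumerate(canon_sets[1:], start=1):
        new = shared & s
        if not new:
            raise HarmonizationError(
                f"no shared genes between {datasets[0].domain_id!r} (+earlier) "
                f"and {datasets[i].domain_id!r}"
            )
        shared = new
    ordered = [g.upper() for g in datasets[0].gene_names if g.upper() in shared]
    out = []
    for ds in datasets:
        pos = {g.upper(): j for j, g in enumerate(ds.gene_names)}
        idx = np.asarray([pos[g] for g in ordered], dtype=int)
        out.append(ds.subset_genes(idx, ordered))
    return out


def normalize(
    dataset: ExpressionDataset,
    total: float = 1e4,
    log_transform: bool = True,
) -> ExpressionDataset:
    """Library-size normalize each cell to ``total`` counts, then log1p.

    All-zero cells are left at zero, and zeros stay exactly zero throughout,
    so the dropout-style augmentation's notion of "non-zero genes" is
    preserved by this transform.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if sp.issparse(dataset.matrix):
        mat = dataset.matrix.tocsr().astype(np.float64, copy=True)
        sums = np.asarray(mat.sum(axis=1)).ravel()
        scale = np.divide(total, sums, out=np.zeros_like(sums), where=sums > 0)
        mat = sp.diags(scale) @ mat
        if log_transform:
            mat.data = np.log1p(mat.data)
        mat = sp.csr_matrix(mat)
    else:
        mat = np.asarray(dataset.matrix, dtype=np.float64).copy()
        sums = mat.sum(axis=1)
        scale = np.divide(total, sums, out=np.zeros_like(sums), where=sums > 0)
        mat = mat * scale[:, None]
        if log_transform:
            mat = np.log1p(mat)
    return replace(dataset, matrix=mat)


def select_hvg(datasets: Sequence[ExpressionDataset], n_top: int) -> list[ExpressionDataset]:
    """Restrict harmonized datasets to the ``n_top`` most dispersed genes.

    Dispersion is the variance/mean ratio of each gene pooled over all
    datasets (genes with zero mean rank last).  Off by default in the
    pipeline; provided for users who preselect features.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    genes = datasets[0].gene_names
    if any(ds.gene_names != genes for ds in datasets[1:]):
        raise HarmonizationError("select_hvg requires harmonized gene names")
    X = np.vstack([ds.dense() for ds in datasets])
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    keep = np.sort(np.argsort(disp)[::-1][: min(n_top, len(genes))])
    kept_names = [genes[i] for i in keep]
    return [ds.subset_genes(keep, kept_names) for ds in datasets]


def write_dataset(dataset: ExpressionDataset, directory: str | Path) -> Path:
    """Write a dataset as MTX + genes.tsv + barcodes.tsv (+ labels.csv).

    Returns the directory written.  Round-trips through
    :func:`read_dataset` with ``fmt="mtx"``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = dataset.matrix if sp.issparse(dataset.matrix) else sp.csr_matrix(dataset.matrix)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(mat))
    (directory / "genes.tsv").write_text("\n".join(dataset.gene_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(dataset.cell_ids) + "\n")
    if dataset.labels is not None:
        pd.DataFrame({"cell_id": dataset.cell_ids, "label": dataset.labels}).to_csv(
            directory / "labels.csv", index=False
        )
    return directory
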