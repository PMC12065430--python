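"""Generate a small multi-source benchmark with known ground truth.

Two annotated source datasets share three cell types; the unannotated
target carries those three plus one type never seen in any source.
Every domain gets its own multiplicative per-gene batch effect.
"""

import numpy as np

from crossclust import SimulationConfig, simulate

config = SimulationConfig(
    n_genes=200,
    n_types=4,
    n_sources=2,
    cells_per_type_per_domain=50,
    target_only_types=1,
    batch_effect_sd=0.5,
    seed=1,
)
sources, target, truth = simulate(config)

for ds in sources:
    print(f"{ds.domain_id}: {ds.n_cells} cells x {ds.n_genes} genes, "
          f"types {sorted(set(ds.labels))}")
print(f"target: {target.n_cells} cells, true types {sorted(set(truth))} "
      "(labels withheld from the pipeline)")
counts = np.asarray(target.dense())
print(f"target sparsity: {np.mean(counts == 0):.1%} zeros, "
      f"median library size {np.median(counts.sum(axis=1)):.0f} counts")
# The type list shows type_03 exists only in the target: the clustering
# stage must notice those cells even though no source ever annotated them.
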