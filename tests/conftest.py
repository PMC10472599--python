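"""Shared fixtures: small deterministic synthetic datasets and one
end-to-end malignancy-calling run reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leukotrace.malignancy import (
    call_leukemic_clusters,
    compose_anchor_set,
    revise_lymphoid,
)
from leukotrace.matrix import CellMatrix
from leukotrace.preprocess import (
    cluster,
    normalize,
    pca_embed,
    qc_filter,
    select_variable_genes,
)
from leukotrace.projection import build_reference, cluster_majority_types, project_cells
from leukotrace.synthetic import (
    SimConfig,
    generate_healthy_reference,
    generate_patient_pair,
    generate_typed_cells,
    leukemic_type_catalog,
)


def make_cellmatrix(normalized: np.ndarray, gene_names=None, barcodes=None) -> CellMatrix:
    """Toy CellMatrix with a directly supplied normalized layer."""
    normalized = np.asarray(normalized, dtype=float)
    n, g = normalized.shape
    gene_names = gene_names or [f"g{j}" for j in range(g)]
    barcodes = barcodes or [f"c{i}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    m = CellMatrix(
        counts=np.zeros((n, g), dtype=int), gene_names=list(gene_names), cell_meta=meta
    )
    m.normalized = normalized
    return m


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=1, n_genes=1000, n_cells_per_type=60, n_cells_per_sample=1000,
                     tumor_burden_pre=0.7, tumor_burden_post=0.03)


@pytest.fixture(scope="session")
def e2e_run(small_config):
    """Full co-clustering malignancy pipeline on one synthetic patient."""
    cfg = small_config
    healthy, _ = generate_healthy_reference(cfg)
    pre, post, truth = generate_patient_pair(cfg)
    healthy, pre, post = (normalize(qc_filter(x)) for x in (healthy, pre, post))
    pooled, origins = compose_anchor_set(healthy, pre, post)
    pooled = normalize(pooled)
    hvg = select_variable_genes(pooled, 800)
    emb, _ = pca_embed(pooled, genes=hvg, seed=0)
    clusters = cluster(emb, seed=0)
    call = call_leukemic_clusters(clusters, origins)
    healthy_mask = (origins == "healthy").to_numpy()
    ref = build_reference(
        pooled.subset_cells(healthy_mask),
        pooled.cell_meta["true_type"][healthy_mask].to_numpy(),
    )
    proj = project_cells(pooled, ref)
    call = revise_lymphoid(call, cluster_majority_types(clusters, proj))
    return {
        "config": cfg,
        "healthy": healthy,
        "pre": pre,
        "post": post,
        "truth": truth,
        "pooled": pooled,
        "origins": origins,
        "clusters": clusters,
        "call": call,
        "ref": ref,
        "proj": proj,
    }


@pytest.fixture(scope="session")
def leukemic_cells():
    """Normalized single-cell data across the 11 leukemic identities."""
    cfg = SimConfig(seed=0, n_genes=1200, n_cells_per_type=120)
    m, truth = generate_typed_cells(
        cfg, leukemic_type_catalog(), sample_id="LEU", timepoint="pre", stream="leukemic"
    )
    return normalize(m), truth, cfg
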