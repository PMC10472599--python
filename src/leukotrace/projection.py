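"""Nearest-centroid cosine projection onto a healthy cell-type reference.

The reference holds, per type, the top marker genes (by average fold
change from one-vs-rest DE) and a centroid of mean normalized expression
over the union of all marker genes. Cells are assigned to the most
cosine-similar centroid; malignant cells are renamed with a "-like"
suffix after their nearest healthy counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellMatrix
from .preprocess import wilcoxon_de

__all__ = ["CellTypeReference", "ProjectionResult", "build_reference", "project_cells",
           "label_malignant_types", "cluster_majority_types"]


@dataclass
class CellTypeReference:
    marker_genes: dict[str, list[str]]  # type -> up to top_n markers
    centroids: pd.DataFrame  # gene union x types, mean normalized expression
    similarity_threshold: float = 0.7

    def __post_init__(self) -> None:
        for t, genes in self.marker_genes.items():
            if len(genes) > 100:
                raise ValueError(f"marker list for {t!r} exceeds 100 genes")

    @property
    def types(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def gene_union(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class ProjectionResult:
    assignments: pd.DataFrame  # index barcode; assigned_type, similarity, unassigned

    @property
    def assigned_types(self) -> pd.Series:
        return self.assignments["assigned_type"]


def build_reference(
    healthy: CellMatrix,
    type_labels,
    top_n: int = 100,
    min_cells: int = 3,
    similarity_threshold: float = 0.7,
    max_q: float = 0.05,
) -> CellTypeReference:
    """Construct per-type marker lists and centroids from labeled cells.

    Per type, one-vs-rest Wilcoxon DE selects up to ``top_n`` genes by
    average fold change among significantly upregulated genes
    (q < ``max_q``); the centroid is the per-gene mean normalized
    expression of the type's cells over the union of all markers.
    """
    if healthy.normalized is None:
        raise ValueError("normalized layer required")
    labels = pd.Series(np.asarray(type_labels), index=healthy.barcodes)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")

    markers: dict[str, list[str]] = {}
    for t in types:
        mask = (labels == t).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"type {t!r} has < {min_cells} cells; excluded from reference",
                          stacklevel=2)
            continue
        de = wilcoxon_de(healthy, mask, ~mask, min_pct=0.1, lfc_min=0.0)
        up = de[(de["lfc"] > 0) & (de["q"] < max_q)]
        up = up.sort_index().sort_values("lfc", ascending=False, kind="stable")
        markers[t] = up.index[:top_n].tolist()
    if len(markers) < 2:
        raise ValueError("fewer than 2 types with enough cells for a reference")

    union = sorted({g for genes in markers.values() for g in genes})
    cols = [healthy.gene_idx(g) for g in union]
    centroids = {}
    for t in markers:
        mask = (labels == t).to_numpy()
        centroids[t] = healthy.normalized[np.ix_(mask, cols)].mean(axis=0)
    return CellTypeReference(
        marker_genes=markers,
        centroids=pd.DataFrame(centroids, index=union),
        similarity_threshold=similarity_threshold,
    )


def project_cells(cells: CellMatrix, ref: CellTypeReference) -> ProjectionResult:
    """Assign each cell to the most cosine-similar reference centroid.

    Reference genes missing from the cells are imputed as 0; a cell
    whose vector is all-zero on the gene union, or whose best similarity
    falls below the threshold, is flagged unassigned. Ties break by
    type-name order.
    """
    if cells.normalized is None:
        raise ValueError("normalized layer required")
    union = ref.gene_union
    present = [g for g in union if cells.has_gene(g)]
    if not present:
        raise ValueError("no reference gene present in the cell matrix")
    x = np.zeros((cells.n_cells, len(union)))
    for k, g in enumerate(union):
        if cells.has_gene(g):
            x[:, k] = cells.gene_values(g, "normalized")

    c = ref.centroids.to_numpy()  # (genes, types)
    cn = c / np.maximum(np.linalg.norm(c, axis=0), 1e-12)
    xnorm = np.linalg.norm(x, axis=1)
    safe = np.maximum(xnorm, 1e-12)
    sims = (x / safe[:, None]) @ cn  # (cells, types)
    # stable argmax with type-name tie-break (columns already name-ordered)
    type_order = np.argsort(ref.types, kind="stable")
    sims_ordered = sims[:, type_order]
    best_local = sims_ordered.argmax(axis=1)
    best_col = type_order[best_local]
    best_sim = sims[np.arange(cells.n_cells), best_col]
    types = np.array(ref.types, dtype=object)[best_col]
    unassigned = (best_sim < ref.similarity_threshold) | (xnorm == 0)
    types[unassigned & (xnorm == 0)] = "unassigned"
    df = pd.DataFrame(
        {"assigned_type": types, "similarity": best_sim, "unassigned": unassigned},
        index=cells.barcodes,
    )
    return ProjectionResult(assignments=df)


def label_malignant_types(proj: ProjectionResult, call) -> pd.Series:
    """Final per-cell labels: '-like' suffix for leukemic cells.

    ``call`` is a MalignancyCall covering the same cells. Unassigned
    leukemic cells get the 'unassigned-like' sentinel.
    """
    per_cell = call.per_cell
    if set(proj.assignments.index) != set(per_cell.index):
        raise ValueError("projection and malignancy call cover different cells")
    a = proj.assignments.reindex(per_cell.index)
    labels = []
    for bc in per_cell.index:
        t = a.loc[bc, "assigned_type"] if not a.loc[bc, "unassigned"] else "unassigned"
        if per_cell.loc[bc, "call"] == "leukemic":
            labels.append(f"{t}-like")
        else:
            labels.append(str(t))
    return pd.Series(labels, index=per_cell.index, name="final_label")


def cluster_majority_types(clusters: np.ndarray, proj: ProjectionResult) -> pd.Series:
    """Majority projected type per cluster (for the lymphoid revision)."""
    df = pd.DataFrame({"cluster": np.asarray(clusters),
                       "type": proj.assignments["assigned_type"].to_numpy()})
    return df.groupby("cluster")["type"].agg(lambda s: s.value_counts().index[0])
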