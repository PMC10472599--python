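"""Single-cell preprocessing: QC, depth-10,000 log normalization,
variable-gene selection, the PC-count heuristic, SNN graph clustering
and the Wilcoxon rank-sum DE primitive used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .matrix import CellMatrix

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize",
    "select_variable_genes",
    "select_pcs",
    "scale_matrix",
    "pca_embed",
    "cluster",
    "integrate",
    "wilcoxon_de",
    "bh_adjust",
]

DEPTH = 10_000.0


@dataclass
class QCThresholds:
    min_genes: int = 200
    min_umi: int = 500
    max_mito: float = 0.15
    min_cells_per_gene: int = 10
    drop_doublets: bool = True

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_umi, self.min_cells_per_gene) < 0 or self.max_mito < 0:
            raise ValueError("QC thresholds must be nonnegative")


def _mito_fraction(m: CellMatrix) -> np.ndarray:
    mt_cols = [i for i, g in enumerate(m.gene_names) if g.startswith("MT-")]
    totals = m.counts.sum(axis=1).astype(float)
    totals[totals == 0] = 1.0
    if not mt_cols:
        return np.zeros(m.n_cells)
    return m.counts[:, mt_cols].sum(axis=1) / totals


def qc_filter(m: CellMatrix, t: QCThresholds | None = None) -> CellMatrix:
    """Drop low-quality cells, then rarely-expressed genes.

    Cells failing any of: expressed genes < min_genes, UMI < min_umi,
    mito fraction > max_mito, flagged doublet. Gene filtering (expressed
    in < min_cells_per_gene cells) runs after cell filtering. Order is
    preserved; n_genes/n_umi/mito_fraction are (re)computed and stored.
    """
    t = t or QCThresholds()
    n_genes_per_cell = (m.counts > 0).sum(axis=1)
    n_umi = m.counts.sum(axis=1)
    mito = _mito_fraction(m)
    keep = (n_genes_per_cell >= t.min_genes) & (n_umi >= t.min_umi) & (mito <= t.max_mito)
    if t.drop_doublets and "doublet_flag" in m.cell_meta.columns:
        keep &= ~m.cell_meta["doublet_flag"].to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError("all cells filtered by QC thresholds")
    out = m.subset_cells(keep)

    cells_per_gene = (out.counts > 0).sum(axis=0)
    gene_keep = cells_per_gene >= t.min_cells_per_gene
    out = out.subset_genes([g for g, k in zip(out.gene_names, gene_keep) if k])
    out.cell_meta = out.cell_meta.assign(
        n_genes=(out.counts > 0).sum(axis=1),
        n_umi=out.counts.sum(axis=1),
        mito_fraction=_mito_fraction(out),
    )
    return out


def normalize(m: CellMatrix) -> CellMatrix:
    """Depth-normalize to 10,000 counts per cell and log1p-transform."""
    totals = m.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    out = m.copy()
    out.normalized = np.log1p(m.counts / totals[:, None] * DEPTH)
    return out


def select_variable_genes(m: CellMatrix, n: int = 3000, n_bins: int = 20) -> list[str]:
    """Top-n genes by binned standardized dispersion of normalized data.

    Genes are binned by mean normalized expression; within each bin the
    dispersion (variance/mean) is z-scored, which removes the
    mean-variance trend. Ties break by gene-name order.
    """
    if m.normalized is None:
        raise ValueError("normalized layer required")
    if n > m.n_genes:
        warnings.warn("requested more variable genes than present; returning all", stacklevel=2)
        n = m.n_genes
    mean = m.normalized.mean(axis=0)
    var = m.normalized.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_bins = max(1, min(n_bins, m.n_genes // 25))  # keep bins statistically meaningful
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum(np.arange(m.n_genes) * n_bins // max(m.n_genes, 1), n_bins - 1)
    z = np.zeros(m.n_genes)
    for b in range(n_bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        d = disp[sel]
        sd = d.std()
        z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranked = sorted(zip(-z, m.gene_names))  # ascending neg-z, then name
    return [g for _, g in ranked[:n]]


def select_pcs(explained_pct, own_pct_max: float = 5.0, cum_pct_min: float = 90.0,
               drop_min: float = 0.1) -> int:
    """Number of PCs to keep given per-PC explained-variance percentages.

    Two criteria: co1 = first PC whose cumulative percentage exceeds
    ``cum_pct_min`` while its own percentage is below ``own_pct_max``;
    co2 = last PC where the drop to the next PC exceeds ``drop_min``.
    Returns min(co1, co2); if one is undefined the other is used; always
    at least 1.
    """
    pct = np.asarray(list(explained_pct), dtype=float)
    if pct.size == 0:
        raise ValueError("empty explained-variance list")
    cum = np.cumsum(pct)
    co1 = None
    for i in range(pct.size):
        if cum[i] > cum_pct_min and pct[i] < own_pct_max:
            co1 = i + 1
            break
    co2 = None
    drops = pct[:-1] - pct[1:]
    big = np.flatnonzero(drops > drop_min)
    if big.size:
        co2 = int(big[-1]) + 1
    if co1 is None and co2 is None:
        return pct.size
    if co1 is None:
        return max(co2, 1)
    if co2 is None:
        return max(co1, 1)
    return max(min(co1, co2), 1)


def scale_matrix(x: np.ndarray, cap: float = 10.0) -> np.ndarray:
    """Per-gene z-score capped at ``cap`` (Seurat-style ScaleData)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return np.clip((x - mu) / sd, -cap, cap)


def pca_embed(m: CellMatrix, genes: list[str] | None = None, n_pcs: int = 30,
              auto_select: bool = True, seed: int = 0) -> tuple[np.ndarray, int]:
    """Scaled PCA embedding on (variable) genes; returns (embedding, k)."""
    from sklearn.decomposition import PCA

    if m.normalized is None:
        raise ValueError("normalized layer required")
    sub = m.subset_genes(genes) if genes is not None else m
    x = scale_matrix(sub.normalized)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    p = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    emb = p.fit_transform(x)
    k = n_pcs
    if auto_select:
        k = select_pcs(p.explained_variance_ratio_ * 100.0)
        k = min(max(k, 2), n_pcs)
    return emb[:, :k], k


def _snn_graph(embedding: np.ndarray, k_neighbors: int, prune: float) -> sparse.csr_matrix:
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors, metric="cosine").fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    adj = adj.maximum(sparse.eye(n, format="csr"))  # include self
    shared = (adj @ adj.T).tocoo()
    ksz = np.asarray(adj.sum(axis=1)).ravel()
    jac = shared.data / (ksz[shared.row] + ksz[shared.col] - shared.data)
    keep = (jac > prune) & (shared.row < shared.col)
    return sparse.coo_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    ).tocsr()


def cluster(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    prune: float = 1 / 15,
    seed: int = 0,
) -> np.ndarray:
    """SNN-graph community detection on a reduced-dimension embedding.

    Builds a cosine k-NN graph, weights edges by Jaccard overlap of
    neighborhoods (pruned below ``prune``), and partitions with Leiden
    modularity at the given resolution. Deterministic for a fixed seed.
    """
    import igraph as ig
    import leidenalg

    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    g = _snn_graph(np.asarray(embedding, dtype=float), k_neighbors, prune)
    coo = g.tocoo()
    graph = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=5,
    )
    return np.asarray(part.membership, dtype=int)


def integrate(embedding: np.ndarray, batches=None, hook=None) -> np.ndarray:
    """Pluggable batch-integration hook; defaults to pass-through.

    ``hook`` may be any callable mapping (cells x k embedding, batch
    labels) to a corrected cells x k embedding. Synthetic data carries
    no batch effect, so the default applies no correction.
    """
    if hook is None:
        return np.asarray(embedding)
    out = np.asarray(hook(np.asarray(embedding), batches))
    if out.shape[0] != np.asarray(embedding).shape[0]:
        raise ValueError("integration hook must preserve the number of cells")
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _ranksum_p_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p (normal approximation, tie-corrected).

    a: (nA, G), b: (nB, G) — one test per gene column.
    """
    nA, nB = a.shape[0], b.shape[0]
    both = np.vstack([a, b])
    ranks = stats.rankdata(both, axis=0)
    ra = ranks[:nA].sum(axis=0)
    u = ra - nA * (nA + 1) / 2.0
    mu = nA * nB / 2.0
    n = nA + nB
    # tie correction per gene
    tie_term = np.zeros(both.shape[1])
    for j in range(both.shape[1]):
        _, counts = np.unique(both[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = nA * nB / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 1e-300)
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 1e-299] = 1.0
    return np.minimum(p, 1.0)


def wilcoxon_de(
    m: CellMatrix,
    group_a,
    group_b,
    min_pct: float = 0.1,
    lfc_min: float = 0.25,
    exact_max_n: int = 30,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell sets.

    Genes are pre-filtered to max(pct_1, pct_2) >= min_pct and
    |lfc| >= lfc_min, where lfc is the natural log of the ratio of
    mean expm1(normalized) values with pseudocount 1. P-values use the
    tie-corrected normal approximation, replaced by the exact
    distribution when the pooled group size is <= ``exact_max_n`` and a
    gene has no ties. BH adjustment runs over tested genes only.
    """
    if m.normalized is None:
        raise ValueError("normalized layer required")
    ia = _resolve_cells(m, group_a)
    ib = _resolve_cells(m, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    if min(len(ia), len(ib)) < 3:
        raise ValueError("each group needs at least 3 cells")
    a = m.normalized[ia]
    b = m.normalized[ib]
    pct1 = (a > 0).mean(axis=0)
    pct2 = (b > 0).mean(axis=0)
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    lfc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= lfc_min)
    cols = np.flatnonzero(tested)
    genes = [m.gene_names[j] for j in cols]
    if cols.size == 0:
        return pd.DataFrame(columns=["lfc", "pct_1", "pct_2", "p", "q"])

    p = _ranksum_p_vec(a[:, cols], b[:, cols])
    if len(ia) + len(ib) <= exact_max_n:
        for kj, j in enumerate(cols):
            av, bv = a[:, j], b[:, j]
            if np.unique(np.concatenate([av, bv])).size == av.size + bv.size:
                p[kj] = stats.mannwhitneyu(av, bv, alternative="two-sided", method="exact").pvalue
    q = bh_adjust(p)
    return pd.DataFrame(
        {"lfc": lfc[cols], "pct_1": pct1[cols], "pct_2": pct2[cols], "p": p, "q": q},
        index=pd.Index(genes, name="gene"),
    )


def _resolve_cells(m: CellMatrix, group) -> np.ndarray:
    """Accept boolean masks, integer positions, or barcode collections."""
    arr = np.asarray(list(group) if not isinstance(group, np.ndarray) else group)
    if arr.dtype == bool:
        if arr.size != m.n_cells:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(int)
    pos = m.barcodes.get_indexer(arr)
    if (pos < 0).any():
        raise KeyError("unknown barcodes in group")
    return pos
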