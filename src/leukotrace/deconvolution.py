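"""Signature-matrix construction and constrained least-squares
deconvolution of bulk expression into leukemic cell-type proportions.

The signature matrix holds per-type mean normalized expression and
per-gene SDs over a specificity-filtered union of top upregulated
genes. Deconvolution solves a variance-weighted nonnegative least
squares with the proportions summing to at most 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import CellMatrix
from .preprocess import wilcoxon_de

__all__ = [
    "SignatureMatrix",
    "ProportionEstimate",
    "build_signature_matrix",
    "make_pseudobulk",
    "deconvolve",
    "deconvolve_cohort",
    "evaluate_recovery",
]


@dataclass
class SignatureMatrix:
    means: pd.DataFrame  # genes x types, mean normalized expression
    sds: pd.DataFrame  # genes x types, SD across cells of the type
    marker_genes: dict[str, list[str]]  # type -> its surviving signature genes

    @property
    def types(self) -> list[str]:
        return list(self.means.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.means.index)


@dataclass
class ProportionEstimate:
    proportions: pd.Series  # type -> fraction
    residual_norm: float
    other: float  # unexplained mass 1 - sum(p) before renormalization


def build_signature_matrix(
    m: CellMatrix,
    type_labels,
    top_n: int = 300,
    min_pct: float = 0.3,
    lfc_min: float = 0.2,
    max_p: float = 0.01,
    max_q: float = 0.01,
    high_expr_frac: float = 0.5,
    max_high_types: int = 2,
    min_cells: int = 20,
) -> SignatureMatrix:
    """Top-upregulated, specificity-filtered signature matrix.

    Per type, one-vs-rest Wilcoxon DE keeps genes with pct_1 > min_pct,
    p < max_p, q < max_q and lfc > lfc_min, top ``top_n`` by fold
    change. A gene counts as highly expressed in a type when that type's
    mean is at least ``high_expr_frac`` of the maximum type mean; genes
    highly expressed in more than ``max_high_types`` types are removed.
    """
    if m.normalized is None:
        raise ValueError("normalized layer required")
    labels = pd.Series(np.asarray(type_labels), index=m.barcodes)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 types")
    small = [t for t in types if (labels == t).sum() < min_cells]
    if small:
        raise ValueError(f"types with fewer than {min_cells} cells: {small}")

    candidates: dict[str, list[str]] = {}
    for t in types:
        mask = (labels == t).to_numpy()
        de = wilcoxon_de(m, mask, ~mask, min_pct=0.0, lfc_min=lfc_min)
        de = de[(de["lfc"] > lfc_min) & (de["pct_1"] > min_pct)
                & (de["p"] < max_p) & (de["q"] < max_q)]
        de = de.sort_index().sort_values("lfc", ascending=False, kind="stable")
        candidates[t] = de.index[:top_n].tolist()

    # per-type mean linear expression of every candidate gene, for specificity
    union = sorted({g for gl in candidates.values() for g in gl})
    cols = [m.gene_idx(g) for g in union]
    type_means = pd.DataFrame(
        {t: np.expm1(m.normalized[np.ix_((labels == t).to_numpy(), cols)]).mean(axis=0)
         for t in types},
        index=union,
    )
    max_mean = type_means.max(axis=1)
    high_counts = (type_means.ge(high_expr_frac * max_mean, axis=0)).sum(axis=1)
    specific = set(type_means.index[high_counts <= max_high_types])

    marker_genes = {t: [g for g in gl if g in specific] for t, gl in candidates.items()}
    empty = [t for t, gl in marker_genes.items() if not gl]
    if empty:
        raise ValueError(f"types with zero signature genes after filtering: {empty}")

    sig_genes = sorted({g for gl in marker_genes.values() for g in gl})
    sig_cols = [m.gene_idx(g) for g in sig_genes]
    means, sds = {}, {}
    for t in types:
        block = m.normalized[np.ix_((labels == t).to_numpy(), sig_cols)]
        means[t] = block.mean(axis=0)
        sds[t] = block.std(axis=0)
    return SignatureMatrix(
        means=pd.DataFrame(means, index=sig_genes),
        sds=pd.DataFrame(sds, index=sig_genes),
        marker_genes=marker_genes,
    )


def make_pseudobulk(
    m: CellMatrix, type_labels, proportions: dict[str, float], n_cells: int, seed: int = 0
) -> tuple[pd.Series, dict[str, float]]:
    """Pool cells at expected ratios and sum normalized expression.

    ``round(n_cells * p_t)`` cells of each type are sampled without
    replacement; the bulk profile is the per-gene sum over sampled
    cells. Returns (bulk profile, realized proportions).
    """
    if m.normalized is None:
        raise ValueError("normalized layer required")
    total_p = sum(proportions.values())
    if not np.isclose(total_p, 1.0, atol=1e-6):
        raise ValueError(f"proportions sum to {total_p}, expected 1")
    labels = pd.Series(np.asarray(type_labels), index=m.barcodes)
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    realized: dict[str, float] = {}
    for t, p in proportions.items():
        k = int(round(n_cells * p))
        realized[t] = k
        if k == 0:
            continue
        pool = np.flatnonzero((labels == t).to_numpy())
        if pool.size < k:
            raise ValueError(f"not enough cells of type {t!r}: need {k}, have {pool.size}")
        rows.append(rng.choice(pool, size=k, replace=False))
    total = sum(realized.values())
    realized = {t: k / total for t, k in realized.items()}
    idx = np.concatenate(rows)
    bulk = pd.Series(m.normalized[idx].sum(axis=0), index=m.gene_names)
    return bulk, realized


def deconvolve(
    bulk: pd.Series,
    sig: SignatureMatrix,
    weight_floor: float = 1e-2,
    linearize_log2: bool = False,
    renorm_other_below: float = 0.05,
) -> ProportionEstimate:
    """Weighted nonnegative least squares with sum(p) <= 1.

    The bulk vector is restricted to signature genes (missing genes
    dropped), optionally un-logged from the log2(x+1) scale, and
    rescaled to the reference's per-gene magnitude. Per-gene weights are
    inverse squared variability (floored). When the unexplained mass is
    below ``renorm_other_below`` the reported proportions are
    renormalized to sum to 1.
    """
    genes = [g for g in sig.genes if g in bulk.index]
    if len(genes) < len(sig.types):
        raise ValueError("fewer signature genes in bulk than cell types")
    s = sig.means.loc[genes].to_numpy()
    if np.linalg.matrix_rank(s) < len(sig.types):
        raise ValueError("signature matrix is rank-deficient; merge duplicated type profiles")
    b = bulk.loc[genes].to_numpy(dtype=float)
    if linearize_log2:
        b = np.power(2.0, b) - 1.0
    # match magnitudes: scale bulk so its total equals the mean type total
    scale = s.sum(axis=0).mean() / max(b.sum(), 1e-12)
    b = b * scale

    sd = sig.sds.loc[genes].to_numpy().mean(axis=1)
    w = 1.0 / np.maximum(sd, weight_floor) ** 2
    sw = np.sqrt(w)
    aw = s * sw[:, None]

    def _solve(bw: np.ndarray) -> np.ndarray:
        p, _ = optimize.nnls(aw, bw)
        if p.sum() > 1.0 + 1e-9:
            # constraint active: project onto the simplex face via SLSQP
            res = optimize.minimize(
                lambda x: 0.5 * np.sum((aw @ x - bw) ** 2),
                x0=p / p.sum(),
                jac=lambda x: aw.T @ (aw @ x - bw),
                bounds=[(0.0, None)] * p.size,
                constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                              "jac": lambda x: -np.ones_like(x)}],
                method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-14},
            )
            p = np.clip(res.x, 0.0, None)
        return p

    bw = b * sw
    p = _solve(bw)
    # the global bulk scale is a nuisance parameter: refit once with the
    # scale implied by the first solution
    if 0 < p.sum() <= 1.0:
        bw = bw / p.sum()
        p = _solve(bw)
    residual = float(np.linalg.norm(aw @ p - bw))
    other = float(max(1.0 - p.sum(), 0.0))
    report = p.copy()
    if other < renorm_other_below and p.sum() > 0:
        report = p / p.sum()
    return ProportionEstimate(
        proportions=pd.Series(report, index=sig.types),
        residual_norm=residual,
        other=other,
    )


def deconvolve_cohort(bulk: pd.DataFrame, sig: SignatureMatrix, **kw) -> pd.DataFrame:
    """Deconvolve every column of a genes x samples bulk matrix."""
    rows = {c: deconvolve(bulk[c], sig, **kw).proportions for c in bulk.columns}
    return pd.DataFrame(rows).T


def evaluate_recovery(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Per-type Pearson R between estimated and true proportions."""
    if len(estimates) < 10:
        raise ValueError("need at least 10 mixture samples")
    truth = truth.loc[estimates.index]
    out = {}
    for t in estimates.columns:
        if t not in truth.columns or truth[t].std() == 0:
            warnings.warn(f"type {t!r} skipped (absent or zero-variance truth)", stacklevel=2)
            continue
        out[t] = float(stats.pearsonr(estimates[t], truth[t])[0])
    return pd.Series(out, name="pearson_r")
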