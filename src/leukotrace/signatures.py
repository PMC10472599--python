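"""Signature scoring: per-cell module scores, the 17-gene weighted
stemness score, GSEA with permutation NES/FDR, the chemoresistance
threshold call, resistant-vs-sensitive DEGs and CD69 positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellMatrix
from .preprocess import wilcoxon_de

__all__ = [
    "LSC17_COEFFICIENTS",
    "EnrichmentResult",
    "module_score",
    "lsc17_score",
    "split_by_median",
    "gsea",
    "gsea_multi",
    "call_chemoresistant",
    "resistant_vs_sensitive_degs",
    "cd69_positive_fraction",
]

# 17-gene stemness score weights (published formula, applied to scaled data)
LSC17_COEFFICIENTS: dict[str, float] = {
    "DNMT3B": 0.0874,
    "ZBTB46": -0.0347,
    "NYNRIN": 0.00865,
    "ARHGAP22": -0.0138,
    "LAPTM4B": 0.00582,
    "MMRN1": 0.0258,
    "DPYSL3": 0.0284,
    "KIAA0125": 0.0196,
    "CDK6": -0.0704,
    "CPXM1": -0.0258,
    "SOCS2": 0.0271,
    "SMIM24": -0.0226,
    "EMP1": 0.0146,
    "NGFRAP1": 0.0465,
    "CD34": 0.0338,
    "AKR1C3": -0.0402,
    "GPR56": 0.0501,
}


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    name: str = ""


def module_score(
    m: CellMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score: member mean minus bin-matched control mean.

    Genes are binned by dataset-wide mean normalized expression; for
    each member gene, up to ``n_ctrl`` control genes are drawn from the
    non-member genes of its bin (seeded); the score is mean member
    expression minus mean control expression per cell. Excluding members
    from the control pool keeps the score exactly linear in member
    expression shifts.
    """
    if m.normalized is None:
        raise ValueError("normalized layer required")
    members = [g for g in gene_set if m.has_gene(g)]
    if not members:
        raise ValueError("no signature gene present in the matrix")
    rng = np.random.default_rng(seed)
    mean_expr = m.normalized.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum(np.arange(m.n_genes) * n_bins // m.n_genes, n_bins - 1)

    member_cols = np.array([m.gene_idx(g) for g in members])
    member_set = set(member_cols.tolist())
    ctrl_cols: list[int] = []
    for j in member_cols:
        pool = np.array([k for k in np.flatnonzero(bins == bins[j]) if k not in member_set])
        if pool.size == 0:
            continue
        ctrl_cols.extend(rng.choice(pool, size=min(n_ctrl, pool.size), replace=False))
    ctrl_cols = np.unique(ctrl_cols)
    if ctrl_cols.size == 0:
        raise ValueError("no control genes available outside the signature")
    return m.normalized[:, member_cols].mean(axis=1) - m.normalized[:, ctrl_cols].mean(axis=1)


def lsc17_score(expr: dict[str, float] | pd.Series) -> float:
    """Weighted 17-gene score on scaled expression values.

    Missing genes contribute 0 with a warning; coefficients are fixed.
    """
    if isinstance(expr, pd.Series):
        expr = expr.to_dict()
    missing = [g for g in LSC17_COEFFICIENTS if g not in expr]
    if missing:
        warnings.warn(f"missing score genes treated as 0: {missing}", stacklevel=2)
    return float(sum(c * float(expr.get(g, 0.0)) for g, c in LSC17_COEFFICIENTS.items()))


def lsc17_scores_cohort(expression: pd.DataFrame) -> pd.Series:
    """Per-patient scores from a genes x patients matrix.

    Each available score gene is z-scored across patients before the
    weighted sum (the 'scaled data' convention).
    """
    scores = pd.Series(0.0, index=expression.columns)
    for g, c in LSC17_COEFFICIENTS.items():
        if g not in expression.index:
            warnings.warn(f"score gene {g} absent from cohort matrix", stacklevel=2)
            continue
        v = expression.loc[g].astype(float)
        sd = v.std(ddof=0)
        z = (v - v.mean()) / sd if sd > 0 else v * 0.0
        scores += c * z
    return scores


def split_by_median(scores: pd.Series) -> pd.Series:
    """Median split: strictly above the median is 'high', else 'low'."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to split")
    med = float(scores.median())
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _running_es(stats_sorted: np.ndarray, hit_mask: np.ndarray, weight_exp: float):
    """Classic weighted Kolmogorov–Smirnov running sum; returns (ES, curve)."""
    n = stats_sorted.size
    nh = int(hit_mask.sum())
    w = np.abs(stats_sorted) ** weight_exp
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total <= 0:
        w_hit = hit_mask.astype(float)
        total = float(nh)
    step_hit = w_hit / total
    step_miss = np.where(hit_mask, 0.0, 1.0 / (n - nh)) if n > nh else np.zeros(n)
    curve = np.cumsum(step_hit - step_miss)
    es = curve[np.argmax(np.abs(curve))]
    return float(es), curve


def _es_for_positions(n: int, weight: np.ndarray, positions: np.ndarray) -> float:
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    nh = positions.size
    w_hit = np.where(hit, weight, 0.0)
    total = w_hit.sum()
    if total <= 0:
        w_hit = hit.astype(float)
        total = float(nh)
    miss = np.where(hit, 0.0, 1.0 / (n - nh)) if n > nh else np.zeros(n)
    curve = np.cumsum(w_hit / total - miss)
    return float(curve[np.argmax(np.abs(curve))])


def gsea(
    ranked: pd.Series,
    gene_set,
    weight_exp: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Single-set GSEA with a gene-label permutation null.

    ``ranked`` maps gene to ranking statistic (sorted internally,
    descending). ES is the running-sum extremum; NES divides by the mean
    |null ES| of the same sign; the nominal p is one-sided on the
    same-sign null. The single-set FDR equals the nominal p here; use
    :func:`gsea_multi` for the cross-set FDR.
    """
    res = gsea_multi(ranked, {"set": list(gene_set)}, weight_exp=weight_exp,
                     n_perm=n_perm, seed=seed)
    row = res.iloc[0]
    return EnrichmentResult(es=row["es"], nes=row["nes"], p=row["p"], fdr=row["fdr"],
                            leading_edge=row["leading_edge"], name=row.name)


def gsea_multi(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    weight_exp: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA over several gene sets with a pooled permutation FDR.

    The null permutes gene labels (set positions) per set; FDR for a set
    with NES* is the fraction of pooled same-sign null NES at least as
    extreme, divided by the corresponding fraction among observed NES,
    clipped to [0, 1].
    """
    ranked = pd.Series(ranked).astype(float)
    if not np.isfinite(ranked.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    ranked = ranked.sort_values(ascending=False, kind="stable")
    genes = ranked.index.to_numpy()
    stats_sorted = ranked.to_numpy()
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    weight = np.abs(stats_sorted) ** weight_exp
    rng = np.random.default_rng(seed)

    rows, null_nes_pool = [], []
    for name, members in gene_sets.items():
        positions = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        if positions.size < 2 and len(gene_sets) == 1 and positions.size == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the ranked list")
        if positions.size == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the ranked list")
        hit = np.zeros(n, dtype=bool)
        hit[positions] = True
        es, curve = _running_es(stats_sorted, hit, weight_exp)
        peak = int(np.argmax(np.abs(curve)))
        if es >= 0:
            leading = [g for g in genes[: peak + 1] if gene_pos[g] in set(positions)]
        else:
            leading = [g for g in genes[peak:] if gene_pos[g] in set(positions)]

        null = np.array([
            _es_for_positions(n, weight, rng.choice(n, size=positions.size, replace=False))
            for _ in range(n_perm)
        ])
        same = null[null >= 0] if es >= 0 else -null[null < 0]
        mean_same = same.mean() if same.size else np.nan
        nes = es / mean_same if same.size and mean_same > 0 else np.sign(es) * abs(es)
        p = ((same >= abs(es)).sum() + 1) / (same.size + 1) if same.size else 1.0
        # normalize the full null per set for the pooled FDR: positive and
        # negative branches each scaled by their own mean magnitude
        pos, neg = null[null >= 0], null[null < 0]
        branch = []
        if pos.size:
            branch.append(pos / pos.mean())
        if neg.size:
            branch.append(neg / abs(neg).mean())
        null_nes_pool.append(np.concatenate(branch) if branch else np.empty(0))
        rows.append({"name": name, "es": es, "nes": float(nes), "p": float(p),
                     "leading_edge": leading})

    df = pd.DataFrame(rows).set_index("name")
    pool = np.concatenate([x for x in null_nes_pool if x.size]) if null_nes_pool else np.empty(0)
    obs = df["nes"].to_numpy()
    fdrs = []
    for nes in obs:
        if pool.size == 0:
            fdrs.append(df.loc[df["nes"] == nes, "p"].iloc[0])
            continue
        if nes >= 0:
            frac_null = (pool >= nes).mean()
            frac_obs = max((obs >= nes).mean(), 1.0 / obs.size)
        else:
            frac_null = (pool <= nes).mean()
            frac_obs = max((obs <= nes).mean(), 1.0 / obs.size)
        fdrs.append(min(frac_null / frac_obs, 1.0))
    df["fdr"] = fdrs
    return df


def call_chemoresistant(
    enrichments: pd.DataFrame, nes_min: float = 1.9, fdr_max: float = 0.001
) -> pd.Series:
    """Boolean call per row: NES strictly above nes_min AND FDR strictly below fdr_max."""
    return (enrichments["nes"] > nes_min) & (enrichments["fdr"] < fdr_max)


def resistant_vs_sensitive_degs(
    m: CellMatrix,
    patient_ids: pd.Series,
    patient_groups: dict[str, str],
    min_pct: float = 0.3,
    lfc_min: float = 0.3,
    max_p: float = 1e-10,
    max_q: float = 0.01,
    min_consistent: int = 2,
) -> pd.DataFrame:
    """DEGs between resistant and sensitive patient groups with
    per-patient consistency.

    Pooled resistant-vs-sensitive Wilcoxon DE is thresholded at the
    stated cutoffs; a gene is kept only if, among patients of the group
    it favors (resistant for up, sensitive for down), at least
    ``min_consistent`` have a same-sign fold change of their own cells
    against the pooled opposite group.
    """
    groups = pd.Series(patient_groups)
    res_patients = groups.index[groups == "resistant"].tolist()
    sen_patients = groups.index[groups == "sensitive"].tolist()
    if min(len(res_patients), len(sen_patients)) < 2:
        raise ValueError("need at least 2 patients per group")
    pid = pd.Series(np.asarray(patient_ids), index=m.barcodes)
    res_mask = pid.isin(res_patients).to_numpy()
    sen_mask = pid.isin(sen_patients).to_numpy()
    de = wilcoxon_de(m, res_mask, sen_mask, min_pct=min_pct, lfc_min=lfc_min)
    de = de[(de["p"] < max_p) & (de["q"] < max_q)]
    if de.empty:
        return de.assign(n_consistent=pd.Series(dtype=int))

    # per-patient fold change vs the pooled opposite group
    def _patient_lfc(patients: list[str], other_mask: np.ndarray) -> pd.DataFrame:
        out = {}
        mean_other = np.expm1(m.normalized[other_mask]).mean(axis=0)
        for p in patients:
            pm = (pid == p).to_numpy()
            mean_p = np.expm1(m.normalized[pm]).mean(axis=0)
            out[p] = np.log((mean_p + 1.0) / (mean_other + 1.0))
        return pd.DataFrame(out, index=m.gene_names)

    lfc_res = _patient_lfc(res_patients, sen_mask)
    lfc_sen = _patient_lfc(sen_patients, res_mask)
    keep, n_cons = [], []
    for g, row in de.iterrows():
        if row["lfc"] > 0:
            consistent = int((lfc_res.loc[g] > 0).sum())
        else:
            consistent = int((lfc_sen.loc[g] > 0).sum())
        keep.append(consistent >= min_consistent)
        n_cons.append(consistent)
    out = de[np.asarray(keep)].copy()
    out["n_consistent"] = np.asarray(n_cons)[np.asarray(keep)]
    return out


def cd69_positive_fraction(m: CellMatrix, population, gene: str = "CD69") -> float:
    """Fraction of the population expressing the gene (normalized > 0)."""
    if not m.has_gene(gene):
        raise KeyError(f"gene {gene!r} absent from matrix")
    pop = list(population)
    if not pop:
        raise ValueError("empty population")
    layer = "normalized" if m.normalized is not None else "counts"
    vals = pd.Series(m.gene_values(gene, layer), index=m.barcodes).loc[pop]
    return float((vals > 0).mean())
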