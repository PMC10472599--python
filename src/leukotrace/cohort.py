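"""Patient-level cohort statistics: filtering, CD69+ stratification,
Fisher exact tests, MRD rates, bulk DEGs, Kaplan–Meier/log-rank and the
Cox proportional-hazards contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

__all__ = [
    "StratificationRule",
    "filter_cohort",
    "stratify_by_cd69",
    "fisher_exact_2x2",
    "mrd_positivity",
    "bulk_deg",
    "km_curve",
    "km_logrank",
    "cox_model",
]


@dataclass
class StratificationRule:
    high_cutoff: float = 0.25
    low_cutoff: float = 0.10
    target_column: str = "cd69_hsc_fraction"

    def __post_init__(self) -> None:
        if not self.low_cutoff < self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")


def filter_cohort(records: pd.DataFrame, min_blast: float = 60.0,
                  exclude_fab: tuple[str, ...] = ("M3",)) -> pd.DataFrame:
    """Keep non-repetitive high-blast patients, excluding listed FAB subtypes.

    Blast percentage must be strictly above ``min_blast``; duplicate
    patient ids keep the first occurrence.
    """
    out = records[records["blast_pct"] > min_blast]
    out = out[~out["fab"].isin(exclude_fab)]
    return out[~out.index.duplicated(keep="first")]


def stratify_by_cd69(records: pd.DataFrame, rule: StratificationRule | None = None) -> pd.Series:
    """Label patients high/middle/low by the target proportion column."""
    rule = rule or StratificationRule()
    frac = records[rule.target_column].astype(float)
    labels = np.where(frac > rule.high_cutoff, "high",
                      np.where(frac < rule.low_cutoff, "low", "middle"))
    return pd.Series(labels, index=records.index, name="cd69_group")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by probability-mass ordering.

    Sums hypergeometric probabilities (margins fixed) of all tables
    whose probability is at most the observed one, with a 1+1e-7
    relative tolerance. Returns (p, odds ratio); the odds ratio is the
    sample ad/bc with 0/0 reported as NaN and x/0 as inf.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("all margins must be positive for testing")
    kmin = max(0, c1 - (n - r1))
    kmax = min(c1, r1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    return min(p, 1.0), odds


def mrd_positivity(records: pd.DataFrame, groups: pd.Series, cutoff: float = 0.1
                   ) -> tuple[pd.DataFrame, float]:
    """Per-group MRD-positive counts/rates and the Fisher p between
    the high and low groups. MRD-positive means MRD percentage >= cutoff.
    """
    pos = records["mrd_pct"].astype(float) >= cutoff
    rows = []
    for g in ("high", "low"):
        sel = groups == g
        rows.append({"group": g, "positive": int(pos[sel].sum()), "total": int(sel.sum()),
                     "rate": float(pos[sel].mean()) if sel.any() else np.nan})
    summary = pd.DataFrame(rows).set_index("group")
    table = np.array([
        [summary.loc["high", "positive"], summary.loc["high", "total"] - summary.loc["high", "positive"]],
        [summary.loc["low", "positive"], summary.loc["low", "total"] - summary.loc["low", "positive"]],
    ])
    if (table.sum(axis=0) == 0).any():  # all-positive or all-negative cohort
        return summary, 1.0
    p, _ = fisher_exact_2x2(table)
    return summary, p


def bulk_deg(
    bulk: pd.DataFrame,
    groups: pd.Series,
    min_fold: float = 1.3,
    max_p: float = 0.01,
    max_q: float = 0.05,
    linearize_log2: bool = True,
) -> pd.DataFrame:
    """Rank-sum DEGs between high and low patient groups on bulk data.

    ``bulk`` is genes x patients (log2(x+1) scale unless
    ``linearize_log2`` is False). Keeps genes with linear fold change
    >= min_fold in either direction, p < max_p, BH q < max_q.
    """
    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    hi = [p for p in hi if p in bulk.columns]
    lo = [p for p in lo if p in bulk.columns]
    if min(len(hi), len(lo)) < 3:
        raise ValueError("need at least 3 patients per group")
    x = bulk[hi].to_numpy(dtype=float)
    y = bulk[lo].to_numpy(dtype=float)
    if linearize_log2:
        x = np.power(2.0, x) - 1.0
        y = np.power(2.0, y) - 1.0
    fold = (x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0)
    pvals = np.ones(bulk.shape[0])
    for i in range(bulk.shape[0]):
        if np.all(x[i] == x[i][0]) and np.all(y[i] == y[i][0]) and x[i][0] == y[i][0]:
            continue
        pvals[i] = stats.mannwhitneyu(x[i], y[i], alternative="two-sided").pvalue
    q = bh_adjust(pvals)
    df = pd.DataFrame({"fold": fold, "p": pvals, "q": q,
                       "direction": np.where(fold >= 1.0, "up", "down")},
                      index=bulk.index)
    passing = ((df["fold"] >= min_fold) | (df["fold"] <= 1.0 / min_fold)) \
        & (df["p"] < max_p) & (df["q"] < max_q)
    return df[passing]


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate (deaths precede censorings at ties)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [{"time": 0.0, "survival": 1.0, "at_risk": t.size, "events": 0}]
    s = 1.0
    for ti in np.unique(t[e]):
        n_at_risk = int((t >= ti).sum())
        d = int(((t == ti) & e).sum())
        s *= 1.0 - d / n_at_risk
        rows.append({"time": float(ti), "survival": s, "at_risk": n_at_risk, "events": d})
    return pd.DataFrame(rows)


def km_logrank(times, events, groups) -> tuple[dict[str, pd.DataFrame], float, float]:
    """KM curves per group plus the standard 1-df log-rank test.

    Returns ({group: curve}, chi-square, p).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("empty group")
    if not e.any():
        raise ValueError("need at least one event")
    curves = {str(lab): km_curve(t[g == lab], e[g == lab]) for lab in labels}

    o_minus_e, var = 0.0, 0.0
    in0 = g == labels[0]
    for ti in np.unique(t[e]):
        at = t >= ti
        n = int(at.sum())
        n0 = int((at & in0).sum())
        d = int(((t == ti) & e).sum())
        d0 = int(((t == ti) & e & in0).sum())
        if n == 0 or d == 0:
            continue
        exp0 = d * n0 / n
        o_minus_e += d0 - exp0
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return curves, float(chi2), p


def cox_model(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "os_time",
    event_col: str = "os_event",
    entry_p: float = 0.10,
    max_corr: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate Cox fits per covariate, then one multivariate fit.

    Covariates with univariate Wald p < ``entry_p`` enter the
    multivariate model; of any pair correlated beyond ``max_corr`` only
    the first (by univariate p) is kept. Non-converging covariates are
    flagged and excluded. Returns (univariate table, multivariate
    table — empty if nothing qualifies). Ties handled by Efron's method
    (lifelines default).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    uni_rows = []
    for cov in covariates:
        df = records[[time_col, event_col, cov]].dropna().astype(float)
        try:
            f = CoxPHFitter()
            f.fit(df, duration_col=time_col, event_col=event_col)
            s = f.summary.loc[cov]
            uni_rows.append({"covariate": cov, "hr": float(s["exp(coef)"]),
                            "ci_low": float(s["exp(coef) lower 95%"]),
                            "ci_high": float(s["exp(coef) upper 95%"]),
                            "p": float(s["p"]), "converged": True})
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"univariate Cox failed for {cov!r}: {err}", stacklevel=2)
            uni_rows.append({"covariate": cov, "hr": np.nan, "ci_low": np.nan,
                            "ci_high": np.nan, "p": np.nan, "converged": False})
    uni = pd.DataFrame(uni_rows).set_index("covariate")

    selected = uni[(uni["p"] < entry_p) & uni["converged"]].sort_values("p").index.tolist()
    # prune strongly correlated covariates, keeping the smaller univariate p
    pruned: list[str] = []
    for cov in selected:
        if all(abs(records[cov].astype(float).corr(records[kept].astype(float))) <= max_corr
               for kept in pruned):
            pruned.append(cov)
    if not pruned:
        return uni, pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
    n_events = int(records[event_col].astype(bool).sum())
    if n_events < 10:
        warnings.warn("fewer than 10 events; multivariate fit skipped", stacklevel=2)
        return uni, pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
    df = records[[time_col, event_col] + pruned].dropna().astype(float)
    f = CoxPHFitter()
    f.fit(df, duration_col=time_col, event_col=event_col)
    multi = pd.DataFrame(
        {
            "hr": f.summary["exp(coef)"],
            "ci_low": f.summary["exp(coef) lower 95%"],
            "ci_high": f.summary["exp(coef) upper 95%"],
            "p": f.summary["p"],
        }
    )
    multi.index.name = "covariate"
    return uni, multi
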