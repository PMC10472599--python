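"""Leukemic-cell classification by anchored co-clustering composition.

Paired pre/post-therapy patient samples are pooled with a healthy
reference; clusters dominated (strictly more than a threshold fraction,
default 80%) by pre-therapy cells are called leukemic. Post-therapy
cells inside leukemic clusters are residual disease. Clusters whose
majority projected type is a mature lymphoid lineage are revised back to
normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CellMatrix, concat_matrices

__all__ = [
    "MalignancyCall",
    "compose_anchor_set",
    "call_leukemic_clusters",
    "revise_lymphoid",
    "summarize_residual",
]

ORIGINS = ("healthy", "pre", "post")
DEFAULT_LYMPHOID = frozenset({"B", "CTL", "NK", "T"})


@dataclass
class MalignancyCall:
    per_cluster: pd.DataFrame  # index cluster; fraction_pre, n_cells, call, projected_majority_type
    per_cell: pd.DataFrame  # index barcode; cluster, origin, call

    @property
    def leukemic_cells(self) -> set[str]:
        df = self.per_cell
        return set(df.index[df["call"] == "leukemic"])


def compose_anchor_set(
    healthy: CellMatrix, pre: CellMatrix, post: CellMatrix
) -> tuple[CellMatrix, pd.Series]:
    """Concatenate the three samples on their shared gene namespace.

    Returns the pooled matrix and per-cell origin labels aligned to it.
    """
    pooled = concat_matrices([healthy, pre, post])
    origins = pd.Series(
        ["healthy"] * healthy.n_cells + ["pre"] * pre.n_cells + ["post"] * post.n_cells,
        index=pooled.barcodes,
        name="origin",
    )
    pooled.cell_meta = pooled.cell_meta.assign(origin=origins.to_numpy())
    return pooled, origins


def call_leukemic_clusters(
    clusters: np.ndarray,
    origins: pd.Series,
    threshold: float = 0.8,
    min_cluster_size: int = 10,
) -> MalignancyCall:
    """Call clusters leukemic when strictly >threshold of cells are pre-therapy.

    Every cell in a leukemic cluster inherits the leukemic call,
    including post-therapy cells (residual disease). Clusters smaller
    than ``min_cluster_size`` are never called leukemic.
    """
    clusters = np.asarray(clusters)
    if clusters.size != len(origins):
        raise ValueError("clusters and origins must cover the same cells")
    bad = set(origins.unique()) - set(ORIGINS)
    if bad:
        raise ValueError(f"unknown origin labels: {sorted(bad)}")

    per_cell = pd.DataFrame({"cluster": clusters, "origin": origins.to_numpy()}, index=origins.index)
    rows = []
    for cl, grp in per_cell.groupby("cluster"):
        frac_pre = float((grp["origin"] == "pre").mean())
        call = "leukemic" if (frac_pre > threshold and len(grp) >= min_cluster_size) else "normal"
        rows.append({"cluster": cl, "fraction_pre": frac_pre, "n_cells": len(grp),
                     "projected_majority_type": None, "call": call})
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    per_cell["call"] = per_cluster["call"].reindex(per_cell["cluster"]).to_numpy()
    return MalignancyCall(per_cluster=per_cluster, per_cell=per_cell)


def revise_lymphoid(
    call: MalignancyCall,
    cluster_majority_type: dict | pd.Series,
    lymphoid_types=DEFAULT_LYMPHOID,
) -> MalignancyCall:
    """Revise leukemic clusters resembling mature lymphoid cells to normal.

    ``cluster_majority_type`` maps cluster id to its majority projected
    type; projections must cover every leukemic cluster. The revision
    never converts normal clusters to leukemic and is idempotent.
    """
    majority = pd.Series(cluster_majority_type)
    per_cluster = call.per_cluster.copy()
    leuk = per_cluster.index[per_cluster["call"] == "leukemic"]
    missing = [c for c in leuk if c not in majority.index]
    if missing:
        raise ValueError(f"missing projected type for leukemic clusters: {missing}")
    lymphoid = {str(t) for t in lymphoid_types}
    per_cluster["projected_majority_type"] = majority.reindex(per_cluster.index)
    revised = [c for c in leuk if str(majority[c]).removesuffix("-like") in lymphoid]
    per_cluster.loc[revised, "call"] = "normal"
    per_cell = call.per_cell.copy()
    per_cell["call"] = per_cluster["call"].reindex(per_cell["cluster"]).to_numpy()
    return MalignancyCall(per_cluster=per_cluster, per_cell=per_cell)


def summarize_residual(call: MalignancyCall) -> pd.DataFrame:
    """Per-origin leukemic counts and fractions (pre and post)."""
    rows = []
    for origin in ("pre", "post"):
        sub = call.per_cell[call.per_cell["origin"] == origin]
        n_leuk = int((sub["call"] == "leukemic").sum())
        total = len(sub)
        rows.append({"origin": origin, "leukemic": n_leuk, "total": total,
                     "fraction": n_leuk / total if total else 0.0})
    return pd.DataFrame(rows).set_index("origin")
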