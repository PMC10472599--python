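"""Core cells-by-genes container shared by every pipeline stage.

The container is deliberately lightweight: a dense integer ``counts``
layer, an optional ``normalized`` layer (depth-10,000 log1p scale), a
gene-name list, and a per-cell metadata table indexed by barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellMatrix", "concat_matrices"]


@dataclass
class CellMatrix:
    """Cells x genes expression matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Dense ``(n_cells, n_genes)`` array of nonnegative integers.
    gene_names
        Unique gene identifiers, one per column.
    cell_meta
        Per-cell table indexed by barcode. Standard columns: ``sample_id``,
        ``timepoint`` and, when known, truth columns (``true_type``,
        ``malignant``, ``mutant``, ``doublet_flag``).
    normalized
        Optional ``(n_cells, n_genes)`` float layer where entry ``(c, g)``
        is ``ln(1 + counts[c, g] / total_c * 10000)``.
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_meta: pd.DataFrame
    normalized: np.ndarray | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes array")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length does not match counts columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if len(self.cell_meta) != self.counts.shape[0]:
            raise ValueError("cell_meta rows do not match counts rows")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValueError("normalized layer shape mismatch")
        self.gene_names = list(self.gene_names)
        self._gene_index = {g: i for i, g in enumerate(self.gene_names)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def gene_idx(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str, layer: str = "normalized") -> np.ndarray:
        """Per-cell values for one gene from the requested layer."""
        j = self.gene_idx(gene)
        arr = self._layer(layer)
        return arr[:, j]

    def _layer(self, layer: str) -> np.ndarray:
        if layer == "counts":
            return self.counts
        if layer == "normalized":
            if self.normalized is None:
                raise ValueError("normalized layer not computed; run normalize() first")
            return self.normalized
        raise ValueError(f"unknown layer {layer!r}")

    # -- subsetting --------------------------------------------------------
    def subset_cells(self, mask_or_index) -> "CellMatrix":
        """Row subset preserving order; accepts boolean mask or positions."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            counts=self.counts[idx],
            gene_names=self.gene_names,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            normalized=None if self.normalized is None else self.normalized[idx],
        )

    def subset_genes(self, genes: list[str]) -> "CellMatrix":
        cols = [self.gene_idx(g) for g in genes]
        return CellMatrix(
            counts=self.counts[:, cols],
            gene_names=list(genes),
            cell_meta=self.cell_meta.copy(),
            normalized=None if self.normalized is None else self.normalized[:, cols],
        )

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            counts=self.counts.copy(),
            gene_names=list(self.gene_names),
            cell_meta=self.cell_meta.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
        )


def concat_matrices(matrices: list[CellMatrix], genes: list[str] | None = None) -> CellMatrix:
    """Stack matrices row-wise on a shared gene namespace.

    When ``genes`` is None the intersection of all gene lists is used,
    preserving the order of the first matrix. Raises if the intersection
    is empty. The normalized layer is dropped (it must be recomputed on
    the merged matrix if needed on the reduced namespace).
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    if genes is None:
        common = set(matrices[0].gene_names)
        for m in matrices[1:]:
            common &= set(m.gene_names)
        if not common:
            raise ValueError("empty gene intersection between matrices")
        genes = [g for g in matrices[0].gene_names if g in common]
    subs = [m.subset_genes(genes) for m in matrices]
    counts = np.vstack([s.counts for s in subs])
    meta = pd.concat([s.cell_meta for s in subs], axis=0)
    if meta.index.duplicated().any():
        meta = meta.copy()
        meta.index = [
            f"{bc}|{sid}" for bc, sid in zip(meta.index, meta.get("sample_id", range(len(meta))))
        ]
    return CellMatrix(counts=counts, gene_names=genes, cell_meta=meta)
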