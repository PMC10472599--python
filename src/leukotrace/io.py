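"""Readers and writers for the plain-text interchange formats.

Single-cell matrices travel as 10x-style triplets (matrix.mtx +
genes.tsv + barcodes.tsv) plus a metadata TSV; gene sets as GMT; read
evidence as a TSV dialect of the SAM fields we consume (with optional
real SAM input via pysam); clinical and bulk tables as TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import CellMatrix

READS_COLUMNS = [
    "read_id",
    "barcode",
    "umi",
    "gene",
    "pos",
    "clip_side",
    "clip_seq",
    "allele",
]


def write_matrix_dir(m: CellMatrix, outdir: str | os.PathLike) -> None:
    """Write counts as matrix.mtx (genes x cells, 10x layout) + TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(m.counts.T))
    pd.Series(m.gene_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    m.cell_meta.to_csv(out / "metadata.tsv", sep="\t", index_label="barcode")


def read_matrix_dir(indir: str | os.PathLike) -> CellMatrix:
    ind = Path(indir)
    counts = np.asarray(spio.mmread(str(ind / "matrix.mtx")).todense()).T
    genes = pd.read_csv(ind / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(ind / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta_path = ind / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
        meta = meta.loc[barcodes]
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CellMatrix(counts=counts.astype(np.int64), gene_names=genes, cell_meta=meta)


def write_gmt(gene_sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_reads_tsv(reads, path: str | os.PathLike) -> None:
    rows = [
        (r.read_id, r.barcode, r.umi, r.mapped_gene, r.mapped_pos, r.clip_side, r.clip_seq, r.allele)
        for r in reads
    ]
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | os.PathLike):
    from .genotype import ReadRecord

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"clip_seq": str})
    return [
        ReadRecord(
            read_id=str(r.read_id),
            barcode=str(r.barcode),
            umi=str(r.umi),
            mapped_gene=str(r.gene),
            mapped_pos=int(r.pos),
            clip_side=str(r.clip_side) or "none",
            clip_seq=str(r.clip_seq),
            allele=str(r.allele) or "none",
        )
        for r in df.itertuples(index=False)
    ]


def read_reads_sam(path: str | os.PathLike, barcode_tag: str = "CB", umi_tag: str = "UB"):
    """Extract read records from a SAM/BAM file.

    The reference name is taken as the mapped gene. Terminal soft-clips
    become clip records whose ``mapped_pos`` is the reference coordinate
    of the clip boundary (alignment start for left clips, alignment end
    for right clips) — matching the TSV dialect convention.
    """
    import pysam

    from .genotype import ReadRecord

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not aln.has_tag(barcode_tag) or not aln.has_tag(umi_tag):
                continue
            cigar = aln.cigartuples or []
            clip_side, clip_seq, pos = "none", "", aln.reference_start
            if cigar and cigar[0][0] == 4:  # leading soft-clip
                clip_side = "left"
                clip_seq = aln.query_sequence[: cigar[0][1]]
                pos = aln.reference_start
            elif cigar and cigar[-1][0] == 4:  # trailing soft-clip
                clip_side = "right"
                clip_seq = aln.query_sequence[-cigar[-1][1]:]
                pos = aln.reference_end
            records.append(
                ReadRecord(
                    read_id=aln.query_name,
                    barcode=aln.get_tag(barcode_tag),
                    umi=aln.get_tag(umi_tag),
                    mapped_gene=aln.reference_name,
                    mapped_pos=pos,
                    clip_side=clip_side,
                    clip_seq=clip_seq,
                    allele="none",
                )
            )
    return records
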