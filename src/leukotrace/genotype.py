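"""Single-cell genotype evidence: SNV assignment, fusion detection,
chrY-loss indicator, LAIP marker coexpression and concordance with
transcriptional malignancy calls.

Fusion detection applies two rules per cell:

* Rule 1 — a soft-clipped read whose clip boundary lies near the
  junction of one partner gene and whose clip sequence realigns
  (ungapped, sliding) to the other partner's junction flank.
* Rule 2 — two reads sharing the same (barcode, UMI) but mapped to the
  two different partner genes.

Mutant status is evidence-positive only: absent evidence yields
``unknown``, never ``wildtype``, for fusions (transcript dropout).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellMatrix

__all__ = [
    "ReadRecord",
    "VariantSpec",
    "FusionSpec",
    "GenotypeCall",
    "assign_snv_genotype",
    "detect_fusion_cells",
    "detect_chrY_loss",
    "detect_laip_cells",
    "concordance",
]

_VALID_NUC = set("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One barcode/UMI-tagged aligned read fragment.

    For clipped reads ``mapped_pos`` is the reference coordinate of the
    clip boundary (where the aligned segment meets the clip).
    """

    read_id: str
    barcode: str
    umi: str
    mapped_gene: str
    mapped_pos: int
    clip_side: str = "none"  # none | left | right
    clip_seq: str = ""
    allele: str = "none"  # ref | alt | none

    def __post_init__(self) -> None:
        if (self.clip_side != "none") != bool(self.clip_seq):
            raise ValueError("clip_seq must be nonempty iff clip_side != none")


@dataclass(frozen=True)
class VariantSpec:
    gene: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class FusionSpec:
    """Fusion partner pair with junction-flank sequences.

    ``flank5`` is the 5' partner's sequence immediately upstream of its
    junction; ``flank3`` the 3' partner's sequence immediately
    downstream of its junction. A junction-spanning read on the 5'
    partner right-clips into ``flank3``; on the 3' partner it left-clips
    into ``flank5``.
    """

    gene5: str
    gene3: str
    junction5: int
    junction3: int
    flank5: str
    flank3: str
    min_clip_len: int = 10
    max_junction_distance: int = 5
    min_identity: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if min(len(self.flank5), len(self.flank3)) < self.min_clip_len:
            raise ValueError("flanks must be at least min_clip_len long")


@dataclass
class GenotypeCall:
    """Per-cell genotype with supporting evidence counts."""

    calls: pd.DataFrame  # index barcode; columns genotype, ref_umis, alt_umis, junction_reads, split_umi_pairs

    def genotype(self, barcode: str) -> str:
        if barcode in self.calls.index:
            return str(self.calls.loc[barcode, "genotype"])
        return "unknown"

    @property
    def mutant_cells(self) -> set[str]:
        df = self.calls
        return set(df.index[df["genotype"] == "mutant"])


def _empty_calls(barcodes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": "unknown",
            "ref_umis": 0,
            "alt_umis": 0,
            "junction_reads": 0,
            "split_umi_pairs": 0,
        },
        index=pd.Index(barcodes, name="barcode"),
    )


def assign_snv_genotype(
    reads: list[ReadRecord], variant: VariantSpec, barcodes=None
) -> GenotypeCall:
    """Per-cell SNV genotype from allele-tagged reads.

    Distinct UMIs supporting ref/alt are counted per cell; a UMI whose
    reads carry conflicting alleles is discarded. Mutant if >=1 alt UMI,
    wildtype if no alt and >=1 ref UMI, otherwise unknown.
    """
    umi_alleles: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in reads:
        if r.allele in ("ref", "alt") and r.mapped_gene == variant.gene:
            umi_alleles[(r.barcode, r.umi)].add(r.allele)

    counts: dict[str, dict[str, int]] = defaultdict(lambda: {"ref": 0, "alt": 0})
    for (bc, _umi), alleles in umi_alleles.items():
        if len(alleles) == 1:  # conflicting UMIs are discarded
            counts[bc][next(iter(alleles))] += 1

    if barcodes is None:
        barcodes = sorted(counts)
    calls = _empty_calls(barcodes)
    for bc in calls.index:
        ref, alt = counts[bc]["ref"], counts[bc]["alt"]
        calls.loc[bc, ["ref_umis", "alt_umis"]] = [ref, alt]
        if alt >= 1:
            calls.loc[bc, "genotype"] = "mutant"
        elif ref >= 1:
            calls.loc[bc, "genotype"] = "wildtype"
    return GenotypeCall(calls=calls)


def _sliding_identity(clip: str, flank: str) -> float:
    """Best ungapped match fraction of clip inside flank (full overlap)."""
    L, F = len(clip), len(flank)
    if L == 0 or L > F:
        return 0.0
    c = np.frombuffer(clip.encode(), dtype=np.uint8)
    f = np.frombuffer(flank.encode(), dtype=np.uint8)
    best = 0.0
    for off in range(F - L + 1):
        best = max(best, float((c == f[off : off + L]).mean()))
    return best


def clip_matches_partner(read: ReadRecord, spec: FusionSpec) -> bool:
    """Rule-1 check for a single clipped read against the fusion spec."""
    if read.clip_side == "none" or len(read.clip_seq) < spec.min_clip_len:
        return False
    if read.mapped_gene == spec.gene5:
        junction, partner_flank = spec.junction5, spec.flank3
    elif read.mapped_gene == spec.gene3:
        junction, partner_flank = spec.junction3, spec.flank5
    else:
        return False
    if abs(read.mapped_pos - junction) > spec.max_junction_distance:
        return False
    return _sliding_identity(read.clip_seq, partner_flank) >= spec.min_identity


def detect_fusion_cells(
    reads: list[ReadRecord], spec: FusionSpec, barcodes=None
) -> GenotypeCall:
    """Two-rule per-cell fusion detection (see module docstring)."""
    junction_reads: dict[str, int] = defaultdict(int)
    umi_genes: dict[tuple[str, str], set[str]] = defaultdict(set)
    partner_genes = {spec.gene5, spec.gene3}
    for r in reads:
        if r.mapped_gene not in partner_genes:
            continue
        if r.clip_seq and not set(r.clip_seq.upper()) <= _VALID_NUC:
            warnings.warn(f"skipping read {r.read_id}: malformed clip sequence", stacklevel=2)
            continue
        umi_genes[(r.barcode, r.umi)].add(r.mapped_gene)
        if clip_matches_partner(r, spec):
            junction_reads[r.barcode] += 1

    split_pairs: dict[str, int] = defaultdict(int)
    for (bc, _umi), genes in umi_genes.items():
        if len(genes) == 2:
            split_pairs[bc] += 1

    if barcodes is None:
        barcodes = sorted(set(junction_reads) | {bc for bc, _ in umi_genes})
    calls = _empty_calls(barcodes)
    for bc in calls.index:
        jr, sp = junction_reads[bc], split_pairs[bc]
        calls.loc[bc, ["junction_reads", "split_umi_pairs"]] = [jr, sp]
        if jr >= 1 or sp >= 1:
            calls.loc[bc, "genotype"] = "mutant"
    return GenotypeCall(calls=calls)


def detect_chrY_loss(
    m: CellMatrix,
    indicator_gene: str = "RPS4Y1",
    population=None,
    loss_cutoff: float = 0.05,
) -> tuple[pd.Series, float, bool]:
    """Per-cell indicator-gene expression and population-level summary.

    Returns (per-cell expressed flags, fraction expressing within the
    population, loss-consistent flag at the cutoff).
    """
    if not m.has_gene(indicator_gene):
        raise KeyError(f"indicator gene {indicator_gene!r} absent from matrix")
    layer = "normalized" if m.normalized is not None else "counts"
    expressed = pd.Series(m.gene_values(indicator_gene, layer) > 0, index=m.barcodes)
    pop = expressed if population is None else expressed.loc[list(population)]
    if len(pop) == 0:
        raise ValueError("empty population")
    frac = float(pop.mean())
    return expressed, frac, frac < loss_cutoff


def detect_laip_cells(m: CellMatrix, markers: list[str]) -> set[str]:
    """Cells coexpressing every LAIP marker (all normalized values > 0)."""
    if not markers:
        raise ValueError("empty marker set")
    missing = [g for g in markers if not m.has_gene(g)]
    if missing:
        raise KeyError(f"LAIP markers absent from matrix: {missing}")
    layer = "normalized" if m.normalized is not None else "counts"
    mask = np.ones(m.n_cells, dtype=bool)
    for g in markers:
        mask &= m.gene_values(g, layer) > 0
    return set(m.barcodes[mask])


def concordance(evidence_cells, leukemic_cells) -> float:
    """Fraction of evidence-bearing cells called leukemic."""
    ev = set(evidence_cells)
    if not ev:
        raise ValueError("empty evidence cell set")
    return len(ev & set(leukemic_cells)) / len(ev)
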