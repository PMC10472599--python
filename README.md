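# leukotrace

Identification and characterization of chemoresistant leukemic cells from
paired pre-/post-chemotherapy single-cell transcriptomes, exercised
end-to-end on synthetic data with known ground truth.

The pipeline covers:

- **`leukotrace.synthetic`** — generation of every input with ground truth:
  a hematopoietic type catalog with disjoint marker-gene blocks
  (negative-binomial counts, log-normal library sizes), healthy reference
  samples, paired pre/post patient samples whose malignant cells carry a
  shared leukemia expression program and a configurable CD69⁺ HSC-like
  subfraction, barcode/UMI read evidence for SNV and fusion genotyping,
  and bulk cohorts with proportions, MRD and survival outcomes linked to
  the CD69⁺ HSC-like fraction.
- **`leukotrace.preprocess`** — QC filtering, depth-10,000 log1p
  normalization, variable-gene selection, the explained-variance PC-count
  heuristic, SNN-graph Leiden clustering, and a Wilcoxon rank-sum DE
  primitive (exact for small untied groups, tie-corrected normal
  approximation otherwise).
- **`leukotrace.malignancy`** — co-clustering of healthy/pre/post samples
  and the cluster-composition rule: clusters with strictly more than 80%
  pre-therapy cells are leukemic; post-therapy cells in those clusters are
  residual disease; mature-lymphoid clusters are revised back to normal.
- **`leukotrace.projection`** — nearest-centroid cosine projection onto a
  marker-based healthy reference, with "-like" labels for malignant cells.
- **`leukotrace.genotype`** — per-cell SNV genotyping from UMI-deduplicated
  allele counts, two-rule fusion detection (junction soft-clip realignment
  and split-UMI partner pairs), chrY-loss via the RPS4Y1 indicator, LAIP
  marker coexpression, and concordance with transcriptional calls.
- **`leukotrace.signatures`** — per-cell module scores with bin-matched
  controls, the 17-gene weighted stemness score, GSEA with permutation
  NES/FDR, the NES/FDR chemoresistance call, resistant-vs-sensitive DEGs
  with per-patient consistency, and CD69 positivity.
- **`leukotrace.deconvolution`** — top-300/specificity-filtered signature
  matrix over the 11 leukemic identities, pseudo-bulk construction by
  pooling cells at expected ratios, constrained weighted least-squares
  deconvolution (p ≥ 0, Σp ≤ 1), and per-type recovery correlation.
- **`leukotrace.cohort`** — cohort filtering (blast > 60%, M3 excluded),
  CD69⁺ stratification (>25% high, <10% low), an exact two-sided Fisher
  test, MRD positivity rates, bulk DEG contrasts, Kaplan–Meier/log-rank,
  and univariate→multivariate Cox modeling (entry at p < 0.10).

## CLI

```bash
leukotrace simulate --config cfg.yaml --out data/ --seed 0
leukotrace preprocess --in data/healthy --out data/healthy_qc \
    --qc-min-genes 200 --qc-min-umi 500 --qc-max-mito 0.15
leukotrace call-malignant --in data/ --out calls.tsv --threshold 0.8
leukotrace genotype --reads data/reads.tsv \
    --fusion-spec data/fusion_spec.json --variant-spec data/variant_spec.json \
    --out genotypes.tsv
leukotrace score --in data/healthy_qc --gmt sigs.gmt --out scores.tsv
leukotrace deconvolve --sig data/leukemic --bulk data/bulk.tsv --out props.tsv
leukotrace cohort --clinical data/clinical.tsv --out cohort.json \
    --high 0.25 --low 0.10 --mrd-cutoff 0.1
```

`simulate` writes MatrixMarket triplets + metadata TSVs per sample, a reads
TSV, bulk/clinical tables, and the fusion/variant specs consumed by
`genotype`.

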