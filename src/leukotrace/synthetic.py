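"""Synthetic data generation with ground truth for every pipeline stage.

Generates a hematopoietic type catalog with disjoint marker-gene blocks,
healthy reference samples, paired pre/post-therapy patient samples whose
malignant cells carry a shared leukemia expression program, barcode/UMI
read evidence for SNV and fusion genotyping, and bulk cohorts with known
type proportions and outcome variables tied to the CD69+ HSC-like
fraction.

Counts are negative-binomial with per-cell log-normal library sizes.
A fixed ``SimConfig.seed`` fully determines every output: each generator
draws from its own child stream of the config seed, so generators can be
called in any order and re-runs are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import FusionSpec, VariantSpec, ReadRecord
from .matrix import CellMatrix

__all__ = [
    "CellTypeSpec",
    "NoiseModel",
    "SimConfig",
    "GroundTruth",
    "default_type_catalog",
    "leukemic_type_catalog",
    "generate_typed_cells",
    "generate_healthy_reference",
    "generate_patient_pair",
    "generate_read_evidence",
    "generate_bulk_cohort",
]

# reserved gene names that the catalog always contains
_SPECIAL_GENES = ["CD69", "RPS4Y1", "MT-CO1", "MT-CO2", "MT-ND1", "MT-ND2", "MT-CYB", "FUSA", "FUSB"]
_MT_GENES = [g for g in _SPECIAL_GENES if g.startswith("MT-")]

_NUC = np.array(list("ACGT"))

LYMPHOID_TYPES = {"B", "CTL", "NK", "T"}


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class CellTypeSpec:
    """One cell type's expression program: a marker block at elevated mean."""

    name: str
    n_markers: int = 20
    marker_fold: float = 4.0
    markers: list[str] | None = None  # resolved against the gene panel if None
    cd69_positive: bool = False  # cells of this type get guaranteed CD69 counts


@dataclass
class NoiseModel:
    nb_dispersion: float = 2.0
    lib_size_log_mean: float = 8.0  # ln scale; exp(8) ~ 3000 UMI
    lib_size_log_sd: float = 0.25


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 1500
    type_catalog: list[CellTypeSpec] = field(default_factory=lambda: default_type_catalog())
    n_cells_per_type: int = 150
    n_cells_per_sample: int = 1500
    tumor_burden_pre: float = 0.7
    tumor_burden_post: float = 0.03
    cd69_hsc_fraction: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)
    # malignant program: a dedicated gene block shared by all leukemic cells
    leukemia_program_size: int = 50
    leukemia_program_fold: float = 4.0
    malignant_base_types: dict[str, float] = field(
        default_factory=lambda: {"HSC": 0.5, "LMPP": 0.25, "GMP": 0.25}
    )
    doublet_rate: float = 0.0
    # genotype plumbing
    male: bool = True
    rps4y1_capture: float = 0.8
    chrY_loss_in_malignant: bool = True
    snv_capture: float = 0.6
    ref_umi_rate: float = 1.5
    fusion_capture: float = 0.5
    decoy_clip_rate: float = 0.05
    fusion: FusionSpec | None = None  # built deterministically if None
    variant: VariantSpec = field(default_factory=lambda: VariantSpec(gene="FUSA", pos=250, ref="C", alt="T"))
    # bulk cohort
    cohort_size: int = 200
    dirichlet_alpha: float = 1.0
    bulk_noise_sd: float = 0.1
    hazard_link: float = 3.0
    cd69_type_name: str = "CD69+ HSC-like"
    mrd_base_logit: float = -1.0
    event_base_rate: float = 0.02
    censor_time: float = 60.0

    def __post_init__(self) -> None:
        for name in ("tumor_burden_pre", "tumor_burden_post", "cd69_hsc_fraction", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_genes < len(_SPECIAL_GENES) + 50:
            raise ConfigurationError("n_genes too small for the reserved gene panel")


@dataclass
class GroundTruth:
    """Truth labels accompanying generated data."""

    per_cell: pd.DataFrame
    per_sample: pd.DataFrame | None = None
    per_bulk: pd.DataFrame | None = None
    per_patient: pd.DataFrame | None = None
    read_truth: pd.DataFrame | None = None


def default_type_catalog() -> list[CellTypeSpec]:
    """Healthy hematopoietic hierarchy stand-in (stem/progenitor + mature)."""
    names = ["HSC", "LMPP", "GMP", "MEP", "CLP", "Mono", "Neutrophil", "cDC", "pDC", "B", "CTL", "NK"]
    return [CellTypeSpec(name=n) for n in names]


def leukemic_type_catalog() -> list[CellTypeSpec]:
    """The 11 leukemic identities used for signature building/deconvolution."""
    specs = [CellTypeSpec(name="CD69+ HSC-like", cd69_positive=True)]
    for n in [
        "CD69- HSC-like",
        "LMPP-like",
        "GMP-like",
        "MEP-like",
        "E/B/M-like",
        "CLP-like",
        "monocyte-like",
        "neutrophil-like",
        "cDC-like",
        "pDC-like",
    ]:
        specs.append(CellTypeSpec(name=n))
    return specs


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------


@dataclass
class _GenePanel:
    gene_names: list[str]
    mu: np.ndarray  # baseline relative expression rate per gene
    marker_idx: dict[str, np.ndarray]  # type name -> marker column indices
    leukemia_idx: np.ndarray
    catalog: list[CellTypeSpec]

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}


def _rng(config: SimConfig, *stream) -> np.random.Generator:
    # crc32 is stable across processes (str hash() is salted per run)
    key = [config.seed] + [zlib.crc32(str(s).encode()) for s in stream]
    return np.random.default_rng(np.random.SeedSequence(key))


def build_gene_panel(config: SimConfig, catalog: list[CellTypeSpec] | None = None) -> _GenePanel:
    """Resolve the gene namespace, baseline means and marker blocks.

    Deterministic given (config.seed, catalog): generic genes are named
    G0000... and marker blocks are carved out of the generic pool in
    catalog order. Explicit marker lists must be disjoint.
    """
    catalog = list(config.type_catalog if catalog is None else catalog)
    n_generic = config.n_genes - len(_SPECIAL_GENES)
    generic = [f"G{i:04d}" for i in range(n_generic)]
    gene_names = _SPECIAL_GENES + generic
    gidx = {g: i for i, g in enumerate(gene_names)}

    rng = _rng(config, "gene-panel")
    mu = rng.lognormal(mean=-0.5, sigma=1.0, size=config.n_genes)
    mu[gidx["CD69"]] = 0.0
    mu[gidx["RPS4Y1"]] = 0.0  # assigned post-hoc by capture model
    for g in _MT_GENES:
        mu[gidx[g]] = 15.0
    for g in ("FUSA", "FUSB"):
        mu[gidx[g]] = 2.0

    taken: set[str] = set()
    cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    resolved: list[CellTypeSpec] = []
    for spec in catalog:
        if spec.markers is not None:
            overlap = taken.intersection(spec.markers)
            if overlap:
                raise ConfigurationError(
                    f"marker block of type {spec.name!r} overlaps others: {sorted(overlap)}"
                )
            markers = list(spec.markers)
        else:
            markers = generic[cursor : cursor + spec.n_markers]
            if len(markers) < spec.n_markers:
                raise ConfigurationError("gene panel too small for requested marker blocks")
            cursor += spec.n_markers
        taken.update(markers)
        missing = [g for g in markers if g not in gidx]
        if missing:
            raise ConfigurationError(f"marker genes not in panel: {missing}")
        idx = np.array([gidx[g] for g in markers], dtype=int)
        # markers must be detectable: floor their baseline rate
        mu[idx] = np.maximum(mu[idx], 0.5)
        marker_idx[spec.name] = idx
        resolved.append(replace(spec, markers=markers))

    leu = [g for g in generic[cursor:] if g not in taken][: config.leukemia_program_size]
    if len(leu) < config.leukemia_program_size:
        raise ConfigurationError("gene panel too small for the leukemia program block")
    leukemia_idx = np.array([gidx[g] for g in leu], dtype=int)
    return _GenePanel(gene_names=gene_names, mu=mu, marker_idx=marker_idx,
                      leukemia_idx=leukemia_idx, catalog=resolved)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------


def _sample_counts(rng: np.random.Generator, rates: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """NB counts with log-normal library sizes from per-cell relative rates."""
    p = rates / rates.sum(axis=1, keepdims=True)
    libs = rng.lognormal(noise.lib_size_log_mean, noise.lib_size_log_sd, size=rates.shape[0])
    mean = p * libs[:, None]
    theta = noise.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        psucc = theta / (theta + mean)
    return rng.negative_binomial(theta, psucc).astype(np.int64)


def _cell_rates(panel: _GenePanel, spec: CellTypeSpec, config: SimConfig,
                malignant: bool = False) -> np.ndarray:
    r = panel.mu.copy()
    r[panel.marker_idx[spec.name]] *= spec.marker_fold
    if malignant:
        r[panel.leukemia_idx] *= config.leukemia_program_fold
    return r


def _force_cd69(rng: np.random.Generator, counts: np.ndarray, rows: np.ndarray, col: int) -> None:
    counts[rows, col] = 1 + rng.poisson(3.0, size=rows.size)


def _assign_rps4y1(rng: np.random.Generator, counts: np.ndarray, col: int,
                   expressed_mask: np.ndarray, capture: float) -> None:
    """RPS4Y1 counts: Bernoulli(capture) x (1 + Poisson) for eligible cells."""
    n = counts.shape[0]
    on = (rng.random(n) < capture) & expressed_mask
    counts[:, col] = 0
    counts[on, col] = 1 + rng.poisson(2.0, size=int(on.sum()))


def _make_doublets(rng: np.random.Generator, counts: np.ndarray, n_doublets: int) -> np.ndarray:
    if n_doublets == 0:
        return np.empty((0, counts.shape[1]), dtype=counts.dtype)
    i = rng.integers(0, counts.shape[0], size=n_doublets)
    j = rng.integers(0, counts.shape[0], size=n_doublets)
    return counts[i] + counts[j]


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_typed_cells(
    config: SimConfig,
    catalog: list[CellTypeSpec] | None = None,
    n_per_type: int | None = None,
    sample_id: str = "REF",
    timepoint: str = "healthy",
    stream: str = "typed-cells",
) -> tuple[CellMatrix, GroundTruth]:
    """Generate labeled cells of each catalog type (no malignant program)."""
    panel = build_gene_panel(config, catalog)
    n_per_type = config.n_cells_per_type if n_per_type is None else n_per_type
    rng = _rng(config, stream, sample_id)
    gidx = panel.gene_index

    blocks, labels, cd69_rows = [], [], []
    offset = 0
    for spec in panel.catalog:
        rates = np.tile(_cell_rates(panel, spec, config), (n_per_type, 1))
        c = _sample_counts(rng, rates, config.noise)
        blocks.append(c)
        labels.extend([spec.name] * n_per_type)
        if spec.cd69_positive:
            cd69_rows.append(np.arange(offset, offset + n_per_type))
        offset += n_per_type
    counts = np.vstack(blocks)
    if cd69_rows:
        _force_cd69(rng, counts, np.concatenate(cd69_rows), gidx["CD69"])
    _assign_rps4y1(rng, counts, gidx["RPS4Y1"],
                   np.full(counts.shape[0], config.male), config.rps4y1_capture)

    n_doub = int(round(config.doublet_rate * counts.shape[0]))
    doublets = _make_doublets(rng, counts, n_doub)
    counts = np.vstack([counts, doublets])
    labels += ["doublet"] * n_doub

    barcodes = [f"{sample_id}:C{i:05d}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "timepoint": timepoint,
            "true_type": labels,
            "malignant": False,
            "mutant": False,
            "doublet_flag": [False] * (counts.shape[0] - n_doub) + [True] * n_doub,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    m = CellMatrix(counts=counts, gene_names=panel.gene_names, cell_meta=meta)
    return m, GroundTruth(per_cell=meta.copy())


def generate_healthy_reference(config: SimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Healthy-donor reference sample across the configured type catalog."""
    names = {s.name for s in config.type_catalog}
    if len(names) < 2:
        raise ConfigurationError("need at least 2 cell types")
    required = {"HSC", "LMPP", "GMP"}
    if not required.issubset(names):
        raise ConfigurationError(f"healthy catalog must contain {sorted(required)}")
    if not names & LYMPHOID_TYPES:
        raise ConfigurationError("healthy catalog must contain a mature lymphoid type")
    return generate_typed_cells(config, sample_id="HD1", timepoint="healthy", stream="healthy")


def generate_patient_pair(config: SimConfig) -> tuple[CellMatrix, CellMatrix, GroundTruth]:
    """Paired pre/post-therapy samples with malignant '-like' cells.

    Malignant cells combine a normal base-type program with the shared
    leukemia program block; a configurable fraction of malignant
    HSC-like cells is CD69-positive (guaranteed CD69 > 0); malignant
    cells optionally lose RPS4Y1 expression (chrY loss).
    """
    if not config.tumor_burden_pre > config.tumor_burden_post:
        raise ConfigurationError("tumor_burden_pre must exceed tumor_burden_post")
    panel = build_gene_panel(config)
    gidx = panel.gene_index
    spec_by_name = {s.name: s for s in panel.catalog}
    for t in config.malignant_base_types:
        if t not in spec_by_name:
            raise ConfigurationError(f"malignant base type {t!r} not in catalog")

    rng = _rng(config, "patient-pair")
    out: dict[str, CellMatrix] = {}
    truth_frames, sample_rows = [], []
    for tp, burden in (("pre", config.tumor_burden_pre), ("post", config.tumor_burden_post)):
        n = config.n_cells_per_sample
        malignant = rng.random(n) < burden
        base_names = list(config.malignant_base_types)
        base_p = np.array(list(config.malignant_base_types.values()), dtype=float)
        base_p /= base_p.sum()
        all_types = [s.name for s in panel.catalog]
        types = np.where(
            malignant,
            rng.choice(base_names, size=n, p=base_p),
            rng.choice(all_types, size=n),
        )
        rates = np.empty((n, config.n_genes))
        for i in range(n):
            rates[i] = _cell_rates(panel, spec_by_name[types[i]], config, malignant=bool(malignant[i]))
        counts = _sample_counts(rng, rates, config.noise)

        hsc_mal = np.flatnonzero(malignant & (types == "HSC"))
        cd69_pos = np.zeros(n, dtype=bool)
        if hsc_mal.size:
            chosen = hsc_mal[rng.random(hsc_mal.size) < config.cd69_hsc_fraction]
            cd69_pos[chosen] = True
            _force_cd69(rng, counts, chosen, gidx["CD69"])
        rps_mask = np.full(n, config.male)
        if config.chrY_loss_in_malignant:
            rps_mask &= ~malignant
        _assign_rps4y1(rng, counts, gidx["RPS4Y1"], rps_mask, config.rps4y1_capture)

        sample_id = f"P1-{tp}"
        barcodes = [f"{sample_id}:C{i:05d}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "sample_id": sample_id,
                "timepoint": tp,
                "true_type": types,
                "malignant": malignant,
                "mutant": malignant,  # the founding clone genotype marks every malignant cell
                "doublet_flag": False,
                "cd69_pos": cd69_pos,
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        out[tp] = CellMatrix(counts=counts, gene_names=panel.gene_names, cell_meta=meta)
        truth_frames.append(meta.copy())
        sample_rows.append({"sample_id": sample_id, "timepoint": tp,
                            "leukemic_fraction": float(malignant.mean())})
    truth = GroundTruth(per_cell=pd.concat(truth_frames),
                        per_sample=pd.DataFrame(sample_rows).set_index("sample_id"))
    return out["pre"], out["post"], truth


def _default_fusion(config: SimConfig) -> FusionSpec:
    rng = _rng(config, "fusion-flanks")
    return FusionSpec(
        gene5="FUSA",
        gene3="FUSB",
        junction5=500,
        junction3=100,
        flank5="".join(rng.choice(_NUC, size=30)),
        flank3="".join(rng.choice(_NUC, size=30)),
    )


def _umi(base: int) -> str:
    # counter encoded base-4 as a 10-mer: unique per cell by construction
    s = []
    for _ in range(10):
        s.append("ACGT"[base % 4])
        base //= 4
    return "".join(s)


def generate_read_evidence(
    config: SimConfig, cells: CellMatrix, truth: GroundTruth
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Barcode/UMI-tagged read records carrying SNV and fusion evidence.

    Mutant cells receive alt-allele UMIs and fusion evidence (junction
    soft-clips and/or split-UMI partner pairs) at the configured capture
    rates; every cell receives ref-allele coverage; decoy soft-clips of
    random sequence are sprinkled at ``decoy_clip_rate``.
    """
    fusion = config.fusion or _default_fusion(config)
    if len(fusion.flank5) < fusion.min_clip_len or len(fusion.flank3) < fusion.min_clip_len:
        raise ConfigurationError("fusion flank shorter than min_clip_len")
    variant = config.variant
    rng = _rng(config, "reads")
    records: list[ReadRecord] = []
    truth_rows: list[dict] = []
    rid = 0

    def emit(kind: str, **kw) -> None:
        nonlocal rid
        rec = ReadRecord(read_id=f"r{rid:07d}", **kw)
        records.append(rec)
        truth_rows.append({"read_id": rec.read_id, "kind": kind, "barcode": rec.barcode})
        rid += 1

    per_cell = truth.per_cell.loc[truth.per_cell.index.intersection(cells.barcodes)]
    for barcode, row in per_cell.iterrows():
        umi_counter = int(rng.integers(0, 4**9))
        mutant = bool(row.get("mutant", False))

        # SNV coverage: ref UMIs for everyone, alt UMIs for captured mutants
        for _ in range(rng.poisson(config.ref_umi_rate)):
            emit("ref", barcode=barcode, umi=_umi(umi_counter), mapped_gene=variant.gene,
                 mapped_pos=variant.pos, clip_side="none", clip_seq="", allele="ref")
            umi_counter += 1
        if mutant and config.snv_capture > 0 and rng.random() < config.snv_capture:
            for _ in range(1 + rng.poisson(0.5)):
                emit("alt", barcode=barcode, umi=_umi(umi_counter), mapped_gene=variant.gene,
                     mapped_pos=variant.pos, clip_side="none", clip_seq="", allele="alt")
                umi_counter += 1

        # fusion evidence for captured mutants
        if mutant and config.fusion_capture > 0 and rng.random() < config.fusion_capture:
            mode = rng.choice(["rule1", "rule2", "both"])
            if mode in ("rule1", "both"):
                clip_len = int(rng.integers(fusion.min_clip_len, len(fusion.flank3) + 1))
                emit("junction_clip", barcode=barcode, umi=_umi(umi_counter),
                     mapped_gene=fusion.gene5, mapped_pos=fusion.junction5,
                     clip_side="right", clip_seq=fusion.flank3[:clip_len], allele="none")
                umi_counter += 1
            if mode in ("rule2", "both"):
                shared = _umi(umi_counter)
                umi_counter += 1
                for gene, pos in ((fusion.gene5, fusion.junction5 - 200), (fusion.gene3, fusion.junction3 + 200)):
                    emit("split_umi", barcode=barcode, umi=shared, mapped_gene=gene,
                         mapped_pos=max(pos, 0), clip_side="none", clip_seq="", allele="none")

        # background partner-gene coverage (never junction-linked)
        if rng.random() < 0.3:
            gene = fusion.gene5 if rng.random() < 0.5 else fusion.gene3
            emit("plain", barcode=barcode, umi=_umi(umi_counter), mapped_gene=gene,
                 mapped_pos=int(rng.integers(0, 400)), clip_side="none", clip_seq="", allele="none")
            umi_counter += 1

        # decoy soft-clips: random sequence near a random position
        if rng.random() < config.decoy_clip_rate:
            seq = "".join(rng.choice(_NUC, size=fusion.min_clip_len + 5))
            gene = fusion.gene5 if rng.random() < 0.5 else fusion.gene3
            junction = fusion.junction5 if gene == fusion.gene5 else fusion.junction3
            emit("decoy_clip", barcode=barcode, umi=_umi(umi_counter), mapped_gene=gene,
                 mapped_pos=junction + int(rng.integers(-3, 4)),
                 clip_side="right" if rng.random() < 0.5 else "left", clip_seq=seq, allele="none")
            umi_counter += 1

    read_truth = pd.DataFrame(truth_rows, columns=["read_id", "kind", "barcode"])
    return records, read_truth


def generate_bulk_cohort(
    config: SimConfig,
    signature_source: CellMatrix,
    proportions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Bulk cohort of proportion-weighted type mixtures with outcomes.

    Each patient's bulk profile is a Dirichlet-proportioned mixture of
    per-type mean linear expression profiles times log-normal gene noise,
    reported on the log2(x+1) scale. MRD positivity odds and event
    hazards increase with the patient's true CD69+ HSC-like fraction via
    ``hazard_link``.
    """
    if config.cohort_size < 2:
        raise ConfigurationError("cohort_size must be >= 2")
    meta = signature_source.cell_meta
    if "true_type" not in meta.columns:
        raise ConfigurationError("signature_source must carry true_type labels")
    if signature_source.normalized is None:
        from .preprocess import normalize

        signature_source = normalize(signature_source)
    linear = np.expm1(signature_source.normalized)
    types = sorted(meta["true_type"].unique())
    profiles = np.vstack([linear[(meta["true_type"] == t).to_numpy()].mean(axis=0) for t in types])

    rng = _rng(config, "bulk-cohort")
    if proportions is not None:
        proportions = proportions.reindex(columns=types).fillna(0.0)
        if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("supplied proportions must sum to 1 per patient")
        props = proportions.to_numpy(dtype=float)
        n = props.shape[0]
    else:
        n = config.cohort_size
        props = rng.dirichlet([config.dirichlet_alpha] * len(types), size=n)
    noise = rng.lognormal(0.0, config.bulk_noise_sd, size=(n, signature_source.n_genes))
    bulk_linear = props @ profiles * noise
    patient_ids = [f"PT{i:04d}" for i in range(n)]
    bulk = pd.DataFrame(
        np.log2(bulk_linear + 1.0).T, index=signature_source.gene_names, columns=patient_ids
    )

    cd69_col = types.index(config.cd69_type_name) if config.cd69_type_name in types else None
    cd69 = props[:, cd69_col] if cd69_col is not None else np.zeros(n)
    centered = cd69 - float(np.median(cd69))

    from scipy.special import expit

    p_mrd = expit(config.mrd_base_logit + config.hazard_link * centered)
    mrd_pos = rng.random(n) < p_mrd
    mrd_pct = np.where(mrd_pos, 10 ** rng.uniform(-1.0, 1.0, n), 10 ** rng.uniform(-3.0, -1.35, n))
    relapse = rng.random(n) < expit(config.mrd_base_logit + config.hazard_link * centered)

    def _surv(rate_scale: float) -> tuple[np.ndarray, np.ndarray]:
        lam = config.event_base_rate * rate_scale * np.exp(config.hazard_link * centered)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(0.25 * config.censor_time, config.censor_time, n)
        return np.minimum(t_event, t_cens), t_event <= t_cens

    os_time, os_event = _surv(1.0)
    efs_time, efs_event = _surv(1.5)

    fab = rng.choice(["M0", "M1", "M2", "M3", "M4", "M5"], size=n,
                     p=[0.1, 0.22, 0.25, 0.08, 0.2, 0.15])
    records = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "blast_pct": rng.uniform(30.0, 95.0, n),
            "fab": fab,
            "mrd_pct": mrd_pct,
            "relapse": relapse,
            "os_time": os_time,
            "os_event": os_event,
            "efs_time": efs_time,
            "efs_event": efs_event,
            "age": rng.uniform(18.0, 70.0, n),
            "wbc": rng.lognormal(2.5, 0.8, n),
            "sct": rng.random(n) < 0.3,
            "cd69_hsc_fraction": cd69,
        }
    ).set_index("patient_id")

    per_bulk = pd.DataFrame(props, index=patient_ids, columns=types)
    truth = GroundTruth(
        per_cell=pd.DataFrame(),
        per_bulk=per_bulk,
        per_patient=records[["cd69_hsc_fraction"]].copy(),
    )
    return bulk, records, truth
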