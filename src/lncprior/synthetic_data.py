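"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the *shapes* of the study's external datasets:

* a small case/control cortex RNA-seq experiment (3 cases + 3 controls,
  two technical replicates each) with planted differentially expressed
  genes under a negative-binomial noise model;
* a developmental cortex expression matrix in which co-expression modules
  are driven by latent trajectories over age, with a designated module
  jointly harbouring planted risk genes and planted lncRNAs (the
  "convergence" the downstream analysis is built to detect);
* a multi-tissue median-expression panel in which some lncRNAs have their
  brain-tissue abundance inflated so their fractional brain expression
  exceeds the 50% selectivity threshold;
* a gene annotation table on a small artificial genome, risk-gene lists,
  and a CNV table placed to overlap designated lncRNAs.

Everything is a pure function of ``(seed, config)``: each operation derives
its own random stream from the seed, so e.g. regenerating the tissue panel
never perturbs the count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CNVRecord,
    CountMatrix,
    ExpressionMatrix,
    ValidationError,
    write_annotation,
    write_cnvs,
    write_count_matrix,
    write_expression_matrix,
    write_gene_list,
)

# stream ids: one independent generator per data product
_STREAM_STRUCTURE = 0
_STREAM_COUNTS = 1
_STREAM_DEV = 2
_STREAM_TISSUE = 3
_STREAM_CNV = 4
_STREAM_ANNOT = 5


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    The defaults mirror the scale of the source study where it states one
    (3 cases and 3 controls, each with two technical replicates; ~40 tissues
    with a handful of brain tissues; four planted developmental modules),
    scaled down elsewhere so a full run takes seconds.
    """

    seed: int = 0
    n_genes: int = 1000
    n_lncRNAs: int = 150
    n_case: int = 3
    n_control: int = 3
    n_tech_reps: int = 2
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    module_sizes: tuple[int, ...] = (100, 80, 60, 40)
    module_strength: float = 0.8
    n_dev_samples: int = 120
    age_range_months: tuple[float, float] = (2.0, 480.0)
    n_tissues: int = 40
    n_brain_tissues: int = 10
    brain_inflation: float = 10.0
    n_cnvs: int = 120
    genome_length: int = 10_000_000
    n_chroms: int = 4
    # planted-convergence knobs
    n_risk_genes: int = 25
    n_risk_in_module: int = 15
    n_lnc_in_module: int = 10
    n_brain_selective: int = 20
    n_top_priority: int = 3
    cnv_hits_per_priority: int = 3

    def validate(self) -> "SimulationConfig":
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("sum(module_sizes) exceeds n_genes")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must be in [0, 1]")
        if not 0 <= self.module_strength <= 1:
            raise ValidationError("module_strength must be in [0, 1]")
        if self.n_brain_tissues > self.n_tissues:
            raise ValidationError("n_brain_tissues cannot exceed n_tissues")
        for name in ("n_genes", "n_lncRNAs", "n_case", "n_control", "n_tech_reps",
                     "n_dev_samples", "n_tissues", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_lncRNAs > self.n_genes:
            raise ValidationError("n_lncRNAs cannot exceed n_genes")
        if self.age_range_months[0] <= 0 or self.age_range_months[1] <= self.age_range_months[0]:
            raise ValidationError("age_range_months must be an increasing positive pair")
        return self


@dataclass
class GroundTruth:
    """Planted structure recorded by the generator for downstream checks."""

    de_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # ^ columns: gene_id, log2fc, base_mean
    module_labels: pd.Series = field(default_factory=pd.Series)  # gene_id -> module label
    brain_selective: set[str] = field(default_factory=set)
    risk_genes: set[str] = field(default_factory=set)
    risk_scores: dict[str, int] = field(default_factory=dict)
    me16_like: set[str] = field(default_factory=set)
    lnc_in_risk_module: set[str] = field(default_factory=set)
    cnv_hit: set[str] = field(default_factory=set)
    top_priority: set[str] = field(default_factory=set)

    @property
    def de_gene_ids(self) -> set[str]:
        if self.de_genes.empty:
            return set()
        return set(self.de_genes["gene_id"])


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


@dataclass
class _Plant:
    """Deterministic global assignment shared by all simulate_* operations."""

    gene_ids: list[str]
    biotypes: pd.Series
    module_labels: pd.Series  # "M1".."Mk" or "background"
    base_means: pd.Series
    de_table: pd.DataFrame
    risk_genes: list[str]
    risk_scores: dict[str, int]
    me16_like: list[str]
    lnc_in_risk_module: list[str]
    brain_selective: list[str]
    top_priority: list[str]


def _plant(cfg: SimulationConfig) -> _Plant:
    cfg.validate()
    rng = _rng(cfg, _STREAM_STRUCTURE)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(1, n + 1)]

    # biotypes: lncRNA sub-biotypes in roughly the observed mix
    # (about half intergenic, most of the rest antisense)
    lnc_idx = rng.choice(n, size=cfg.n_lncRNAs, replace=False)
    biotypes = pd.Series("protein_coding", index=gene_ids, name="biotype")
    lnc_kinds = rng.choice(
        ["lincRNA", "antisense", "processed_transcript", "sense_intronic", "other_lncRNA"],
        size=cfg.n_lncRNAs,
        p=[0.45, 0.41, 0.06, 0.04, 0.04],
    )
    biotypes.iloc[lnc_idx] = lnc_kinds
    lnc_ids = [gene_ids[i] for i in lnc_idx]
    pc_ids = [g for g in gene_ids if biotypes[g] == "protein_coding"]

    # module assignment: module 1 is the "risk" module, seeded with planted
    # risk genes (protein-coding) and planted lncRNAs
    module_labels = pd.Series("background", index=gene_ids, name="module")
    k_lnc = min(cfg.n_lnc_in_module, len(lnc_ids), cfg.module_sizes[0])
    lnc_in_m1 = [str(g) for g in rng.choice(lnc_ids, size=k_lnc, replace=False)]
    k_risk_m1 = min(cfg.n_risk_in_module, cfg.module_sizes[0] - k_lnc)
    n_risk = max(cfg.n_risk_genes, k_risk_m1)
    risk_pool = [str(g) for g in rng.choice(pc_ids, size=min(n_risk, len(pc_ids)), replace=False)]
    risk_in_m1 = risk_pool[:k_risk_m1]

    remaining = [g for g in gene_ids if g not in set(lnc_in_m1) | set(risk_in_m1)]
    rng.shuffle(remaining)
    cursor = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        label = f"M{m}"
        if m == 1:
            members = lnc_in_m1 + risk_in_m1
            fill = size - len(members)
            members = members + remaining[cursor : cursor + fill]
            cursor += fill
        else:
            members = remaining[cursor : cursor + size]
            cursor += size
        module_labels[members] = label

    # an "independent-study module" list: mostly members of M1 plus extras,
    # emulating an externally derived risk-enriched module gene set
    m1_pc = [g for g in module_labels.index[module_labels == "M1"] if biotypes[g] == "protein_coding"]
    me16_core = [str(g) for g in rng.choice(m1_pc, size=min(12, len(m1_pc)), replace=False)]
    outside = [g for g in pc_ids if module_labels[g] != "M1"]
    me16_like = me16_core + [str(g) for g in rng.choice(outside, size=8, replace=False)]

    # baseline count means; planted candidate lncRNAs get solidly detectable
    # abundance (the analysis targets well-expressed brain lncRNAs)
    base = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n))
    base_means = pd.Series(base, index=gene_ids, name="base_mean")
    base_means[lnc_in_m1] = np.exp(rng.normal(np.log(500.0), 0.3, size=len(lnc_in_m1)))

    # planted DE genes: module-1 lncRNAs are all DE and down-regulated
    # (mirroring a down-regulated synaptic-type module); the rest random sign
    n_de = int(round(cfg.de_fraction * n))
    if cfg.de_fraction > 0 and n_de < 1:
        raise ValidationError("de_fraction * n_genes < 1: no DE genes can be planted")
    if n_de > 0:
        forced = list(lnc_in_m1)[: min(len(lnc_in_m1), n_de)]
        others_pool = [g for g in gene_ids if g not in set(forced)]
        extra = [str(g) for g in rng.choice(others_pool, size=n_de - len(forced), replace=False)]
        de_ids = forced + extra
        signs = np.concatenate(
            [-np.ones(len(forced)), rng.choice([-1.0, 1.0], size=len(extra))]
        )
        de_table = pd.DataFrame(
            {
                "gene_id": de_ids,
                "log2fc": signs * cfg.de_log2fc,
                "base_mean": base_means[de_ids].to_numpy(),
            }
        )
    else:
        de_table = pd.DataFrame(columns=["gene_id", "log2fc", "base_mean"])

    # brain-selective lncRNAs: the planted module-1 lncRNAs plus extras
    extra_pool = [g for g in lnc_ids if g not in set(lnc_in_m1)]
    n_extra = max(0, cfg.n_brain_selective - len(lnc_in_m1))
    brain_selective = lnc_in_m1 + [
        str(g) for g in rng.choice(extra_pool, size=min(n_extra, len(extra_pool)), replace=False)
    ]

    scores = {g: int(s) for g, s in zip(risk_pool, rng.integers(1, 6, size=len(risk_pool)))}
    top_priority = lnc_in_m1[: cfg.n_top_priority]

    return _Plant(
        gene_ids=gene_ids,
        biotypes=biotypes,
        module_labels=module_labels,
        base_means=base_means,
        de_table=de_table,
        risk_genes=risk_pool,
        risk_scores=scores,
        me16_like=me16_like,
        lnc_in_risk_module=lnc_in_m1,
        brain_selective=brain_selective,
        top_priority=top_priority,
    )


def _truth(plant: _Plant) -> GroundTruth:
    return GroundTruth(
        de_genes=plant.de_table.copy(),
        module_labels=plant.module_labels.copy(),
        brain_selective=set(plant.brain_selective),
        risk_genes=set(plant.risk_genes),
        risk_scores=dict(plant.risk_scores),
        me16_like=set(plant.me16_like),
        lnc_in_risk_module=set(plant.lnc_in_risk_module),
        cnv_hit=set(plant.top_priority),
        top_priority=set(plant.top_priority),
    )


# ---------------------------------------------------------------------------
# Case/control counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2; alpha=0 degenerates to Poisson."""
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_case_control_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Case/control counts with planted DE genes and technical replicates.

    Counts are NB(mean = mu_g * s_j, dispersion alpha) with a lognormal
    baseline mu_g and per-column size factors drawn around 1.  Planted DE
    genes have their case-group mean multiplied by ``2**log2fc``; technical
    replicates of one biological sample share the biological mean but get
    independent draws.
    """
    plant = _plant(cfg)
    rng = _rng(cfg, _STREAM_COUNTS)
    n = cfg.n_genes

    subjects = [f"case_{i+1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i+1}" for i in range(cfg.n_control)
    ]
    conditions = ["case"] * cfg.n_case + ["control"] * cfg.n_control

    lfc = pd.Series(0.0, index=plant.gene_ids)
    if not plant.de_table.empty:
        lfc[plant.de_table["gene_id"].to_list()] = plant.de_table["log2fc"].to_numpy()
    mu = plant.base_means.to_numpy()

    columns, sample_rows = [], []
    data = np.empty((n, len(subjects) * cfg.n_tech_reps), dtype=np.int64)
    col = 0
    for subj, cond in zip(subjects, conditions):
        mean_bio = mu * np.power(2.0, lfc.to_numpy()) if cond == "case" else mu
        for t in range(cfg.n_tech_reps):
            s_j = float(np.exp(rng.normal(0.0, 0.15)))
            data[:, col] = _nb_draw(rng, mean_bio * s_j, cfg.nb_dispersion)
            name = f"{subj}_t{t+1}" if cfg.n_tech_reps > 1 else subj
            columns.append(name)
            sample_rows.append({"sample": name, "condition": cond, "subject": subj})
            col += 1

    counts = pd.DataFrame(data, index=plant.gene_ids, columns=columns)
    cm = CountMatrix(counts=counts, samples=pd.DataFrame(sample_rows))
    return cm, _truth(plant)


# ---------------------------------------------------------------------------
# Developmental matrix
# ---------------------------------------------------------------------------

_TRAJECTORY_KINDS = ("monotone", "sinusoid", "shared_factor")


def _trajectory(module_index: int, log_age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latent factor driving one module.

    Kinds cycle round-robin: "monotone" follows log-age, "sinusoid"
    oscillates over the sampled span, and "shared_factor" is a random
    age-independent latent vector (a co-expressed module with no
    developmental trend).  When a kind recurs it is varied — the monotone
    sign flips, the sinusoid frequency increases — so no two modules share
    the same latent factor.
    """
    kind = _TRAJECTORY_KINDS[module_index % len(_TRAJECTORY_KINDS)]
    cycle = module_index // len(_TRAJECTORY_KINDS)
    if kind == "monotone":
        f = log_age * (-1.0) ** cycle
    elif kind == "sinusoid":
        span = log_age.max() - log_age.min()
        f = np.sin(2.0 * np.pi * (cycle + 1) * (log_age - log_age.min()) / span)
    else:  # shared_factor: a fresh random vector each time
        f = rng.standard_normal(log_age.size)
    sd = f.std()
    if sd == 0:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def simulate_developmental_matrix(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Developmental expression with planted co-expression modules.

    Each planted module m has a latent trajectory f_m over age (kinds
    assigned round-robin); member genes follow
    ``x = s * f_m + sqrt(1 - s^2) * noise`` with s = module_strength.
    Background genes are pure noise.  Values are shifted per gene to be
    nonnegative (an affine map, so correlations are untouched).
    """
    plant = _plant(cfg)
    rng = _rng(cfg, _STREAM_DEV)
    lo, hi = cfg.age_range_months
    ages = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_dev_samples)))
    log_age = np.log(ages)

    s = cfg.module_strength
    noise_w = float(np.sqrt(max(0.0, 1.0 - s * s)))
    factors = {
        f"M{m}": _trajectory(m - 1, log_age, rng)
        for m in range(1, len(cfg.module_sizes) + 1)
    }

    X = rng.standard_normal((cfg.n_genes, cfg.n_dev_samples))
    labels = plant.module_labels
    for m, f in factors.items():
        idx = np.flatnonzero((labels == m).to_numpy())
        X[idx] = s * f[None, :] + noise_w * X[idx]
    bg = np.flatnonzero((labels == "background").to_numpy())
    # background rows stay pure standard-normal noise

    # per-gene abundance scale: genes in coherent developmental modules sit
    # above the background variance floor, which is what the downstream
    # bottom-two-quartile variance filter is designed to exploit
    log_scale = rng.normal(0.0, 0.5, size=cfg.n_genes)
    in_module = (labels != "background").to_numpy()
    log_scale[in_module] = rng.normal(0.8, 0.4, size=int(in_module.sum()))
    X = X * np.exp(log_scale)[:, None]
    X = X - X.min(axis=1, keepdims=True)  # per-gene shift to nonnegative

    samples = [f"S{j:04d}" for j in range(1, cfg.n_dev_samples + 1)]
    values = pd.DataFrame(X, index=plant.gene_ids, columns=samples)
    meta = pd.DataFrame({"age_months": ages}, index=pd.Index(samples, name="sample"))
    return ExpressionMatrix(values=values, meta=meta), _truth(plant)


# ---------------------------------------------------------------------------
# Tissue panel
# ---------------------------------------------------------------------------


def simulate_tissue_matrix(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Median-expression panel across tissues with planted brain selectivity.

    Brain-selective genes have their brain-tissue means multiplied by
    ``brain_inflation`` so their fractional brain expression exceeds the
    selectivity threshold; all other genes are roughly uniform across
    tissues.  Some non-brain tissues are given fewer than 50 samples to
    exercise the panel filter.
    """
    plant = _plant(cfg)
    rng = _rng(cfg, _STREAM_TISSUE)
    n_brain = cfg.n_brain_tissues
    tissues = [f"brain_{i+1}" for i in range(n_brain)] + [
        f"tissue_{i+1}" for i in range(cfg.n_tissues - n_brain)
    ]
    # brain tissues always survive the >=50-sample filter; others may not
    n_samples = np.concatenate(
        [
            rng.integers(60, 400, size=n_brain),
            rng.integers(20, 400, size=cfg.n_tissues - n_brain),
        ]
    )
    is_brain = np.array([t.startswith("brain_") for t in tissues])

    base = np.exp(rng.normal(1.0, 0.8, size=cfg.n_genes))[:, None]
    noise = np.exp(rng.normal(0.0, 0.3, size=(cfg.n_genes, cfg.n_tissues)))
    vals = base * noise
    sel_idx = [plant.gene_ids.index(g) for g in plant.brain_selective]
    vals[np.ix_(sel_idx, np.flatnonzero(is_brain))] *= cfg.brain_inflation

    values = pd.DataFrame(vals, index=plant.gene_ids, columns=tissues)
    meta = pd.DataFrame(
        {"n_samples": n_samples, "is_brain": is_brain},
        index=pd.Index(tissues, name="tissue"),
    )
    return ExpressionMatrix(values=values, meta=meta), _truth(plant)


# ---------------------------------------------------------------------------
# Annotation, CNVs, gene lists
# ---------------------------------------------------------------------------


def simulate_annotation(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Non-overlapping gene spans on a small artificial genome (0-based half-open)."""
    plant = _plant(cfg)
    rng = _rng(cfg, _STREAM_ANNOT)
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.genome_length // per_chrom
    if slot < 600:
        raise ValidationError("genome_length too small for non-overlapping gene placement")
    rows = []
    for i, g in enumerate(plant.gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        k = i % per_chrom
        length = int(rng.integers(500, min(5000, slot - 50)))
        offset = int(rng.integers(0, slot - length - 1))
        start = k * slot + offset
        rows.append(
            {
                "gene_id": g,
                "symbol": f"SYM{i+1:05d}",
                "biotype": plant.biotypes[g],
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": str(rng.choice(["+", "-"])),
            }
        )
    ann = pd.DataFrame(rows)
    return ann, _truth(plant)


def simulate_cnvs(cfg: SimulationConfig) -> tuple[list[CNVRecord], GroundTruth]:
    """CNV intervals, "Major" class mostly, planted to overlap priority lncRNAs."""
    ann, _ = simulate_annotation(cfg)
    plant = _plant(cfg)
    rng = _rng(cfg, _STREAM_CNV)
    ann_ix = ann.set_index("gene_id")
    records: list[CNVRecord] = []
    cid = 0

    def _next_id() -> str:
        nonlocal cid
        cid += 1
        return f"CNV{cid:05d}"

    # planted hits: a few CNVs straddling each top-priority lncRNA span
    for g in plant.top_priority:
        row = ann_ix.loc[g]
        for _ in range(cfg.cnv_hits_per_priority):
            pad_l = int(rng.integers(0, 20000))
            pad_r = int(rng.integers(0, 20000))
            start = max(0, int(row.start) - pad_l)
            end = int(row.end) + pad_r
            records.append(CNVRecord(_next_id(), str(row.chrom), start, end, "Major"))

    n_random = max(0, cfg.n_cnvs - len(records))
    chroms = [f"chr{c+1}" for c in range(cfg.n_chroms)]
    for _ in range(n_random):
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(5000, 200000))
        start = int(rng.integers(0, max(1, cfg.genome_length - length)))
        klass = "Major" if rng.random() < 0.8 else "Minor"
        records.append(CNVRecord(_next_id(), chrom, start, start + length, klass))
    return records, _truth(plant)


def simulate_gene_lists(cfg: SimulationConfig) -> tuple[dict[str, set[str]], GroundTruth]:
    """Risk-gene list files: a curated-style scored list and an independent-module list."""
    plant = _plant(cfg)
    return {"sfari": set(plant.risk_genes), "me16": set(plant.me16_like)}, _truth(plant)


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------


def write_all(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate every input table and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_case_control_counts(cfg)
    write_count_matrix(cm, outdir / "counts.tsv", outdir / "samples.tsv")
    dev, _ = simulate_developmental_matrix(cfg)
    write_expression_matrix(dev, outdir / "dev_expression.tsv", outdir / "dev_samples.tsv")
    tis, _ = simulate_tissue_matrix(cfg)
    write_expression_matrix(tis, outdir / "tissue_expression.tsv", outdir / "tissue_panel.tsv")
    ann, _ = simulate_annotation(cfg)
    write_annotation(ann, outdir / "annotation.tsv")
    cnvs, _ = simulate_cnvs(cfg)
    write_cnvs(cnvs, outdir / "cnvs.tsv")
    lists, _ = simulate_gene_lists(cfg)
    for name, ids in lists.items():
        write_gene_list(ids, outdir / f"genes_{name}.txt")
    pd.DataFrame(
        sorted((g, s) for g, s in truth.risk_scores.items()), columns=["gene_id", "score"]
    ).to_csv(outdir / "risk_scores.tsv", sep="\t", index=False)
    # ground truth for inspection
    truth.de_genes.to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    truth.module_labels.rename_axis("gene_id").to_frame().to_csv(
        outdir / "truth_modules.tsv", sep="\t"
    )
    for name, ids in (
        ("brain_selective", truth.brain_selective),
        ("top_priority", truth.top_priority),
        ("cnv_hit", truth.cnv_hit),
    ):
        write_gene_list(ids, outdir / f"truth_{name}.txt")
    return truth
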