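"""Readers, writers and validation for every table the pipeline touches.

All genomic intervals are stored 0-based half-open internally (BED
convention on disk).  Readers validate and reject rather than silently
coerce; every writer produces files its reader round-trips bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lncprior")

#: Closed biotype vocabulary.  Everything except protein_coding counts as lncRNA.
BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "other_lncRNA",
)

ANNOTATION_COLUMNS = ["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]
CNV_COLUMNS = ["chrom", "start", "end", "cnv_id", "report_class"]


class ValidationError(ValueError):
    """A file or table failed validation; the message names the offending row."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every threshold and tunable of the pipeline, with the published defaults.

    Attributes
    ----------
    de_alpha, de_lfc_min:
        Significance rule for differential expression: BH-adjusted p < 0.05
        and |log2 fold change| >= 1 (the fold-change bound is inclusive).
    beta:
        Soft-threshold power for the signed co-expression network (12).
    n_permutations:
        Draws for every permutation null (10,000).
    tissue_min_samples:
        Tissues with fewer than this many donors are dropped (50; a tissue
        with exactly 50 is kept).
    brain_fraction_threshold:
        Fractional brain expression (percent) above which a gene is called
        brain-selective (strictly greater than 50).
    min_module_size, cut_height_quantile, hybrid_assign, kme_min:
        Dynamic tree-cut parameters for module detection.
    dispersion_shrinkage:
        Weight pulling per-gene method-of-moments dispersions toward their
        across-gene mean.
    """

    seed: int = 0
    # differential expression
    de_alpha: float = 0.05
    de_lfc_min: float = 1.0
    dispersion_shrinkage: float = 0.5
    dispersion_floor: float = 1e-8
    # tissue selectivity
    tissue_min_samples: int = 50
    brain_fraction_threshold: float = 50.0
    # network
    beta: float = 12.0
    correlation: str = "bicor"  # {"bicor", "pearson"}
    min_module_size: int = 30
    cut_method: str = "height"  # {"height", "hybrid"}
    cut_height_quantile: float = 0.5
    hybrid_assign: bool = False
    kme_min: float = 0.3
    merge_threshold: float | None = None  # eigengene-correlation merging, off
    # statistics
    n_permutations: int = 10000
    enrichment_alpha: float = 0.05
    # CNV
    cnv_class_filter: str = "Major"

    def validate(self) -> "RunConfig":
        if not 0 < self.de_alpha < 1:
            raise ValidationError(f"de_alpha must be in (0,1), got {self.de_alpha}")
        if self.beta < 1:
            raise ValidationError(f"beta must be >= 1, got {self.beta}")
        if self.min_module_size < 3:
            raise ValidationError("min_module_size must be >= 3")
        if self.correlation not in ("bicor", "pearson"):
            raise ValidationError(f"unknown correlation kind {self.correlation!r}")
        if self.cut_method not in ("height", "hybrid"):
            raise ValidationError(f"unknown cut method {self.cut_method!r}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True)
        )

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs).validate()


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus sample metadata.

    ``samples`` must carry columns ``sample``, ``condition`` and ``subject``;
    technical replicates of one biological sample share a ``subject``.
    """

    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # columns: sample, condition, subject

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValidationError("count matrix columns do not match sample sheet order")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            g = self.counts.index[np.where((vals < 0).any(axis=1))[0][0]]
            raise ValidationError(f"negative count for gene {g!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def condition_of(self, sample: str) -> str:
        return self.samples.set_index("sample").loc[sample, "condition"]


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample (or gene x tissue) expression values.

    ``meta`` is indexed like the columns; for developmental data it carries
    ``age_months`` (months post-conception), for tissue panels ``n_samples``
    and ``is_brain``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValidationError("expression columns do not match metadata index")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression value")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class CNVRecord:
    cnv_id: str
    chrom: str
    start: int
    end: int
    report_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"CNV {self.cnv_id}: start must be < end, got [{self.start}, {self.end})"
            )


def is_lncRNA(biotype: str | pd.Series):
    """lncRNA predicate: any annotated biotype other than protein_coding."""
    if isinstance(biotype, pd.Series):
        return biotype != "protein_coding"
    return biotype != "protein_coding"


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation missing columns {missing}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in annotation")
    bad_bt = set(ann["biotype"]) - set(BIOTYPES)
    if bad_bt:
        raise ValidationError(f"unknown biotypes {sorted(bad_bt)}")
    bad = ann[ann["start"] >= ann["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(f"gene {r.gene_id}: start must be < end")
    bad_strand = set(ann["strand"]) - {"+", "-", "."}
    if bad_strand:
        raise ValidationError(f"invalid strand values {sorted(bad_strand)}")
    return ann.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message carries the line
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc


def read_count_matrix(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    counts = _read_tsv(path, index_col=0)
    samples = _read_tsv(sample_sheet)
    for col in ("sample", "condition", "subject"):
        if col not in samples.columns:
            raise ValidationError(f"{sample_sheet}: sample sheet missing column {col!r}")
    unknown = set(counts.columns) - set(samples["sample"])
    if unknown:
        raise ValidationError(f"{path}: sample ids {sorted(unknown)} absent from sample sheet")
    samples = samples.set_index("sample").loc[list(counts.columns)].reset_index()
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{path}: non-integer counts")
    counts = counts.astype(np.int64)
    return CountMatrix(counts=counts, samples=samples)


def read_expression_matrix(path: str | Path, metadata: str | Path) -> ExpressionMatrix:
    values = _read_tsv(path, index_col=0)
    meta = _read_tsv(metadata, index_col=0)
    unknown = set(values.columns) - set(meta.index)
    if unknown:
        raise ValidationError(f"{path}: columns {sorted(unknown)} absent from metadata")
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values.astype(float), meta=meta)


def read_annotation(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED-style annotation table.

    Columns: chrom, start, end, gene_id, symbol, strand, biotype.  Set
    ``one_based=True`` for 1-based inclusive input; coordinates are converted
    to 0-based half-open at this boundary.
    """
    df = _read_tsv(path)
    if one_based:
        df = df.assign(start=df["start"] - 1)
    df = df[["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]]
    return validate_annotation(df)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[["chrom", "start", "end", "gene_id", "symbol", "strand", "biotype"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> set[str]:
    ids = {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
    if not ids:
        raise ValidationError(f"{path}: empty gene list")
    return ids


def write_gene_list(ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ids)))


def read_cnvs(
    path: str | Path, class_filter: str | None = "Major", one_based: bool = False
) -> list[CNVRecord]:
    """Read a BED-style CNV table, keeping only the requested report class.

    The default retains only records whose report class is "Major", the
    curation tier used for the published CNV list.
    """
    df = _read_tsv(path)
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: CNV table missing columns {missing}")
    if one_based:
        df = df.assign(start=df["start"] - 1)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.start >= row.end:
            raise ValidationError(f"{path}: line {i}: start must be < end")
        if class_filter is not None and row.report_class != class_filter:
            continue
        records.append(
            CNVRecord(
                cnv_id=str(row.cnv_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                report_class=str(row.report_class),
            )
        )
    logger.info("read %d/%d CNVs with report class %r", len(records), len(df), class_filter)
    return records


def write_cnvs(records: list[CNVRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.chrom, r.start, r.end, r.cnv_id, r.report_class) for r in records],
        columns=CNV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index=False)


def write_expression_matrix(em: ExpressionMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    em.values.to_csv(values_path, sep="\t", index_label="gene_id")
    em.meta.to_csv(meta_path, sep="\t", index_label=em.meta.index.name or "sample")
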