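"""End-to-end orchestration: simulate/load -> DE -> tissue -> network ->
permutations -> enrichment -> CNV -> prioritize, with a reproducible manifest.

One global seed is split deterministically into independent per-stage seeds,
so changing the permutation count of one test never perturbs another stage.
Every stage can also be run standalone (see :mod:`lncprior.cli`) with
results identical to the orchestrated run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (
    enrich_modules,
    lncrna_geneset_coexpression_test,
    module_coexpression_test,
    module_de_overlay_test,
)
from .coexpr_network import (
    correlation_matrix,
    detect_modules,
    eigengene_age_correlation,
    top_correlated_gene,
    variance_filter,
)
from .diffexpr import run_de
from .io_formats import (
    CountMatrix,
    ExpressionMatrix,
    RunConfig,
    ValidationError,
    is_lncRNA,
    read_annotation,
    read_cnvs,
    read_count_matrix,
    read_expression_matrix,
    read_gene_list,
)
from .prioritization import cnv_overlap_counts, rank_candidates
from .synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_case_control_counts,
    simulate_cnvs,
    simulate_developmental_matrix,
    simulate_gene_lists,
    simulate_tissue_matrix,
)
from .tissue_profile import score_specificity

logger = logging.getLogger("lncprior")

_STAGES = ("de", "tissue", "network", "permute", "enrich", "cnv", "prioritize")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (always below 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineInputs:
    counts: CountMatrix
    dev: ExpressionMatrix
    tissue: ExpressionMatrix
    annotation: pd.DataFrame
    cnvs: list
    gene_lists: dict[str, set[str]]
    risk_scores: dict[str, int]

    @classmethod
    def from_simulation(cls, sim_cfg: SimulationConfig) -> "PipelineInputs":
        cm, _ = simulate_case_control_counts(sim_cfg)
        dev, _ = simulate_developmental_matrix(sim_cfg)
        tis, truth = simulate_tissue_matrix(sim_cfg)
        ann, _ = simulate_annotation(sim_cfg)
        cnvs, _ = simulate_cnvs(sim_cfg)
        lists, _ = simulate_gene_lists(sim_cfg)
        return cls(
            counts=cm, dev=dev, tissue=tis, annotation=ann,
            cnvs=[c for c in cnvs if c.report_class == "Major"],
            gene_lists=lists, risk_scores=truth.risk_scores,
        )

    @classmethod
    def from_dir(cls, d: str | Path, cnv_class: str = "Major") -> "PipelineInputs":
        d = Path(d)
        cm = read_count_matrix(d / "counts.tsv", d / "samples.tsv")
        dev = read_expression_matrix(d / "dev_expression.tsv", d / "dev_samples.tsv")
        tis = read_expression_matrix(d / "tissue_expression.tsv", d / "tissue_panel.tsv")
        ann = read_annotation(d / "annotation.tsv")
        cnv_path = d / "cnvs.tsv"
        if not cnv_path.exists():
            raise ValidationError(f"prioritization stage: missing CNV file {cnv_path}")
        cnvs = read_cnvs(cnv_path, class_filter=cnv_class)
        lists = {
            p.stem.removeprefix("genes_"): read_gene_list(p)
            for p in sorted(d.glob("genes_*.txt"))
        }
        scores = {}
        score_path = d / "risk_scores.tsv"
        if score_path.exists():
            sdf = pd.read_csv(score_path, sep="\t")
            scores = dict(zip(sdf["gene_id"], sdf["score"]))
        tis.meta["is_brain"] = tis.meta["is_brain"].astype(bool)
        return cls(
            counts=cm, dev=dev, tissue=tis, annotation=ann,
            cnvs=cnvs, gene_lists=lists, risk_scores=scores,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: RunConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> dict:
    """Execute every stage in dependency order and write a run manifest.

    Any stage failure halts with a stage-named error; outputs written by
    earlier stages are preserved on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lncprior",
        "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _emit(stage: str, name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)
        return path

    def _run(stage: str, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].setdefault(stage, {})["elapsed_s"] = round(time.time() - t0, 3)
        return out

    # ---- differential expression -------------------------------------
    def _de():
        de = run_de(
            inputs.counts,
            alpha=config.de_alpha,
            fc_min=config.de_lfc_min,
            shrinkage=config.dispersion_shrinkage,
        )
        _emit("de", "de.tsv", de.reset_index(drop=True))
        return de

    de = _run("de", _de)
    ann = inputs.annotation.set_index("gene_id")
    lnc_mask = is_lncRNA(ann["biotype"])
    de_lnc = sorted(set(de.index[de["significant"]]) & set(ann.index[lnc_mask]))
    logger.info("%d significant DE genes, %d DE lncRNAs",
                int(de["significant"].sum()), len(de_lnc))

    # ---- tissue selectivity ------------------------------------------
    def _tissue():
        spec = score_specificity(
            inputs.tissue,
            min_samples=config.tissue_min_samples,
            threshold=config.brain_fraction_threshold,
        )
        _emit("tissue", "specificity.tsv", spec.reset_index(drop=True))
        return spec

    spec = _run("tissue", _tissue)

    # ---- network ------------------------------------------------------
    def _network():
        filtered = variance_filter(inputs.dev)
        corr = correlation_matrix(filtered.values, kind=config.correlation)
        partition = detect_modules(filtered, params=config, corr=corr)
        _emit(
            "network", "modules.tsv",
            pd.DataFrame(
                {
                    "gene_id": partition.labels.index,
                    "module": partition.labels.to_numpy(),
                    "kME": partition.membership.to_numpy(),
                }
            ),
        )
        _emit(
            "network", "eigengenes.tsv",
            partition.eigengenes.rename_axis("module").reset_index(),
        )
        if "age_months" in filtered.meta.columns and len(partition.eigengenes):
            age_r = eigengene_age_correlation(
                partition, filtered.meta["age_months"]
            )
            _emit("network", "eigengene_age_corr.tsv",
                  age_r.rename_axis("module").reset_index())
        return filtered, corr, partition

    filtered, corr, partition = _run("network", _network)

    # ---- permutation statistics --------------------------------------
    def _permute():
        seed = stage_seed(config.seed, "permute")
        B = config.n_permutations
        coexpr = module_coexpression_test(corr, partition.labels, B=B, seed=seed)
        overlay = module_de_overlay_test(partition.labels, de, B=B, seed=seed + 1)
        sets = dict(inputs.gene_lists)
        lnc_in_net = sorted(set(de_lnc) & set(corr.index))
        setcor = (
            lncrna_geneset_coexpression_test(corr, lnc_in_net, sets, B=B, seed=seed + 2)
            if lnc_in_net
            else pd.DataFrame()
        )
        _emit("permute", "perm_module_coexpression.tsv", coexpr)
        _emit("permute", "perm_de_overlay.tsv", overlay)
        _emit("permute", "perm_lnc_geneset.tsv", setcor)
        return coexpr, overlay, setcor

    perm_coexpr, perm_overlay, perm_setcor = _run("permute", _permute)

    # ---- enrichment ---------------------------------------------------
    def _enrich():
        gene_sets = {name: set(ids) for name, ids in inputs.gene_lists.items()}
        gene_sets["de_lncrnas"] = set(de_lnc)
        universe = set(partition.labels.index)
        gene_sets = {k: v & universe for k, v in gene_sets.items() if v & universe}
        enr = enrich_modules(
            partition.labels, gene_sets, universe=universe, alpha=config.enrichment_alpha
        )
        _emit("enrich", "enrichment.tsv", enr)
        return enr

    enrichment = _run("enrich", _enrich)

    # ---- CNV overlaps -------------------------------------------------
    def _cnv():
        counts = cnv_overlap_counts(inputs.annotation, inputs.cnvs)
        _emit("cnv", "cnv_overlaps.tsv", counts.reset_index())
        return counts

    cnv_counts = _run("cnv", _cnv)

    # ---- prioritization ----------------------------------------------
    def _prioritize():
        lnc_in_net = sorted(set(de_lnc) & set(partition.labels.index))
        if not lnc_in_net:
            raise ValidationError("no DE lncRNA present in the network")
        pc_genes = set(ann.index[ann["biotype"] == "protein_coding"]) & set(corr.index)
        tc_rows = []
        for g in lnc_in_net:
            gene, r = top_correlated_gene(filtered.values, g, pc_genes, kind=config.correlation)
            tc_rows.append({"lncrna_id": g, "top_corr_gene": gene, "top_corr_r": r})
        top_corr = pd.DataFrame(tc_rows).set_index("lncrna_id")
        risk_names = [n for n in inputs.gene_lists if n != "de_lncrnas"]
        table = rank_candidates(
            lnc_in_net,
            partition.labels,
            enrichment,
            cnv_counts,
            spec,
            de,
            top_corr,
            risk_set_names=risk_names,
            lnc_set_name="de_lncrnas",
            risk_scores=inputs.risk_scores,
        )
        _emit("prioritize", "priority.tsv", table)
        return table

    priority = _run("prioritize", _prioritize)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "manifest": manifest,
        "de": de,
        "specificity": spec,
        "partition": partition,
        "corr": corr,
        "perm_coexpr": perm_coexpr,
        "perm_overlay": perm_overlay,
        "perm_setcor": perm_setcor,
        "enrichment": enrichment,
        "cnv_counts": cnv_counts,
        "priority": priority,
        "de_lncrnas": de_lnc,
    }
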