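"""CNV overlap counting and the final candidate-lncRNA ranking.

Candidates are the differentially expressed lncRNAs present in the
developmental network.  They are ranked module-first: lncRNAs in modules
enriched for a risk-gene set come first (tier 1), then lncRNAs in modules
enriched only for the DE-lncRNA set itself (tier 2), then the rest.
Within a module, lncRNAs are ordered by descending overlap count with
disorder-associated CNVs; residual ties break by |log2 fold change|
descending, then gene id.  Each record carries every evidence column so
the final table is self-contained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CNVRecord, ValidationError

logger = logging.getLogger("lncprior")

TIER_ORDER = {"risk_enriched": 1, "lnc_enriched": 2, "other": 3}


def cnv_overlap_counts(annotation: pd.DataFrame, cnvs: list[CNVRecord]) -> pd.Series:
    """Count, per gene, the CNVs whose interval intersects the gene span.

    Coordinates are 0-based half-open on both sides, so abutting intervals
    ([100,200) vs [200,300)) do not overlap.  Strand is ignored.  CNVs on
    chromosomes absent from the annotation are skipped with a warning.
    """
    known = set(annotation["chrom"])
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in known}
    skipped = 0
    for r in cnvs:
        if r.chrom not in trees:
            skipped += 1
            continue
        trees[r.chrom].addi(r.start, r.end, r.cnv_id)
    if skipped:
        logger.warning("skipped %d CNVs on chromosomes absent from the annotation", skipped)
    counts = [
        len(trees[row.chrom].overlap(row.start, row.end))
        for row in annotation.itertuples(index=False)
    ]
    return pd.Series(counts, index=pd.Index(annotation["gene_id"], name="gene_id"), name="cnv_overlaps")


def module_tiers(
    enrichment: pd.DataFrame,
    risk_set_names,
    lnc_set_name: str,
) -> tuple[pd.Series, pd.Series]:
    """Classify modules by what they are enriched for.

    Tier ``risk_enriched``: enriched for at least one risk-gene set;
    ``lnc_enriched``: enriched for the DE-lncRNA set only; ``other``: rest.
    Also returns a within-tier ordering key per module: the smallest
    enrichment adj_p over the sets that define its tier.
    """
    risk_set_names = set(risk_set_names)
    tiers, keys = {}, {}
    for m, grp in enrichment.groupby("module"):
        enriched = grp[grp["enriched"]]
        risk_rows = enriched[enriched["gene_set"].isin(risk_set_names)]
        lnc_rows = enriched[enriched["gene_set"] == lnc_set_name]
        if len(risk_rows):
            tiers[m] = "risk_enriched"
            keys[m] = float(risk_rows["adj_p"].min())
        elif len(lnc_rows):
            tiers[m] = "lnc_enriched"
            keys[m] = float(lnc_rows["adj_p"].min())
        else:
            tiers[m] = "other"
            keys[m] = 1.0
    return pd.Series(tiers, name="module_tier"), pd.Series(keys, name="module_order_key")


def rank_candidates(
    de_lncrnas,
    labels: pd.Series,
    enrichment: pd.DataFrame,
    cnv_counts: pd.Series,
    specificity: pd.DataFrame,
    de: pd.DataFrame,
    top_corr: pd.DataFrame,
    risk_set_names=("sfari",),
    lnc_set_name: str = "de_lncrnas",
    risk_scores: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble and rank the candidate-lncRNA priority table.

    ``top_corr`` carries per-lncRNA columns ``top_corr_gene`` and
    ``top_corr_r``.  Candidates missing from an evidence table get NA for
    that column, a warning, and sort last within their tier.
    """
    risk_scores = risk_scores or {}
    candidates = sorted(set(de_lncrnas) & set(labels.index))
    if not candidates:
        raise ValidationError("no DE lncRNA is present in the network")
    tiers, order_keys = module_tiers(enrichment, risk_set_names, lnc_set_name)

    rows = []
    for g in candidates:
        module = labels[g]
        tier = tiers.get(module, "other")
        cnv = cnv_counts.get(g, np.nan)
        lfc = de.loc[g, "log2fc"] if g in de.index else np.nan
        frac = (
            specificity.loc[g, "fractional_brain_expression"]
            if g in specificity.index
            else np.nan
        )
        if g in top_corr.index:
            tc_gene = top_corr.loc[g, "top_corr_gene"]
            tc_r = top_corr.loc[g, "top_corr_r"]
        else:
            tc_gene, tc_r = None, np.nan
        if any(pd.isna(v) for v in (cnv, lfc)):
            logger.warning("candidate %s missing evidence; ranked last within its tier", g)
        rows.append(
            {
                "lncrna_id": g,
                "module": module,
                "module_tier": tier,
                "cnv_overlaps": cnv,
                "log2fc_asd": lfc,
                "fractional_brain_expression": frac,
                "top_corr_gene": tc_gene,
                "top_corr_r": tc_r,
                "top_corr_gene_risk_score": risk_scores.get(tc_gene, np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df["_tier"] = df["module_tier"].map(TIER_ORDER)
    df["_module_key"] = df["module"].map(order_keys).fillna(1.0)
    df["_cnv"] = df["cnv_overlaps"].fillna(-1)
    df["_abs_lfc"] = df["log2fc_asd"].abs().fillna(-1)
    df = df.sort_values(
        by=["_tier", "_module_key", "module", "_cnv", "_abs_lfc", "lncrna_id"],
        ascending=[True, True, True, False, False, True],
        kind="mergesort",
    ).drop(columns=["_tier", "_module_key", "_cnv", "_abs_lfc"])
    df["final_rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
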