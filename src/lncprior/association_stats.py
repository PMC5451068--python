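"""Permutation-based module statistics and Fisher-exact gene-set enrichment.

Three permutation nulls, each built from random same-size gene sets drawn
without replacement from the network genes, B = 10,000 draws by default:

* module co-expression — is the mean within-module biweight midcorrelation
  higher than for random gene sets of the same size (one-sided greater)?
* differential-expression overlay — does the module's mean case/control
  log2 fold change (non-significant genes set to 0) deviate from random
  sets in either direction (two-sided around the null mean)?
* lncRNA / risk-gene-set co-expression — is the summed biweight
  midcorrelation between a fixed lncRNA set and a gene set higher than
  against random sets of the same size (one-sided greater)?

Empirical p-values use the (r + 1) / (B + 1) convention so a p-value of
zero is impossible; the smallest reportable value at B = 10,000 is
1e-4.  Gene-set overrepresentation in modules uses a one-sided Fisher
exact (hypergeometric tail) test; a set is called enriched in a module
when the BH-adjusted p is below 0.05 *and* the odds ratio exceeds 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

logger = logging.getLogger("lncprior")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _empirical_p_greater(observed: float, null: np.ndarray) -> float:
    return (int((null >= observed).sum()) + 1) / (null.size + 1)


def _empirical_p_two_sided(observed: float, null: np.ndarray) -> float:
    center = null.mean()
    return (int((np.abs(null - center) >= abs(observed - center)).sum()) + 1) / (null.size + 1)


def _null_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def _mean_pairwise(C: np.ndarray, idx: np.ndarray) -> float:
    m = idx.size
    sub = C[np.ix_(idx, idx)]
    return (sub.sum() - np.trace(sub)) / (m * (m - 1))


def module_coexpression_test(
    corr: pd.DataFrame,
    labels: pd.Series,
    B: int = 10000,
    seed: int = 0,
    exclude_unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Mean within-module correlation vs random same-size gene sets.

    ``corr`` is the full network correlation matrix; the null draws gene
    sets from *all* network genes (no exclusions).  One-sided greater.
    """
    rng = np.random.default_rng(seed)
    genes = list(corr.index)
    pos = {g: i for i, g in enumerate(genes)}
    C = corr.to_numpy()
    n = len(genes)
    modules = [m for m in labels.unique() if m != exclude_unassigned_label]
    rows = []
    for m in sorted(modules):
        members = [g for g in labels.index[labels == m] if g in pos]
        if len(members) < 2:
            raise ValidationError(f"module {m!r} has fewer than 2 network genes")
        idx = np.array([pos[g] for g in members])
        observed = _mean_pairwise(C, idx)
        null = np.empty(B)
        for b in range(B):
            null[b] = _mean_pairwise(C, rng.choice(n, size=idx.size, replace=False))
        rows.append(
            {
                "target": m,
                "observed": observed,
                "null_mean": null.mean(),
                "null_sd": null.std(ddof=1),
                "B": B,
                "p": _empirical_p_greater(observed, null),
                "direction": int(np.sign(observed - null.mean())),
            }
        )
    return _null_frame(rows)


def module_de_overlay_test(
    labels: pd.Series,
    de: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    exclude_unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Mean significant-only log2 fold change per module vs random gene sets.

    Network genes absent from the DE table — or present but not significant
    — contribute a fold change of 0.  Two-sided around the null mean, since
    both up- and down-regulated modules are of interest.
    """
    rng = np.random.default_rng(seed)
    genes = list(labels.index)
    lfc = pd.Series(0.0, index=labels.index)
    de_sig = de[de["significant"]] if "significant" in de.columns else de
    common = de_sig.index.intersection(lfc.index)
    lfc[common] = de_sig.loc[common, "log2fc"]
    v = lfc.to_numpy()
    n = len(genes)
    modules = [m for m in labels.unique() if m != exclude_unassigned_label]
    rows = []
    for m in sorted(modules):
        mask = (labels == m).to_numpy()
        if not mask.any():
            raise ValidationError(f"module {m!r} is empty")
        observed = float(v[mask].mean())
        size = int(mask.sum())
        draws = np.empty(B)
        for b in range(B):
            draws[b] = v[rng.choice(n, size=size, replace=False)].mean()
        rows.append(
            {
                "target": m,
                "observed": observed,
                "null_mean": draws.mean(),
                "null_sd": draws.std(ddof=1),
                "B": B,
                "p": _empirical_p_two_sided(observed, draws),
                "direction": int(np.sign(observed)),
            }
        )
    return _null_frame(rows)


def lncrna_geneset_coexpression_test(
    corr: pd.DataFrame,
    lnc_ids,
    gene_sets: dict[str, set[str]],
    B: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Summed lncRNA-to-gene-set correlation vs random same-size sets.

    The lncRNA set stays fixed; each null draw replaces the gene set with a
    random same-size set from the network.  Pairs where the two ids
    coincide (a lncRNA inside the gene set) are excluded and logged.
    One-sided greater, BH across the gene sets tested.
    """
    rng = np.random.default_rng(seed)
    genes = list(corr.index)
    pos = {g: i for i, g in enumerate(genes)}
    lnc = sorted(set(lnc_ids) & set(pos))
    if not lnc:
        raise ValidationError("no lncRNA ids present in the correlation matrix")
    C = corr.to_numpy()
    lnc_idx = np.array([pos[g] for g in lnc])
    col_sums = C[lnc_idx, :].sum(axis=0)  # for each gene, sum of corr to all lncRNAs
    in_lnc = np.zeros(len(genes))
    in_lnc[lnc_idx] = 1.0  # self-pairs contribute corr 1 to col_sums; subtract them
    n = len(genes)
    rows = []
    for name in sorted(gene_sets):
        members = sorted(set(gene_sets[name]) & set(pos))
        if not members:
            raise ValidationError(f"gene set {name!r} has no genes in the network")
        overlap = set(members) & set(lnc)
        if overlap:
            logger.info("gene set %r: excluding %d self pairs", name, len(overlap))
        set_idx = np.array([pos[g] for g in members])
        observed = float(col_sums[set_idx].sum() - in_lnc[set_idx].sum())
        size = set_idx.size
        draws_idx = np.empty((B, size), dtype=np.intp)
        for b in range(B):
            draws_idx[b] = rng.choice(n, size=size, replace=False)
        null = col_sums[draws_idx].sum(axis=1) - in_lnc[draws_idx].sum(axis=1)
        rows.append(
            {
                "target": name,
                "observed": observed,
                "null_mean": float(null.mean()),
                "null_sd": float(null.std(ddof=1)),
                "B": B,
                "p": _empirical_p_greater(observed, null),
                "direction": int(np.sign(observed - null.mean())),
            }
        )
    return _null_frame(rows)


# ---------------------------------------------------------------------------
# Fisher-exact enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(module_genes, gene_set, universe) -> dict:
    """One-sided (greater) Fisher exact test of a gene set within a module.

    2x2 table: a = |module & set|, b = |module - set|, c = |set - module|,
    d = the rest of the universe.  p is the hypergeometric upper tail
    P(X >= a); the odds ratio uses a Haldane +0.5 correction when any cell
    is zero.
    """
    module_genes = set(module_genes)
    gene_set = set(gene_set)
    universe = set(universe)
    if not module_genes <= universe:
        raise ValidationError("module genes must be a subset of the universe")
    if not gene_set <= universe:
        raise ValidationError(
            "gene set is not a subset of the universe; intersect before calling"
        )
    N = len(universe)
    m = len(module_genes)
    n = len(gene_set)
    a = len(module_genes & gene_set)
    b = m - a
    c = n - a
    d = N - a - b - c
    p = float(stats.hypergeom.sf(a - 1, N, n, m))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "universe_size": N,
        "module_size": m,
        "set_size": n,
        "overlap": a,
        "odds_ratio": float(odds),
        "p": min(1.0, p),
    }


def enrich_modules(
    labels: pd.Series,
    gene_sets: dict[str, set[str]],
    universe=None,
    alpha: float = 0.05,
    exclude_unassigned_label: str | None = "unassigned",
) -> pd.DataFrame:
    """Fisher enrichment of every (module, gene set) pair with a shared BH run.

    The default universe is every gene carrying a network label (including
    unassigned genes); gene sets are intersected with the universe.  Works
    identically for any user-supplied term -> gene map, which makes it a
    generic overrepresentation routine.
    """
    universe = set(universe) if universe is not None else set(labels.index)
    modules = sorted(m for m in labels.unique() if m != exclude_unassigned_label)
    rows = []
    for m in modules:
        members = set(labels.index[labels == m]) & universe
        for name in sorted(gene_sets):
            gs = set(gene_sets[name]) & universe
            if not gs:
                continue
            res = fisher_enrichment(members, gs, universe)
            res.update(module=m, gene_set=name)
            rows.append(res)
    df = pd.DataFrame(rows)
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = (df["adj_p"] < alpha) & (df["odds_ratio"] > 1)
        df["neg_log10_adj_p"] = -np.log10(np.maximum(df["adj_p"], 1e-300))
        df = df[
            [
                "module", "gene_set", "universe_size", "module_size", "set_size",
                "overlap", "odds_ratio", "p", "adj_p", "enriched", "neg_log10_adj_p",
            ]
        ]
    return df
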