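"""Signed weighted co-expression network construction and module detection.

The construction follows the standard weighted co-expression recipe on a
developmental expression matrix:

1. variance filter — drop the bottom two quartiles of genes by
   across-sample variance;
2. biweight midcorrelation between all gene pairs (robust to outlying
   samples; Pearson fallback for degenerate rows);
3. signed soft-thresholded adjacency ``a_ij = ((1 + c_ij) / 2) ** beta``
   with beta = 12, so anti-correlated genes get near-zero adjacency;
4. topological overlap between all gene pairs, rewarding shared
   neighbourhoods over bare pairwise correlation;
5. average-linkage hierarchical clustering of ``1 - TOM`` with a
   height-based dynamic cut; branches smaller than ``min_module_size``
   are left unassigned.

Each detected module is summarized by its eigengene — the first principal
component of the standardized module submatrix, sign-oriented to follow the
module's mean expression profile — which serves as the module's
developmental trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, RunConfig, ValidationError

logger = logging.getLogger("lncprior")

#: stable size-ranked module labels, following the conventional color scheme
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------


def variance_filter(em: ExpressionMatrix) -> ExpressionMatrix:
    """Remove the bottom two quartiles of genes by across-sample variance.

    Genes whose variance ties the median are kept (stable rule), so at least
    half the genes always survive.
    """
    if len(em.values) < 4:
        raise ValidationError("variance filter requires at least 4 genes")
    var = em.values.var(axis=1, ddof=1)
    keep = var >= var.median()
    logger.info("variance filter kept %d/%d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(values=em.values.loc[keep], meta=em.meta)


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------


def _robust_deviations(x: np.ndarray) -> np.ndarray | None:
    """Tukey-biweight deviations for one vector; None if degenerate."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))  # unscaled MAD (no consistency factor)
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0  # mask before squaring: huge u would overflow
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    d = (x - med) * w
    if (d * d).sum() == 0:
        return None
    return d


def _pearson_deviations(x: np.ndarray) -> np.ndarray | None:
    d = x - x.mean()
    if (d * d).sum() == 0:
        return None
    return d


def bicor(x, y) -> float:
    """Biweight midcorrelation of two sample vectors.

    Median/MAD-standardized deviations weighted by the Tukey biweight
    (tuning constant 9, observations beyond 9 MADs ignored), normalized like
    a correlation.  If either vector has zero MAD or all weights vanish the
    pair falls back to the Pearson correlation (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("bicor: length mismatch")
    if x.size < 3:
        raise ValidationError("bicor requires vectors of length >= 3")
    dx, dy = _robust_deviations(x), _robust_deviations(y)
    if dx is None or dy is None:
        logger.debug("bicor: Pearson fallback for a degenerate pair")
        dx, dy = _pearson_deviations(x), _pearson_deviations(y)
        if dx is None or dy is None:
            return 0.0
    r = float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(values: pd.DataFrame, kind: str = "bicor") -> pd.DataFrame:
    """Gene x gene correlation matrix (symmetric, unit diagonal).

    For ``kind="bicor"``, rows whose MAD is zero fall back to Pearson: any
    pair touching such a row is computed as a plain Pearson correlation.
    """
    X = values.to_numpy(dtype=float)
    n_genes = X.shape[0]
    if kind == "pearson":
        C = np.corrcoef(X)
        C = np.nan_to_num(C, nan=0.0)
    elif kind == "bicor":
        D = np.empty_like(X)
        fallback = np.zeros(n_genes, dtype=bool)
        for i in range(n_genes):
            d = _robust_deviations(X[i])
            if d is None:
                fallback[i] = True
                d = _pearson_deviations(X[i])
                if d is None:  # constant row
                    d = np.zeros(X.shape[1])
            D[i] = d
        norms = np.sqrt((D * D).sum(axis=1))
        norms[norms == 0] = 1.0
        Dn = D / norms[:, None]
        C = Dn @ Dn.T
        if fallback.any():
            logger.info("bicor: Pearson fallback for %d gene(s)", int(fallback.sum()))
            P = X - X.mean(axis=1, keepdims=True)
            pn = np.sqrt((P * P).sum(axis=1))
            pn[pn == 0] = 1.0
            Pn = P / pn[:, None]
            fb = np.flatnonzero(fallback)
            rows = Pn[fb] @ Pn.T
            C[fb, :] = rows
            C[:, fb] = rows.T
    else:
        raise ValidationError(f"unknown correlation kind {kind!r}")
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=values.index, columns=values.index)


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------


def signed_adjacency(corr: pd.DataFrame | np.ndarray, beta: float = 12.0) -> np.ndarray:
    """Signed soft-thresholded adjacency ``((1 + c) / 2) ** beta``, unit diagonal."""
    if beta < 1:
        raise ValidationError(f"beta must be >= 1, got {beta}")
    C = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    if C.max() > 1 + 1e-9 or C.min() < -1 - 1e-9:
        raise ValidationError("correlations must lie in [-1, 1]")
    A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_u a_iu a_uj`` over u distinct from i and j and
    ``k_i = sum_u a_iu`` over u distinct from i; diagonal 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValidationError("adjacency must be symmetric")
    k = A.sum(axis=1) - np.diag(A)
    # (A @ A)_ij counts u = i and u = j, each contributing a_ij (unit diagonal)
    L = A @ A - 2.0 * A
    num = L + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes and dendrogram provenance."""

    labels: pd.Series  # gene_id -> module label ("unassigned" for background)
    eigengenes: pd.DataFrame  # module x sample, unit variance rows
    membership: pd.Series  # gene -> correlation with its own module eigengene
    linkage: np.ndarray | None = None
    cut_height: float | None = None
    params: RunConfig | None = None

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _eigengene(values: np.ndarray) -> np.ndarray:
    """First PC over samples of the per-gene standardized submatrix.

    Unit (population) variance, sign-oriented so its correlation with the
    module's mean standardized profile is nonnegative.
    """
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (values - mean) / sd
    # first right singular vector = first PC of the sample-space covariance
    _, _, vt = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
    me = vt[0]
    ref = Z.mean(axis=0)
    if np.dot(me - me.mean(), ref - ref.mean()) < 0:
        me = -me
    sd_me = me.std(ddof=0)
    return me / sd_me if sd_me > 0 else me


def detect_modules(
    em: ExpressionMatrix,
    params: RunConfig | None = None,
    corr: pd.DataFrame | None = None,
) -> ModulePartition:
    """Cluster the co-expression network into modules.

    Average-linkage hierarchical clustering of ``1 - TOM``; the tree is cut
    at the ``cut_height_quantile`` of merge heights and branches smaller
    than ``min_module_size`` are relabeled unassigned.  With
    ``cut_method="hybrid"`` (or ``hybrid_assign``), unassigned genes are
    afterwards adopted by the module whose eigengene they correlate with
    best, when that correlation exceeds ``kme_min``.

    Modules are named by size rank with conventional color labels.
    """
    params = (params or RunConfig()).validate()
    genes = list(em.gene_ids)
    n = len(genes)
    if n < params.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all unassigned", n)
        labels = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene_id"))
        return ModulePartition(
            labels=labels,
            eigengenes=pd.DataFrame(columns=em.values.columns),
            membership=pd.Series(np.nan, index=labels.index),
            params=params,
        )

    if corr is None:
        corr = correlation_matrix(em.values, kind=params.correlation)
    elif list(corr.index) != genes:
        raise ValidationError("precomputed correlation matrix does not match the genes")
    A = signed_adjacency(corr, beta=params.beta)
    T = topological_overlap(A)
    dissim = 1.0 - T
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    cut_h = float(np.quantile(link[:, 2], params.cut_height_quantile))
    # tiny tolerance so merges that tie the cut height at float precision join
    raw = hierarchy.fcluster(link, t=cut_h + 1e-9 + 1e-6 * cut_h, criterion="distance")

    counts = pd.Series(raw).value_counts()
    keep_clusters = counts[counts >= params.min_module_size].index
    # order clusters by size descending, ties by smallest member gene id
    ordered = sorted(
        keep_clusters,
        key=lambda c: (-counts[c], min(g for g, r in zip(genes, raw) if r == c)),
    )
    name_of = {
        c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i + 1}")
        for i, c in enumerate(ordered)
    }
    labels = pd.Series(
        [name_of.get(r, UNASSIGNED) for r in raw], index=pd.Index(genes, name="gene_id")
    )

    def _compute_eigengenes(labels: pd.Series) -> pd.DataFrame:
        rows = {}
        for m in [name_of[c] for c in ordered]:
            sub = em.values.loc[labels == m].to_numpy(dtype=float)
            rows[m] = _eigengene(sub)
        return pd.DataFrame(rows, index=em.values.columns).T

    eigengenes = _compute_eigengenes(labels)

    if (params.cut_method == "hybrid" or params.hybrid_assign) and len(eigengenes):
        unassigned = labels.index[labels == UNASSIGNED]
        if len(unassigned):
            kme = _kme_matrix(em.values.loc[unassigned], eigengenes)
            best = kme.idxmax(axis=1)
            best_val = kme.max(axis=1)
            adopt = best_val > params.kme_min
            labels.loc[unassigned[adopt]] = best[adopt]
            if adopt.any():
                eigengenes = _compute_eigengenes(labels)

    membership = pd.Series(np.nan, index=labels.index, name="kME")
    for m in eigengenes.index:
        members = labels.index[labels == m]
        me = eigengenes.loc[m].to_numpy()
        for g in members:
            membership[g] = bicor(em.values.loc[g].to_numpy(), me)

    logger.info(
        "detected %d modules (%d/%d genes assigned) at cut height %.4f",
        len(eigengenes), int((labels != UNASSIGNED).sum()), n, cut_h,
    )
    return ModulePartition(
        labels=labels,
        eigengenes=eigengenes,
        membership=membership,
        linkage=link,
        cut_height=cut_h,
        params=params,
    )


def _kme_matrix(values: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    out = np.empty((len(values), len(eigengenes)))
    for j, m in enumerate(eigengenes.index):
        me = eigengenes.loc[m].to_numpy()
        for i in range(len(values)):
            out[i, j] = bicor(values.iloc[i].to_numpy(), me)
    return pd.DataFrame(out, index=values.index, columns=eigengenes.index)


def eigengene_age_correlation(partition: ModulePartition, ages: pd.Series) -> pd.Series:
    """Pearson correlation of each module eigengene with sample age."""
    ages = ages.loc[partition.eigengenes.columns].to_numpy(dtype=float)
    out = {}
    for m in partition.eigengenes.index:
        me = partition.eigengenes.loc[m].to_numpy()
        if me.std() == 0:
            raise ValidationError(f"module {m}: constant eigengene")
        out[m] = float(np.corrcoef(me, ages)[0, 1])
    return pd.Series(out, name="age_correlation")


def top_correlated_gene(
    values: pd.DataFrame,
    query_gene: str,
    candidate_set,
    kind: str = "bicor",
) -> tuple[str, float]:
    """Most highly co-expressed candidate for a query gene.

    Returns ``(gene_id, correlation)`` maximizing the network correlation;
    the query itself is excluded and ties break lexicographically.
    """
    candidates = sorted(set(candidate_set) - {query_gene})
    if not candidates:
        raise ValidationError("empty candidate set")
    if query_gene not in values.index:
        raise ValidationError(f"query gene {query_gene!r} not in matrix")
    q = values.loc[query_gene].to_numpy(dtype=float)
    corr_fn = bicor if kind == "bicor" else lambda a, b: float(np.corrcoef(a, b)[0, 1])
    best_gene, best_r = None, -np.inf
    for g in candidates:
        r = corr_fn(q, values.loc[g].to_numpy(dtype=float))
        if r > best_r:
            best_gene, best_r = g, r
    return best_gene, float(best_r)
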