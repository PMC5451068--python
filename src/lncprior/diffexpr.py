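"""Negative-binomial differential expression between two groups.

The model follows the standard NB count-regression framework: per-sample
size factors by median-of-ratios, a per-gene method-of-moments dispersion
(variance = mu + alpha * mu^2) with optional shrinkage toward the
across-gene mean, and a per-gene NB log-link GLM with a group indicator fit
by iteratively reweighted least squares.  Significance combines a BH-
adjusted Wald p-value < alpha with |log2 fold change| >= fc_min (inclusive),
the rule used throughout the downstream analysis.

The IRLS fit is vectorized across genes: the design matrix (intercept +
group indicator) is shared, so each iteration is a closed-form 2x2 weighted
least-squares solve per gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, ValidationError

logger = logging.getLogger("lncprior")

LN2 = float(np.log(2.0))
_MAX_ITER = 100
_TOL = 1e-8
_BETA_BOUND = 30.0


def collapse_technical_replicates(cm: CountMatrix) -> CountMatrix:
    """Sum counts across technical replicates of each biological sample.

    NB inference assumes independent biological units; summing technical
    replicates preserves the Poisson-process interpretation of the counts.
    Samples without replication pass through unchanged.
    """
    samples = cm.samples
    by_subject = samples.groupby("subject", sort=False)
    for subj, grp in by_subject:
        if grp["condition"].nunique() > 1:
            raise ValidationError(
                f"technical replicates of subject {subj!r} span multiple conditions"
            )
    subjects = list(dict.fromkeys(samples["subject"]))
    cols = {}
    rows = []
    for subj in subjects:
        grp = samples[samples["subject"] == subj]
        cols[subj] = cm.counts[list(grp["sample"])].sum(axis=1)
        rows.append({"sample": subj, "condition": grp["condition"].iloc[0], "subject": subj})
    collapsed = pd.DataFrame(cols, index=cm.counts.index)
    return CountMatrix(counts=collapsed, samples=pd.DataFrame(rows))


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``s_j = median_g count_gj / geomean_g`` over genes expressed in every
    sample.  If no gene is nonzero everywhere, pass ``pseudo_reference=True``
    to build the reference from positive counts only.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.where(arr > 0, np.log(arr), np.nan)
    if pseudo_reference:
        # geometric mean over positive counts only
        with np.errstate(invalid="ignore"):
            log_ref = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValidationError("no usable reference genes for size-factor estimation")
    else:
        usable = (arr > 0).all(axis=1)
        if not usable.any():
            raise ValidationError(
                "no gene has nonzero counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        log_ref = np.nanmean(logs, axis=1)
    with np.errstate(invalid="ignore"):
        ratios = np.exp(logs[usable] - log_ref[usable, None])
    s = np.nanmedian(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: pd.Series,
    alpha_floor: float = 1e-8,
    shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each group, ``alpha = (var - mean) / mean^2``; group estimates are
    pooled by degrees of freedom, floored at ``alpha_floor``, and optionally
    shrunk toward the across-gene mean with weight ``shrinkage``.  Genes with
    zero mean are flagged untestable.

    Returns a frame with columns ``alpha`` and ``testable``.
    """
    if not 0 <= shrinkage <= 1:
        raise ValidationError("shrinkage weight must be in [0, 1]")
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    groups = conditions.to_numpy()
    alphas = np.zeros(norm.shape[0])
    weight_sum = np.zeros(norm.shape[0])
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = sub.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / (mu * mu)
        a = np.where(mu > 0, a, 0.0)
        alphas += df * a
        weight_sum += df
    alphas = alphas / weight_sum
    alphas = np.maximum(alpha_floor, alphas)
    testable = counts.to_numpy().sum(axis=1) > 0
    if shrinkage > 0 and testable.any():
        trend = float(alphas[testable].mean())
        alphas = (1.0 - shrinkage) * alphas + shrinkage * trend
        alphas = np.maximum(alpha_floor, alphas)
    return pd.DataFrame({"alpha": alphas, "testable": testable}, index=counts.index)


def _irls_two_group(
    y: np.ndarray, log_s: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB GLM fit, one intercept+slope model per row of ``y``.

    Returns (beta, se_slope, converged); beta has shape (G, 2).
    """
    G, n = y.shape
    beta = np.zeros((G, 2))
    mu0 = np.maximum(y.mean(axis=1), 0.5)
    beta[:, 0] = np.log(mu0)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    x2 = x * x
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        b = beta[active]
        eta = b[:, [0]] + b[:, [1]] * x[None, :] + log_s[None, :]
        mu = np.exp(np.clip(eta, -_BETA_BOUND, _BETA_BOUND))
        W = mu / (1.0 + alpha[active, None] * mu)
        z = (eta - log_s[None, :]) + (y[active] - mu) / mu
        a11 = W.sum(axis=1)
        a12 = (W * x[None, :]).sum(axis=1)
        a22 = (W * x2[None, :]).sum(axis=1)
        b1 = (W * z).sum(axis=1)
        b2 = (W * z * x[None, :]).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new0 = (a22 * b1 - a12 * b2) / det
        new1 = (a11 * b2 - a12 * b1) / det
        new = np.column_stack([new0, new1])
        new = np.clip(new, -_BETA_BOUND, _BETA_BOUND)
        bad = ~np.isfinite(new).all(axis=1)
        new[bad] = b[bad]
        delta = np.abs(new - b).max(axis=1)
        beta[active] = new
        done = (delta < _TOL) & ~bad
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        still = np.zeros_like(active)
        still[idx[~done & ~bad]] = True
        active = still
    # final SE at converged beta
    eta = beta[:, [0]] + beta[:, [1]] * x[None, :] + log_s[None, :]
    mu = np.exp(np.clip(eta, -_BETA_BOUND, _BETA_BOUND))
    W = mu / (1.0 + alpha[:, None] * mu)
    a11 = W.sum(axis=1)
    a12 = (W * x[None, :]).sum(axis=1)
    a22 = (W * x2[None, :]).sum(axis=1)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(a11 / det)
    # estimates pinned at the bound did not truly converge
    converged &= np.abs(beta).max(axis=1) < _BETA_BOUND
    return beta, se, converged


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.DataFrame,
    conditions: pd.Series,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    case_label: str = "case",
) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs control.

    Positive log2 fold change means higher expression in the case group.
    BH adjustment runs over testable, converged genes only; a gene is
    ``significant`` iff adj_p < ``alpha`` and |log2fc| >= ``fc_min``.
    """
    labels = conditions.to_numpy()
    uniq = set(labels)
    if len(uniq) != 2:
        raise ValidationError(f"expected exactly two groups, got {sorted(uniq)}")
    if case_label not in uniq:
        raise ValidationError(f"case label {case_label!r} not among groups {sorted(uniq)}")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 biological samples")

    x = (labels == case_label).astype(float)
    y = counts.to_numpy(dtype=float)
    log_s = np.log(sf.to_numpy(dtype=float))
    testable = dispersions["testable"].to_numpy()
    disp = dispersions["alpha"].to_numpy()

    beta = np.full((len(counts), 2), np.nan)
    se = np.full(len(counts), np.nan)
    conv = np.zeros(len(counts), dtype=bool)
    if testable.any():
        b, s_, c = _irls_two_group(y[testable], log_s, x, disp[testable])
        beta[testable] = b
        se[testable] = s_
        conv[testable] = c

    log2fc = beta[:, 1] / LN2
    se_l2 = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, 1] / se
    p = np.where(conv, 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    norm = y / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    adj_p = np.full(len(counts), np.nan)
    ok = conv & np.isfinite(p)
    if ok.any():
        adj_p[ok] = multipletests(p[ok], method="fdr_bh")[1]

    significant = ok & (adj_p < alpha) & (np.abs(log2fc) >= fc_min)
    n_skip = int((~conv & testable).sum())
    if n_skip:
        logger.warning("%d genes failed to converge and were excluded from BH", n_skip)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_l2,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
            "testable": testable,
            "converged": conv,
        }
    ).set_index("gene_id", drop=False)


def run_de(
    cm: CountMatrix,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    shrinkage: float = 0.5,
    collapse: bool = True,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full DE stage: collapse replicates, normalize, estimate, test."""
    if collapse and cm.samples["subject"].duplicated().any():
        cm = collapse_technical_replicates(cm)
    sf = size_factors(cm.counts, pseudo_reference=pseudo_reference)
    conditions = pd.Series(cm.samples["condition"].to_numpy(), index=cm.counts.columns)
    disp = estimate_dispersion(cm.counts, sf, conditions, shrinkage=shrinkage)
    return nb_wald_test(cm.counts, sf, disp, conditions, alpha=alpha, fc_min=fc_min)
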