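"""Tissue-selectivity scoring from a multi-tissue median-expression matrix.

A gene is brain-selective when its fractional brain expression — total
expression over brain tissues divided by total over all retained tissues,
times 100 — strictly exceeds a threshold (default 50%).  Tissues backed by
fewer than 50 donors are dropped before scoring.  Values are treated as
unit-agnostic nonnegative abundances (RPKM/FPKM/TPM alike), since the
fraction is invariant to any positive per-gene rescaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, ValidationError


def filter_tissues(panel: pd.DataFrame, min_samples: int = 50) -> pd.DataFrame:
    """Drop tissues with fewer than ``min_samples`` donors (boundary kept)."""
    if panel.empty:
        raise ValidationError("empty tissue panel")
    kept = panel[panel["n_samples"] >= min_samples]
    if kept.empty:
        raise ValidationError(f"no tissue has at least {min_samples} samples")
    return kept


def fractional_brain_expression(expr_row: pd.Series, panel: pd.DataFrame) -> float:
    """100 * (sum over brain tissues) / (sum over all tissues); NaN if all zero."""
    vals = expr_row.loc[panel.index].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("negative expression value in tissue profile")
    total = vals.sum()
    if total == 0:
        return float("nan")
    brain = vals[panel["is_brain"].to_numpy(dtype=bool)].sum()
    return 100.0 * brain / total


def zscore_profile(expr_row: pd.Series, population_sd: bool = True) -> tuple[pd.Series, bool]:
    """Z-score a profile across tissues; constant rows give zeros plus a flag.

    Population (n-denominator) standard deviation by default: the profile is
    normalized for comparison/clustering, not for inference.
    """
    x = expr_row.to_numpy(dtype=float)
    if x.size < 2:
        raise ValidationError("z-score profile requires at least two tissues")
    sd = x.std(ddof=0 if population_sd else 1)
    if sd == 0:
        return pd.Series(np.zeros_like(x), index=expr_row.index), True
    return pd.Series((x - x.mean()) / sd, index=expr_row.index), False


def score_specificity(
    em: ExpressionMatrix,
    min_samples: int = 50,
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Score every gene: fractional brain expression, selectivity call, Z-profile.

    ``brain_selective`` is a strict comparison with ``threshold``; genes with
    zero total expression are reported with NaN fraction and called
    non-selective explicitly.
    """
    panel = filter_tissues(em.meta, min_samples=min_samples)
    vals = em.values[list(panel.index)]
    arr = vals.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative expression value")
    total = arr.sum(axis=1)
    brain_mask = panel["is_brain"].to_numpy(dtype=bool)
    brain = arr[:, brain_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, 100.0 * brain / total, np.nan)
    selective = np.where(np.isnan(frac), False, frac > threshold)

    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mean) / sd, 0.0)

    out = pd.DataFrame(
        {
            "gene_id": em.gene_ids,
            "fractional_brain_expression": frac,
            "brain_selective": selective.astype(bool),
            "constant_profile": constant,
        }
    ).set_index("gene_id", drop=False)
    z_cols = pd.DataFrame(z, index=out.index, columns=[f"z_{t}" for t in panel.index])
    return pd.concat([out, z_cols], axis=1)


def tissue_ordering(em: ExpressionMatrix, min_samples: int = 50) -> list[str]:
    """Leaf order of average-linkage clustering of tissues on Z-profiles.

    Presentation utility only (heatmap column ordering); no statistics.
    """
    panel = filter_tissues(em.meta, min_samples=min_samples)
    arr = em.values[list(panel.index)].to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    mean = arr.mean(axis=1, keepdims=True)
    z = np.where(sd > 0, (arr - mean) / sd, 0.0)
    if z.shape[1] < 3:
        return list(panel.index)
    link = hierarchy.linkage(pdist(z.T), method="average")
    order = hierarchy.leaves_list(link)
    return [panel.index[i] for i in order]
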