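import math

import numpy as np
import pandas as pd
import pytest

from lncprior.association_stats import (
    bh_adjust,
    enrich_modules,
    fisher_enrichment,
    lncrna_geneset_coexpression_test,
    module_coexpression_test,
    module_de_overlay_test,
)
from lncprior.coexpr_network import correlation_matrix
from lncprior.io_formats import ValidationError


def _noise_corr(rng, n_genes=60, n_samples=30):
    X = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
    )
    return correlation_matrix(X)


def _labels(corr, module_genes, name="turquoise"):
    lab = pd.Series("unassigned", index=corr.index)
    lab[list(module_genes)] = name
    return lab


# ---------------------------------------------------------------------------
# module co-expression test
# ---------------------------------------------------------------------------


def test_perfect_module_gets_minimal_p(rng):
    """A perfectly correlated module beats every random draw: p = 1/(B+1)."""
    t = np.linspace(0, 2 * np.pi, 30)
    X = np.vstack([np.sin(t) + rng.normal(0, 0.01, 30) for _ in range(10)]
                  + [rng.normal(size=30) for _ in range(50)])
    corr = correlation_matrix(pd.DataFrame(X, index=[f"g{i}" for i in range(60)]))
    labels = _labels(corr, [f"g{i}" for i in range(10)])
    B = 200
    res = module_coexpression_test(corr, labels, B=B, seed=0)
    assert res["p"].iloc[0] == pytest.approx(1 / (B + 1))
    assert res["observed"].iloc[0] > res["null_mean"].iloc[0]


def test_coexpression_null_distribution_is_seed_deterministic(rng):
    corr = _noise_corr(rng)
    labels = _labels(corr, [f"g{i}" for i in range(8)])
    a = module_coexpression_test(corr, labels, B=100, seed=42)
    b = module_coexpression_test(corr, labels, B=100, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_module_smaller_than_two_rejected(rng):
    corr = _noise_corr(rng, n_genes=10)
    labels = _labels(corr, ["g0"])
    with pytest.raises(ValidationError, match="fewer than 2"):
        module_coexpression_test(corr, labels, B=10, seed=0)


# ---------------------------------------------------------------------------
# DE overlay test
# ---------------------------------------------------------------------------


def _de_table(gene_ids, lfc, significant):
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "significant": significant}
    ).set_index("gene_id", drop=False)


def test_overlay_all_null_gives_p_one(rng):
    corr = _noise_corr(rng)
    labels = _labels(corr, [f"g{i}" for i in range(10)])
    de = _de_table(list(corr.index), rng.normal(size=60), [False] * 60)
    res = module_de_overlay_test(labels, de, B=50, seed=0)
    assert res["observed"].iloc[0] == 0.0
    assert res["p"].iloc[0] == 1.0


def test_overlay_loaded_module_detected(rng):
    """A module full of significant down-regulated genes in a null background."""
    corr = _noise_corr(rng, n_genes=200)
    members = [f"g{i}" for i in range(20)]
    labels = _labels(corr, members)
    lfc = np.zeros(200)
    sig = np.zeros(200, dtype=bool)
    lfc[:20] = -2.0
    sig[:20] = True
    de = _de_table(list(corr.index), lfc, sig)
    B = 500
    res = module_de_overlay_test(labels, de, B=B, seed=1)
    assert res["observed"].iloc[0] == pytest.approx(-2.0)
    assert res["p"].iloc[0] == pytest.approx(1 / (B + 1))
    assert res["direction"].iloc[0] == -1


def test_overlay_handles_genes_missing_from_de(rng):
    """Network genes without DE results contribute fold change zero."""
    corr = _noise_corr(rng, n_genes=30)
    labels = _labels(corr, [f"g{i}" for i in range(5)])
    de = _de_table(["g0", "g1"], [1.5, 2.5], [True, True])
    res = module_de_overlay_test(labels, de, B=50, seed=0)
    assert res["observed"].iloc[0] == pytest.approx((1.5 + 2.5) / 5)


# ---------------------------------------------------------------------------
# lncRNA / gene-set summed-correlation test
# ---------------------------------------------------------------------------


def test_setcor_shared_factor_detected(rng):
    t = np.linspace(0, 2 * np.pi, 40)
    f = np.sin(t)
    def member():
        return 0.9 * f + math.sqrt(1 - 0.81) * rng.normal(size=40)
    X = np.vstack([member() for _ in range(6)]      # lncRNAs
                  + [member() for _ in range(8)]    # risk genes
                  + [rng.normal(size=40) for _ in range(80)])
    corr = correlation_matrix(pd.DataFrame(X, index=[f"g{i}" for i in range(94)]))
    lnc = [f"g{i}" for i in range(6)]
    risk = {f"g{i}" for i in range(6, 14)}
    B = 300
    res = lncrna_geneset_coexpression_test(corr, lnc, {"risk": risk}, B=B, seed=0)
    assert res["p"].iloc[0] == pytest.approx(1 / (B + 1))


def test_setcor_excludes_self_pairs_and_observed_stable_in_B(rng):
    corr = _noise_corr(rng, n_genes=40)
    lnc = [f"g{i}" for i in range(5)]
    overlapping = {"s": {"g0", "g10", "g11"}}  # g0 is also a lncRNA
    r1 = lncrna_geneset_coexpression_test(corr, lnc, overlapping, B=50, seed=3)
    r2 = lncrna_geneset_coexpression_test(corr, lnc, overlapping, B=100, seed=3)
    assert r1["observed"].iloc[0] == pytest.approx(r2["observed"].iloc[0])
    # manual observed: sum of corr between lnc and set members, minus self pair
    C = corr.to_numpy()
    idx = {g: i for i, g in enumerate(corr.index)}
    manual = sum(
        C[idx[l], idx[s]] for l in lnc for s in overlapping["s"] if l != s
    )
    assert r1["observed"].iloc[0] == pytest.approx(manual, abs=1e-10)


def test_empirical_p_never_zero(rng):
    """Every permutation p respects the +1 correction: p >= 1/(B+1)."""
    corr = _noise_corr(rng, n_genes=50)
    labels = _labels(corr, [f"g{i}" for i in range(25)])
    for B in (10, 99):
        res = module_coexpression_test(corr, labels, B=B, seed=0)
        assert (res["p"] >= 1 / (B + 1) - 1e-12).all()
        assert (res["p"] > 0).all()


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def hypergeom_tail_oracle(N, n_set, m_module, a):
    """Exhaustive enumeration of P(X >= a) for the 2x2 overlap table."""
    total = math.comb(N, n_set)
    return sum(
        math.comb(m_module, k) * math.comb(N - m_module, n_set - k)
        for k in range(a, min(m_module, n_set) + 1)
    ) / total


class TestFisherEnrichment:
    def test_worked_example(self):
        """N=20, m=5, n=4, a=3: p = 155/4845 and OR = 21."""
        universe = {f"g{i}" for i in range(20)}
        module = {"g0", "g1", "g2", "g3", "g4"}
        gene_set = {"g0", "g1", "g2", "g10"}
        res = fisher_enrichment(module, gene_set, universe)
        assert res["p"] == pytest.approx(155 / 4845, abs=1e-12)
        assert res["odds_ratio"] == pytest.approx(21.0)
        assert res["overlap"] == 3

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(10, 61))
            m = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = {f"g{i}" for i in range(N)}
            module = set(rng.choice(sorted(universe), size=m, replace=False))
            gene_set = set(rng.choice(sorted(universe), size=n, replace=False))
            res = fisher_enrichment(module, gene_set, universe)
            expected = hypergeom_tail_oracle(N, n, m, res["overlap"])
            assert res["p"] == pytest.approx(expected, abs=1e-10)

    def test_zero_overlap_is_never_enriched(self):
        universe = {f"g{i}" for i in range(30)}
        labels = pd.Series(
            ["turquoise"] * 10 + ["unassigned"] * 20, index=sorted(universe)
        )
        gene_set = set(labels.index[10:15])
        df = enrich_modules(labels, {"s": gene_set}, universe)
        assert df["overlap"].iloc[0] == 0
        assert df["odds_ratio"].iloc[0] < 1
        assert not df["enriched"].iloc[0]

    def test_module_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(12)}
        res = fisher_enrichment(universe, {"g0", "g5"}, universe)
        assert res["p"] == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="subset"):
            fisher_enrichment({"a"}, {"zzz"}, {"a", "b"})


def test_generic_overrepresentation_interface():
    """Any term -> gene map works through the same enrichment machinery."""
    genes = [f"g{i}" for i in range(40)]
    labels = pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=genes)
    terms = {"synapse": set(genes[:15]), "immune": set(genes[20:30])}
    df = enrich_modules(labels, terms, alpha=0.05)
    t = df.set_index(["module", "gene_set"])
    assert t.loc[("turquoise", "synapse"), "enriched"]
    assert t.loc[("blue", "immune"), "enriched"]
    assert not t.loc[("blue", "synapse"), "enriched"]


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_independent_step_up(self, rng):
        p = rng.uniform(size=57)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        prev = 1.0
        for back, idx in enumerate(order[::-1]):
            prev = min(prev, p[idx] * m / (m - back))
            adj[idx] = prev
        assert np.allclose(bh_adjust(p), adj, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
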