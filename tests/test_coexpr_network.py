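import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from sklearn.metrics import adjusted_rand_score

from lncprior.coexpr_network import (
    ModulePartition,
    bicor,
    correlation_matrix,
    detect_modules,
    eigengene_age_correlation,
    signed_adjacency,
    top_correlated_gene,
    topological_overlap,
    variance_filter,
)
from lncprior.io_formats import RunConfig, ValidationError
from lncprior.synthetic_data import SimulationConfig, simulate_developmental_matrix

from conftest import make_expression_matrix


# ---------------------------------------------------------------------------
# Independent oracles, written straight from the definitions
# ---------------------------------------------------------------------------


def bicor_oracle(x, y):
    """Direct transliteration of the biweight midcorrelation definition."""
    def dev(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    dx, dy = dev(np.asarray(x, float)), dev(np.asarray(y, float))
    return np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2))


def tom_oracle(A):
    """Triple-loop topological overlap."""
    n = A.shape[0]
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            T[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return T


# ---------------------------------------------------------------------------
# variance filter
# ---------------------------------------------------------------------------


def test_variance_filter_keeps_top_half(rng):
    base = rng.normal(0, 1, size=(8, 30))
    scales = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
    em = make_expression_matrix(np.abs(base * scales[:, None]) + 1)
    kept = variance_filter(em)
    var = em.values.var(axis=1, ddof=1).sort_values()
    assert set(kept.gene_ids) == set(var.index[-4:])


def test_variance_filter_tie_rule_keeps_everything():
    em = make_expression_matrix(np.tile([1.0, 2.0, 3.0, 6.0], (5, 1)))
    assert len(variance_filter(em).values) == 5


def test_variance_filter_order_invariant(rng):
    em = make_expression_matrix(np.abs(rng.normal(0, 1, size=(11, 20))))
    kept = set(variance_filter(em).gene_ids)
    perm = rng.permutation(len(em.values))
    em2 = make_expression_matrix(em.values.to_numpy()[perm])
    from_perm = {em.values.index[perm[i]] for i, g in enumerate(em2.values.index)
                 if g in set(variance_filter(em2).gene_ids)}
    # map permuted kept genes back to original ids
    kept2 = {em.values.index[perm[int(g[1:]) - 1]] for g in variance_filter(em2).gene_ids}
    assert kept == kept2


# ---------------------------------------------------------------------------
# bicor
# ---------------------------------------------------------------------------


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(0, 1, 25)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_image_is_minus_one(self, rng):
        x = rng.normal(0, 1, 25)
        assert bicor(x, 3.0 - 2.0 * x) == pytest.approx(-1.0, abs=1e-12)

    def test_outlier_example_matches_oracle_and_differs_from_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        expected = bicor_oracle(x, y)
        assert bicor(x, y) == pytest.approx(expected, abs=1e-12)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(bicor(x, y) - pearson) > 0.05

    def test_errors(self):
        with pytest.raises(ValidationError, match="mismatch"):
            bicor([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError, match="length"):
            bicor([1, 2], [3, 4])

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])  # MAD = 0
        y = np.array([2.0, 1.0, 3.0, 1.5, 8.0])
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian_data(self, rng):
        """Without outliers the robust estimate tracks Pearson closely."""
        for _ in range(20):
            z = rng.normal(size=1000)
            x = z + rng.normal(size=1000)
            y = z + rng.normal(size=1000)
            assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.normal(0, 1, size=(12, 30))
        X[3] = np.concatenate([np.ones(16), rng.normal(5, 1, 14)])  # MAD 0 row
        df = pd.DataFrame(X)
        C = correlation_matrix(df).to_numpy()
        for i in range(12):
            for j in range(12):
                assert C[i, j] == pytest.approx(bicor(X[i], X[j]), abs=1e-10)


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------


class TestSignedAdjacency:
    def test_endpoints_and_closed_form(self):
        C = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 0.5], [-1.0, 0.5, 1.0]])
        A = signed_adjacency(C, beta=12.0)
        assert A[0, 2] == pytest.approx(0.0, abs=1e-30)
        assert A[0, 1] == pytest.approx(2.0 ** -12, abs=1e-18)
        assert np.allclose(np.diag(A), 1.0)

    def test_monotone_in_correlation(self):
        cs = np.linspace(-1, 1, 21)
        a = ((1 + cs) / 2) ** 12
        assert (np.diff(a) > 0).all()
        C = np.eye(2)
        with pytest.raises(ValidationError, match="beta"):
            signed_adjacency(C, beta=0.5)


class TestTopologicalOverlap:
    def test_two_gene_closed_form(self):
        a = 0.37
        A = np.array([[1.0, a], [a, 1.0]])
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(a, abs=1e-12)

    def test_identical_binary_rows_full_overlap(self):
        # i and j fully connected to each other and the same neighbours
        A = np.array(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
        )
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        M = rng.uniform(0, 1, size=(10, 10))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(topological_overlap(A), tom_oracle(A), atol=1e-10)

    def test_rejects_asymmetric(self, rng):
        A = rng.uniform(0, 1, size=(4, 4))
        with pytest.raises(ValidationError, match="symmetric"):
            topological_overlap(A)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


def _two_orthogonal_modules(n_samples=40, size=30):
    t = np.linspace(0, 4 * np.pi, n_samples)
    f1, f2 = np.sin(t), np.cos(t)
    X = np.vstack([np.outer(np.ones(size), f1), np.outer(np.ones(size), f2)])
    X = X + np.linspace(0.1, 1, 2 * size)[:, None] * 0.0  # exact copies
    X = X - X.min(axis=1, keepdims=True)
    return make_expression_matrix(X), np.array([0] * size + [1] * size)


def test_noiseless_orthogonal_modules_fully_recovered():
    em, truth = _two_orthogonal_modules()
    part = detect_modules(em, params=RunConfig(min_module_size=10))
    labels = part.labels.to_numpy()
    assert len(part.eigengenes) == 2
    assert adjusted_rand_score(truth, labels) == 1.0


def test_planted_modules_recovered_at_strength_07():
    """Scaled-down analogue of the study's network: 4 planted modules plus
    background recovered with high agreement."""
    aris = []
    for seed in range(5):
        cfg = SimulationConfig(
            seed=seed, n_genes=600, n_lncRNAs=60, module_sizes=(100, 80, 60, 40),
            module_strength=0.7, n_dev_samples=100,
        )
        em, truth = simulate_developmental_matrix(cfg)
        part = detect_modules(em)
        aris.append(adjusted_rand_score(truth.module_labels, part.labels))
    assert np.mean(aris) >= 0.8


def test_partition_structure_invariants(small_sim_cfg):
    em, _ = simulate_developmental_matrix(small_sim_cfg)
    part = detect_modules(em, params=RunConfig(min_module_size=20))
    assert set(part.labels.index) == set(em.gene_ids)
    sizes = part.sizes
    for m in part.module_names:
        assert sizes[m] >= 20
    # eigengenes have unit population variance
    for m in part.module_names:
        assert part.eigengenes.loc[m].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    # kME defined for assigned genes
    assigned = part.labels != "unassigned"
    assert part.membership[assigned].notna().all()


def test_detection_invariant_to_gene_order(small_sim_cfg, rng):
    em, _ = simulate_developmental_matrix(small_sim_cfg)
    part1 = detect_modules(em)
    perm = rng.permutation(len(em.values))
    em2 = replace(em, values=em.values.iloc[perm])
    part2 = detect_modules(em2)
    joined = pd.concat([part1.labels, part2.labels.loc[part1.labels.index]], axis=1)
    assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0


def test_too_few_genes_yields_unassigned_partition():
    em = make_expression_matrix(np.abs(np.random.default_rng(0).normal(size=(5, 10))))
    part = detect_modules(em, params=RunConfig(min_module_size=30))
    assert (part.labels == "unassigned").all()


def test_eigengene_follows_common_trajectory():
    t = np.linspace(0, 1, 50)
    X = np.tile(t, (20, 1)) + 0.0
    em = make_expression_matrix(X)
    part = detect_modules(em, params=RunConfig(min_module_size=5, cut_height_quantile=0.9))
    assert len(part.eigengenes) == 1
    me = part.eigengenes.iloc[0].to_numpy()
    assert np.corrcoef(me, t)[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_eigengene_age_correlation():
    ages = pd.Series(
        np.linspace(1, 100, 30), index=[f"s{j+1}" for j in range(30)]
    )
    me = (ages - ages.mean()) / ages.std(ddof=0)
    eig = pd.DataFrame([me.to_numpy()], index=["turquoise"], columns=ages.index)
    part = ModulePartition(
        labels=pd.Series(), eigengenes=eig, membership=pd.Series()
    )
    r = eigengene_age_correlation(part, ages)
    assert r["turquoise"] == pytest.approx(1.0, abs=1e-12)
    # orthogonalized eigengene has ~zero correlation
    resid = np.sin(np.linspace(0, 20, 30))
    resid = resid - np.polyval(np.polyfit(ages, resid, 1), ages)
    eig2 = pd.DataFrame([resid / resid.std()], index=["blue"], columns=ages.index)
    part2 = ModulePartition(labels=pd.Series(), eigengenes=eig2, membership=pd.Series())
    assert abs(eigengene_age_correlation(part2, ages)["blue"]) < 1e-9


def test_monotone_module_eigengene_tracks_age():
    cfg = SimulationConfig(
        seed=9, n_genes=300, n_lncRNAs=30, module_sizes=(60,),
        module_strength=0.9, n_dev_samples=100, n_lnc_in_module=5,
    )
    em, truth = simulate_developmental_matrix(cfg)
    part = detect_modules(em)
    r = eigengene_age_correlation(part, em.meta["age_months"])
    assert r.abs().max() > 0.5


# ---------------------------------------------------------------------------
# top correlated gene
# ---------------------------------------------------------------------------


class TestTopCorrelatedGene:
    def test_identical_profile_wins(self, rng):
        X = rng.normal(size=(6, 30))
        X[4] = X[0]
        df = pd.DataFrame(X, index=[f"g{i+1}" for i in range(6)])
        gene, r = top_correlated_gene(df, "g1", {"g3", "g4", "g5", "g6"})
        assert gene == "g5"
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_partner_found(self):
        cfg = SimulationConfig(
            seed=2, n_genes=200, n_lncRNAs=20, module_sizes=(30,),
            module_strength=0.95, n_dev_samples=80, n_lnc_in_module=3,
        )
        em, truth = simulate_developmental_matrix(cfg)
        lnc = sorted(truth.lnc_in_risk_module)[0]
        risk = truth.risk_genes & set(
            truth.module_labels.index[truth.module_labels == "M1"]
        )
        gene, r = top_correlated_gene(em.values, lnc, set(em.gene_ids) - {lnc})
        assert truth.module_labels[gene] == "M1"
        assert r > 0.8

    def test_candidate_order_irrelevant_and_errors(self, rng):
        X = rng.normal(size=(5, 20))
        df = pd.DataFrame(X, index=[f"g{i+1}" for i in range(5)])
        a = top_correlated_gene(df, "g1", ["g2", "g3", "g4"])
        b = top_correlated_gene(df, "g1", ["g4", "g3", "g2"])
        assert a == b
        with pytest.raises(ValidationError, match="empty"):
            top_correlated_gene(df, "g1", {"g1"})
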