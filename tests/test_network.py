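"""Network core: adjacency, TOM, clustering, eigengenes, K and GS."""

import numpy as np
import pytest

import cohub.network as net
from cohub.datatypes import ExpressionMatrix, PhenotypeTable
from cohub.network import (
    CoexpressionAnalysis,
    adjacency_from_correlation,
    average_linkage_dendrogram,
    correlation_matrix,
    gene_network_scores,
    module_eigengene,
    module_trait_correlation,
    pick_soft_power,
    static_cut_modules,
    tom_from_adjacency,
)
from cohub.simulate import generate_synthetic_study

from conftest import small_study


def matrix_from(values, platform="P1"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        platform=[platform] * values.shape[1],
        values=values,
    )


def tom_oracle(adj):
    """Independent triple-loop topological overlap."""
    n = adj.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(adj[i, u] * adj[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(adj[i, u] for u in range(n) if u != i)
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + adj[i, j]) / (min(k_i, k_j) + 1 - adj[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestCorrelation:
    def test_identical_and_negated_rows(self):
        x = np.arange(5.0)
        cor = correlation_matrix(matrix_from([x, x, -x]))
        assert cor[0, 1] == pytest.approx(1.0)
        assert cor[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(cor), 1.0)

    def test_matches_naive_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((10, 50))
        cor = correlation_matrix(matrix_from(values))
        centered = values - values.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / values.shape[1]
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(cor, cov / np.outer(sd, sd), atol=1e-12)

    def test_constant_row_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            correlation_matrix(matrix_from([[1, 2, 3], [5, 5, 5]]))


class TestAdjacency:
    @pytest.mark.parametrize("cor,beta,expected", [(0.5, 6, 0.015625), (-0.5, 6, 0.015625)])
    def test_unsigned_power(self, cor, beta, expected):
        c = np.array([[1.0, cor], [cor, 1.0]])
        assert adjacency_from_correlation(c, beta)[0, 1] == pytest.approx(expected)

    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(0)
        c = np.clip(random_adjacency(rng, 6) * 2 - 1, -1, 1)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2
        np.testing.assert_allclose(adjacency_from_correlation(c, 1), np.abs(c))


class TestTom:
    def test_complete_graph_is_all_ones(self):
        adj = np.ones((5, 5))
        np.testing.assert_allclose(tom_from_adjacency(adj), np.ones((5, 5)))

    def test_three_node_shared_neighbour_case(self):
        adj = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        tom = tom_from_adjacency(adj)
        # l_12 = 0, min(k) = 0.5, denominator 0.5 + 1 - 0.5 = 1 -> TOM = 0.5
        assert tom[1, 2] == pytest.approx(0.25 / 1.5)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_empty_graph_has_zero_overlap(self):
        tom = tom_from_adjacency(np.eye(4))
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_array_equal(off, 0.0)

    def test_matches_triple_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            adj = random_adjacency(rng, 12)
            np.testing.assert_allclose(tom_from_adjacency(adj), tom_oracle(adj), atol=1e-10)

    def test_range_preserved_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tom = tom_from_adjacency(random_adjacency(rng, 15))
            assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        adj = np.eye(3)
        adj[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_from_adjacency(adj)


class TestDendrogramAndCut:
    def test_two_points_merge_at_their_dissimilarity(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        z = average_linkage_dendrogram(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.3)

    def test_two_tight_blocks_merge_last_at_between_distance(self):
        # 4 points: pairs {0,1} and {2,3} at 0.1 inside, 0.9 across
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        z = average_linkage_dendrogram(d)
        np.testing.assert_allclose(sorted(z[:, 2]), [0.1, 0.1, 0.9])

    def test_equal_dissimilarity_merges_at_common_height(self):
        d = np.full((4, 4), 0.4)
        np.fill_diagonal(d, 0.0)
        z = average_linkage_dendrogram(d)
        np.testing.assert_allclose(z[:, 2], 0.4)

    def test_static_cut_finds_two_well_separated_blocks(self):
        rng = np.random.default_rng(5)
        n1, n2 = 30, 40
        d = np.full((n1 + n2, n1 + n2), 0.97) + rng.random((n1 + n2, n1 + n2)) * 0.001
        d = (d + d.T) / 2
        d[:n1, :n1] = 0.2
        d[n1:, n1:] = 0.2
        np.fill_diagonal(d, 0.0)
        z = average_linkage_dendrogram(d)
        part = static_cut_modules(z, [f"g{i}" for i in range(n1 + n2)], 0.95, 25)
        assert part.sizes() == {"M1": 40, "M2": 30}
        # deterministic naming: M1 is the larger block
        assert part.module_label[0] == "M2" and part.module_label[-1] == "M1"

    def test_undersized_cluster_is_unassigned(self):
        d = np.full((8, 8), 0.1)
        np.fill_diagonal(d, 0.0)
        z = average_linkage_dendrogram(d)
        part = static_cut_modules(z, [f"g{i}" for i in range(8)], 0.95, 100)
        assert set(part.module_label) == {"unassigned"}

    def test_cut_at_height_one_gives_single_module(self):
        rng = np.random.default_rng(6)
        d = rng.random((12, 12)) * 0.5
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        z = average_linkage_dendrogram(d)
        part = static_cut_modules(z, [f"g{i}" for i in range(12)], 1.0, 5)
        assert part.sizes() == {"M1": 12}


class TestPickSoftPower:
    def test_first_sustained_crossing(self, monkeypatch):
        r2 = {1: 0.5, 2: 0.7, 3: 0.85}
        monkeypatch.setattr(net, "scale_free_fit", lambda adj, n_bins=10: r2[adj[0, 1]])
        monkeypatch.setattr(
            net, "adjacency_from_correlation",
            lambda cor, beta, signed=False: np.array([[1.0, beta], [beta, 1.0]]),
        )
        assert pick_soft_power(
            np.eye(2), candidates=[1, 2, 3], r2_threshold=0.8, min_mean_connectivity=0.0
        ) == 3

    def test_isolated_crossing_not_trusted(self, monkeypatch):
        r2 = {1: 0.5, 2: 0.85, 3: 0.5, 4: 0.6}
        monkeypatch.setattr(net, "scale_free_fit", lambda adj, n_bins=10: r2[adj[0, 1]])
        monkeypatch.setattr(
            net, "adjacency_from_correlation",
            lambda cor, beta, signed=False: np.array([[1.0, beta], [beta, 1.0]]),
        )
        beta = pick_soft_power(np.eye(2), candidates=[1, 2, 3, 4], r2_threshold=0.8,
                               n_samples=300, min_mean_connectivity=0.0)
        assert beta == 6  # falls back to the sample-size default

    def test_reproducible_on_synthetic_data(self):
        m, _, _ = generate_synthetic_study(small_study(seed=21))
        cor = correlation_matrix(m)
        b1 = pick_soft_power(cor, n_samples=m.n_samples)
        b2 = pick_soft_power(cor, n_samples=m.n_samples)
        assert b1 == b2


class TestEigengene:
    def test_identical_rows_reproduce_common_profile(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        m = matrix_from([profile, profile, profile])
        eig = module_eigengene(m, m.gene_ids)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, z / np.linalg.norm(z), atol=1e-12)
        assert abs(np.corrcoef(eig, profile)[0, 1]) == pytest.approx(1.0)

    def test_sign_convention_survives_global_flip(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((6, 20))
        m = matrix_from(values)
        eig = module_eigengene(m, m.gene_ids)
        eig_flipped = module_eigengene(matrix_from(-values), m.gene_ids)
        np.testing.assert_allclose(eig, -eig_flipped, atol=1e-10)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(10)
        values = rng.standard_normal((8, 30))
        m = matrix_from(values)
        eig = module_eigengene(m, m.gene_ids)
        Z = (values - values.mean(1, keepdims=True)) / values.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        assert np.sum((Z @ eig) ** 2) == pytest.approx(evals[-1], rel=1e-10)
        np.testing.assert_allclose(np.abs(eig), np.abs(evecs[:, -1]), atol=1e-8)

    def test_too_few_members_rejected(self):
        m = matrix_from(np.random.default_rng(0).standard_normal((3, 5)))
        with pytest.raises(ValueError):
            module_eigengene(m, m.gene_ids[:1])


class TestModuleTrait:
    def test_perfect_association_minimizes_p(self):
        eig = np.linspace(-1, 1, 20)
        trait = (eig > 0).astype(float)
        r = module_trait_correlation(eig, trait, n_tests=4)
        assert r.computable and r.r > 0.8
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 4))
        assert r.p_raw < 1e-4

    def test_independent_trait_keeps_small_correlation(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            eig = rng.standard_normal(1000)
            trait = (rng.random(1000) < 0.5).astype(float)
            r = module_trait_correlation(eig, trait, 1)
            hits += abs(r.r) < 0.1
        assert hits >= 57  # >= 95%

    def test_unknowns_excluded_and_flagged_when_too_few(self):
        eig = np.arange(6.0)
        trait = np.array([1.0, np.nan, np.nan, np.nan, np.nan, 0.0])
        r = module_trait_correlation(eig, trait, 1)
        assert not r.computable and r.n == 2


class TestGeneScores:
    def _study(self):
        rng = np.random.default_rng(12)
        values = rng.standard_normal((3, 12))
        m = matrix_from(values)
        pheno = PhenotypeTable(
            sample_ids=m.sample_ids,
            status=np.ones(12, dtype=int),
            grade=np.array([0, 1] * 6, dtype=float),
            type=np.full(12, np.nan),
            stage=np.full(12, np.nan),
        )
        return m, pheno

    def test_scaled_connectivity_within_module(self):
        m, pheno = self._study()
        adj = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.1], [0.9, 0.1, 1.0]])
        network = net.CoexpressionNetwork(m.gene_ids, adj, np.eye(3), soft_power=1)
        part = net.ModulePartition(m.gene_ids, ["M1"] * 3, np.array([]), 0.95, 1)
        scores = gene_network_scores(m, network, part, pheno)
        ks = {s.gene: s.K for s in scores}
        assert ks["g0"] == pytest.approx(1.0)
        assert ks["g1"] == pytest.approx(1.0 / 1.8)
        assert ks["g2"] == pytest.approx(1.0 / 1.8)

    def test_gene_equal_to_trait_vector_has_unit_significance(self):
        m, pheno = self._study()
        values = m.values.copy()
        values[0] = pheno.grade
        m2 = matrix_from(values)
        network = net.CoexpressionNetwork(m2.gene_ids, np.eye(3), np.eye(3), 1)
        part = net.ModulePartition(m2.gene_ids, ["M1"] * 3, np.array([]), 0.95, 1)
        scores = gene_network_scores(m2, network, part, pheno)
        assert scores[0].GS["grade"] == pytest.approx(1.0)

    def test_exactly_one_gene_per_module_attains_unit_k(self):
        m, _, _ = generate_synthetic_study(small_study(seed=30))
        pheno = PhenotypeTable(
            sample_ids=m.sample_ids,
            status=np.ones(m.n_samples, dtype=int),
            grade=np.array([0.0, 1.0] * (m.n_samples // 2)),
            type=np.full(m.n_samples, np.nan),
            stage=np.full(m.n_samples, np.nan),
        )
        res = CoexpressionAnalysis(m, pheno, beta=4, min_size=20).fit()
        for module in res.partition.modules:
            ks = [s.K for s in res.gene_scores if s.module == module]
            assert sum(k == 1.0 for k in ks) == 1


def test_planted_hubs_have_higher_scaled_connectivity_than_members():
    wins = 0
    n_rep = 25
    for seed in range(n_rep):
        cfg = small_study(seed=seed, loading_in_module=0.6, loading_hub=0.9)
        m, pheno, truth = generate_synthetic_study(cfg)
        res = CoexpressionAnalysis(m, pheno, beta=4, min_size=20).fit()
        hubs = set(truth.hubs_for_module(0)) | set(truth.hubs_for_module(1))
        k_hub = [s.K for s in res.gene_scores if s.gene in hubs and s.module != "unassigned"]
        k_member = [
            s.K for s in res.gene_scores
            if s.gene not in hubs and s.module != "unassigned" and not s.gene.startswith("BG")
        ]
        wins += np.mean(k_hub) > np.mean(k_member)
    assert wins >= int(0.95 * n_rep)
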