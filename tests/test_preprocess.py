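"""Merging, standardization, differential expression, network-gene choice."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cohub.datatypes import ExpressionMatrix
from cohub.preprocess import (
    bh_fdr,
    intersect_by_gene_id,
    merge_platforms,
    select_network_genes,
    standardize_within_platform,
    t_test_de,
)
from cohub.simulate import generate_synthetic_study

from conftest import small_study


def make_matrix(gene_ids, values, platform="P1", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        platform=[platform] * values.shape[1],
        values=values,
    )


class TestIntersect:
    def test_common_genes_in_sorted_order(self):
        a = make_matrix(["A", "B", "C"], np.arange(6).reshape(3, 2))
        b = make_matrix(["D", "C", "B"], np.arange(6).reshape(3, 2), platform="P2")
        ra, rb = intersect_by_gene_id([a, b])
        assert ra.gene_ids == rb.gene_ids == ["B", "C"]
        np.testing.assert_array_equal(ra.values, [[2, 3], [4, 5]])
        np.testing.assert_array_equal(rb.values, [[4, 5], [2, 3]])

    def test_single_matrix_row_sorted(self):
        a = make_matrix(["B", "A"], [[1, 2], [3, 4]])
        (r,) = intersect_by_gene_id([a])
        assert r.gene_ids == ["A", "B"]

    def test_disjoint_gene_sets_rejected(self):
        a = make_matrix(["A"], [[1, 2]])
        b = make_matrix(["B"], [[1, 2]])
        with pytest.raises(ValueError, match="empty"):
            intersect_by_gene_id([a, b])


class TestStandardize:
    def test_arithmetic_sequence_z_scores(self):
        m = standardize_within_platform(make_matrix(["g"], [[1, 2, 3]]))
        np.testing.assert_allclose(m.values[0], [-1.224744871, 0.0, 1.224744871])

    def test_constant_row_maps_to_zero(self):
        m = standardize_within_platform(make_matrix(["g"], [[5, 5, 5]]))
        np.testing.assert_array_equal(m.values[0], [0, 0, 0])

    def test_affine_platform_distortion_removed_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, 6))
        distorted = base * 3.7 - 2.2
        m1 = standardize_within_platform(make_matrix(list("abcd"), base))
        m2 = standardize_within_platform(make_matrix(list("abcd"), distorted))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    def test_single_sample_platform_rejected(self):
        with pytest.raises(ValueError, match="single sample"):
            standardize_within_platform(make_matrix(["g"], [[1.0]]))


class TestMerge:
    def test_column_concatenation(self):
        a = make_matrix(["x", "y", "z"], np.ones((3, 2)), platform="P1", sample_prefix="a")
        b = make_matrix(["x", "y", "z"], np.zeros((3, 2)), platform="P2", sample_prefix="b")
        m = merge_platforms([a, b])
        assert m.values.shape == (3, 4)
        assert m.platform == ["P1", "P1", "P2", "P2"]

    def test_sample_collision_prefixed_by_platform(self):
        a = make_matrix(["x"], [[1, 2]], platform="P1")
        b = make_matrix(["x"], [[3, 4]], platform="P2")
        m = merge_platforms([a, b])
        assert m.sample_ids == ["P1:s0", "P1:s1", "P2:s0", "P2:s1"]

    def test_single_platform_unchanged(self):
        a = make_matrix(["x", "y"], [[1, 2], [3, 4]])
        m = merge_platforms([a])
        assert m.sample_ids == a.sample_ids
        np.testing.assert_array_equal(m.values, a.values)

    def test_mismatched_gene_order_rejected(self):
        a = make_matrix(["x", "y"], np.ones((2, 2)))
        b = make_matrix(["y", "x"], np.ones((2, 2)), platform="P2")
        with pytest.raises(ValueError, match="gene order"):
            merge_platforms([a, b])


def welch_oracle(case, control):
    """Textbook Welch t with Welch-Satterthwaite degrees of freedom."""
    n1, n2 = len(case), len(control)
    v1, v2 = np.var(case, ddof=1), np.var(control, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(case) - np.mean(control)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestTTest:
    def test_matches_hand_welch_computation(self):
        case = [1.2, 1.9, 1.4]
        control = [0.1, 0.4, 0.2]
        m = make_matrix(["g"], [control + case])
        status = np.array([0, 0, 0, 1, 1, 1])
        (r,) = t_test_de(m, status)
        t_exp, p_exp = welch_oracle(case, control)
        assert r.t_statistic == pytest.approx(t_exp, rel=1e-12)
        assert r.p_value == pytest.approx(p_exp, rel=1e-12)
        assert r.log_fold_change == pytest.approx(np.mean(case) - np.mean(control))

    def test_identical_groups_give_t0_p1(self):
        m = make_matrix(["g"], [[2, 2, 2, 2]])
        (r,) = t_test_de(m, np.array([1, 1, 0, 0]))
        assert r.t_statistic == 0.0 and r.p_value == 1.0

    def test_zero_variance_separation_gives_p0_sentinel(self):
        m = make_matrix(["g"], [[2, 2, 0, 0]])
        (r,) = t_test_de(m, np.array([1, 1, 0, 0]))
        assert r.p_value == 0.0 and np.isinf(r.t_statistic)

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        m = make_matrix([f"g{i}" for i in range(20)], rng.standard_normal((20, 12)))
        status = np.array([1] * 5 + [0] * 7)
        fwd = t_test_de(m, status)
        rev = t_test_de(m, 1 - status)
        for a, b in zip(fwd, rev):
            assert a.t_statistic == pytest.approx(-b.t_statistic, rel=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_single_sample_group_rejected(self):
        m = make_matrix(["g"], [[1, 2, 3]])
        with pytest.raises(ValueError):
            t_test_de(m, np.array([1, 0, 0]))


def bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_(j) >= p_i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(1.0, running)
    return q


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_zero_and_singleton(self):
        assert bh_fdr([0.0, 0.0]) == [0.0, 0.0]
        assert bh_fdr([0.37]) == [0.37]

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(1, 101))
            p = rng.random(n)
            np.testing.assert_allclose(bh_fdr(list(p)), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSelectNetworkGenes:
    def _de_and_matrix(self, qs, lfcs, variances):
        n = len(qs)
        # rows with exactly the requested variances (alternating-sign pattern)
        pattern = np.tile([-1.0, 1.0], 15)
        values = np.sqrt(np.asarray(variances))[:, None] * pattern[None, :]
        values += 0.001 * np.arange(30)[None, :]  # break exact group symmetry
        m = make_matrix([f"g{i}" for i in range(n)], values)
        de = t_test_de(m, np.array([1] * 15 + [0] * 15))
        de = [dataclasses.replace(r, q_value=q, log_fold_change=l)
              for r, q, l in zip(de, qs, lfcs)]
        return de, m

    def test_de_genes_plus_variance_fill(self):
        qs = [0.001] * 3 + [0.9] * 7
        lfcs = [2.0] * 3 + [0.0] * 7
        variances = [1.0] * 3 + list(range(10, 3, -1))
        de, m = self._de_and_matrix(qs, lfcs, variances)
        chosen = select_network_genes(de, m, fdr_cut=0.05, fc_cut=1.5, target_n=5)
        assert set(chosen[:3]) == {"g0", "g1", "g2"}
        assert len(chosen) == 5
        # the two fill slots go to the highest-variance non-DE genes
        assert set(chosen[3:]) == {"g3", "g4"}

    def test_no_de_genes_pure_variance_ranking(self):
        qs = [0.9] * 10
        lfcs = [0.0] * 10
        variances = list(range(1, 11))
        de, m = self._de_and_matrix(qs, lfcs, variances)
        chosen = select_network_genes(de, m, fdr_cut=0.05, fc_cut=1.5, target_n=5)
        assert set(chosen) == {"g5", "g6", "g7", "g8", "g9"}

    def test_de_overflow_keeps_all_de_genes(self):
        qs = [0.001] * 8 + [0.9] * 2
        lfcs = [2.0] * 8 + [0.0] * 2
        de, m = self._de_and_matrix(qs, lfcs, [1.0] * 10)
        chosen = select_network_genes(de, m, fdr_cut=0.05, fc_cut=1.5, target_n=5)
        assert len(chosen) == 8


def test_standardize_merge_removes_planted_platform_effects():
    clean_cfg = small_study(seed=13, platform_shift_sd=0.0, platform_scale_sd=0.0)
    dirty_cfg = dataclasses.replace(clean_cfg, platform_shift_sd=0.8, platform_scale_sd=0.3)

    def merged(cfg):
        m, _, _ = generate_synthetic_study(cfg)
        platform = np.asarray(m.platform)
        parts = [m.subset_samples(platform == p) for p in m.platforms]
        return merge_platforms(
            [standardize_within_platform(x) for x in intersect_by_gene_id(parts)]
        )

    np.testing.assert_allclose(merged(clean_cfg).values, merged(dirty_cfg).values, atol=1e-10)
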