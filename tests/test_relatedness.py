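"""Kinship, PCA, LD pruning and subpopulation clustering."""

import numpy as np
import pytest

from soygs import io, relatedness, simulate
from soygs.errors import DataError

from .conftest import toy_genotypes


class TestKinship:
    def test_formula_oracle(self):
        D = np.array(
            [[0, 1, 2], [2, 1, 0], [1, 2, 1], [0, 0, 2]], dtype=float
        )
        K = relatedness.vanraden_kinship(toy_genotypes(D)).values
        # explicit VanRaden method-1 evaluation, term by term
        p = D.mean(axis=0) / 2.0
        W = D - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expected[i, j] = np.sum(W[i] * W[j]) / denom
        assert np.allclose(K, expected, atol=1e-12)

    def test_duplicated_samples_share_entries(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 3, size=(5, 40)).astype(float)
        D[3] = D[0]
        K = relatedness.vanraden_kinship(toy_genotypes(D)).values
        assert abs(K[0, 0] - K[0, 3]) < 1e-10
        assert abs(K[0, 0] - K[3, 3]) < 1e-10

    def test_unrelated_samples_have_zero_mean_offdiagonal(self):
        cfg = simulate.SimulationConfig(n_samples=200, n_markers=5000,
                                        n_subpops=1, fst=0.0, ld_rho=0.0, seed=6)
        G = simulate.simulate_structured_genotypes(cfg)
        K = relatedness.vanraden_kinship(G).values
        off = K[~np.eye(len(K), dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_marker_order_invariance_and_psd(self, small_panel):
        G = small_panel[0]
        K1 = relatedness.vanraden_kinship(G).values
        rng = np.random.default_rng(0)
        perm = rng.permutation(G.n_markers)
        shuffled = toy_genotypes(G.dosages[:, perm])
        K2 = relatedness.vanraden_kinship(shuffled).values
        assert np.allclose(K1, K2, atol=1e-10)
        ev = np.linalg.eigvalsh(K1)
        assert ev.min() > -1e-8 * ev.max()

    def test_all_monomorphic_is_error(self):
        with pytest.raises(DataError):
            relatedness.vanraden_kinship(toy_genotypes(np.ones((4, 3))))


class TestPCA:
    def test_rank_one_matrix(self):
        v = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        D = np.column_stack([v, v, v, 2 - v])
        res = relatedness.genotype_pca(toy_genotypes(D), 2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_scores_orthogonal_and_sign_deterministic(self, small_panel):
        G = small_panel[0]
        r1 = relatedness.genotype_pca(G, 5)
        r2 = relatedness.genotype_pca(G, 5)
        assert np.array_equal(r1.scores, r2.scores)
        gram = r1.scores.T @ r1.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_pc1_separates_diverged_subpopulations(self):
        cfg = simulate.SimulationConfig(n_samples=400, n_markers=2000,
                                        n_subpops=2, fst=0.3, ld_rho=0.0, seed=3)
        G = io.impute_missing_mean(
            io.maf_filter(simulate.simulate_structured_genotypes(cfg))
        )
        part = simulate.subpopulation_assignment(cfg)
        res = relatedness.genotype_pca(G, 2)
        side = res.scores[:, 0] > 0
        truth = part.labels == "pop2"
        agreement = max(np.mean(side == truth), np.mean(side != truth))
        assert agreement > 0.99

    def test_no_structure_gives_no_dominant_axis(self):
        cfg = simulate.SimulationConfig(n_samples=400, n_markers=2000,
                                        n_subpops=2, fst=0.0, ld_rho=0.0, seed=9)
        G = io.impute_missing_mean(
            io.maf_filter(simulate.simulate_structured_genotypes(cfg))
        )
        res = relatedness.genotype_pca(G, 3)
        evr = res.explained_variance_ratio
        assert evr[0] < 2 * evr[1]


class TestLDPrune:
    def test_perfect_ld_keeps_only_first(self):
        v = np.array([0.0, 1, 2, 1, 0, 2])
        D = np.column_stack([v] * 4)
        kept = relatedness.ld_prune_adjacent(toy_genotypes(D), 0.5)
        assert list(kept) == ["m0"]

    def test_duplicate_then_independent(self):
        rng = np.random.default_rng(2)
        m1 = rng.integers(0, 3, 100).astype(float)
        m3 = rng.integers(0, 3, 100).astype(float)
        D = np.column_stack([m1, m1, m3])
        kept = relatedness.ld_prune_adjacent(toy_genotypes(D), 0.5)
        assert list(kept) == ["m0", "m2"]

    def test_independent_markers_mostly_retained(self):
        cfg = simulate.SimulationConfig(n_samples=500, n_markers=1000,
                                        n_subpops=1, fst=0.0, ld_rho=0.0, seed=8)
        G = simulate.simulate_structured_genotypes(cfg)
        kept = relatedness.ld_prune_adjacent(G, 0.5)
        assert len(kept) / G.n_markers >= 0.99

    def test_output_is_ordered_subset(self, small_panel):
        G = small_panel[0]
        kept = relatedness.ld_prune_adjacent(G, 0.5)
        pos_in_map = [list(G.marker_ids).index(k) for k in kept]
        assert pos_in_map == sorted(pos_in_map)

    def test_zero_variance_marker_kept(self):
        rng = np.random.default_rng(3)
        D = np.column_stack(
            [rng.integers(0, 3, 50), np.ones(50), rng.integers(0, 3, 50)]
        ).astype(float)
        kept = relatedness.ld_prune_adjacent(toy_genotypes(D), 0.5)
        assert "m1" in list(kept)


class TestClustering:
    def test_recovers_two_diverged_groups(self):
        cfg = simulate.SimulationConfig(n_samples=300, n_markers=1500,
                                        n_subpops=2, fst=0.3, ld_rho=0.0, seed=14)
        G = io.impute_missing_mean(
            io.maf_filter(simulate.simulate_structured_genotypes(cfg))
        )
        part = simulate.subpopulation_assignment(cfg)
        pcs = relatedness.genotype_pca(G, 10)
        clus = relatedness.cluster_subpopulations(pcs, (2, 4), seed=14)
        assert clus.selected_k == 2
        a = clus.partition.labels == "Gpop1"
        b = part.labels == "pop1"
        assert max(np.mean(a == b), np.mean(a != b)) > 0.99

    def test_weak_structure_flagged_at_zero_divergence(self):
        cfg = simulate.SimulationConfig(n_samples=300, n_markers=1000,
                                        n_subpops=2, fst=0.0, ld_rho=0.0, seed=4)
        G = io.impute_missing_mean(
            io.maf_filter(simulate.simulate_structured_genotypes(cfg))
        )
        pcs = relatedness.genotype_pca(G, 10)
        clus = relatedness.cluster_subpopulations(pcs, (2, 2), seed=4)
        assert clus.silhouette_by_k[2] < 0.2
        assert clus.weak_structure

    def test_group_sizes_sorted_descending(self):
        cfg = simulate.benchmark_config(n_samples=500, n_markers=1500, fst=0.35,
                                        ld_rho=0.0, seed=21)
        G = io.impute_missing_mean(
            io.maf_filter(simulate.simulate_structured_genotypes(cfg))
        )
        pcs = relatedness.genotype_pca(G, 10)
        clus = relatedness.cluster_subpopulations(pcs, (5, 5), seed=21)
        sizes = [clus.partition.group_sizes()[g]
                 for g in sorted(clus.partition.group_sizes())]
        assert sizes == sorted(sizes, reverse=True)
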