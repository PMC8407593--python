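"""Trait simulator: variance budget, determinism, causal selection."""

import numpy as np
import pytest

from bann.annotation import build_annotation_mask
from bann.simulate import (
    PopulationStructure,
    SimulationConfig,
    select_causal,
    simulate_covariate_structure,
    simulate_dataset,
    simulate_genotypes,
    simulate_trait,
    tiling_gene_intervals,
)


class TestGenotypes:
    def test_dosages_and_expected_mean_at_half_maf(self):
        cfg = SimulationConfig(n_individuals=3000, n_snps=50, maf_range=(0.5, 0.5), seed=0)
        X, snp_map = simulate_genotypes(cfg)
        assert set(np.unique(X)) <= {0.0, 1.0, 2.0}
        assert np.allclose(X.mean(axis=0), 1.0, atol=0.1)
        assert len(snp_map) == 50 and snp_map["position"].is_monotonic_increasing

    def test_same_seed_is_bitwise_reproducible(self):
        cfg = SimulationConfig(n_individuals=100, n_snps=40, seed=11)
        X1, _ = simulate_genotypes(cfg)
        X2, _ = simulate_genotypes(cfg)
        assert np.array_equal(X1, X2)

    def test_zero_divergence_structure_matches_group_frequencies(self):
        cfg = SimulationConfig(
            n_individuals=2000, n_snps=1000, seed=3,
            structure=PopulationStructure(n_subpopulations=2, fst=0.0),
        )
        X, snp_map = simulate_genotypes(cfg)
        groups = snp_map.attrs["groups"]
        f0 = X[groups == 0].mean(axis=0) / 2
        f1 = X[groups == 1].mean(axis=0) / 2
        # binomial sampling bound: sd of the difference is sqrt(p(1-p)/2n0+...)
        n0, n1 = (groups == 0).sum(), (groups == 1).sum()
        p = X.mean(axis=0) / 2
        sd = np.sqrt(p * (1 - p) / 2 * (1 / n0 + 1 / n1))
        assert np.mean(np.abs(f0 - f1) < 4 * sd) > 0.99

    def test_nonzero_divergence_separates_groups(self):
        cfg = SimulationConfig(
            n_individuals=2000, n_snps=500, seed=3,
            structure=PopulationStructure(n_subpopulations=2, fst=0.2),
        )
        X, snp_map = simulate_genotypes(cfg)
        groups = snp_map.attrs["groups"]
        gap = np.abs(X[groups == 0].mean(axis=0) - X[groups == 1].mean(axis=0))
        assert gap.mean() > 0.1

    def test_ld_weight_induces_adjacent_correlation(self):
        cfg = SimulationConfig(n_individuals=3000, n_snps=100, seed=5, ld_weight=0.6)
        X, _ = simulate_genotypes(cfg)
        adj = np.array([np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(99)])
        assert adj.mean() > 0.4

    def test_tiny_dimensions_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(SimulationConfig(n_individuals=1, n_snps=10))


class TestSelectCausal:
    @pytest.fixture(scope="class")
    def mask(self):
        cfg = SimulationConfig(n_individuals=200, n_snps=1400, seed=2)
        _, snp_map = simulate_genotypes(cfg)
        genes = tiling_gene_intervals(snp_map, snps_per_gene=10, gap_snps=4)
        return build_annotation_mask(snp_map, genes)

    def test_one_percent_of_100_sets_is_one_set(self, mask):
        assert mask.n_sets >= 100
        cfg = SimulationConfig(n_snps=1400, pct_enriched_sets=1.0 / mask.n_sets, seed=4)
        enriched, causal = select_causal(mask, cfg)
        assert len(enriched) == 1
        assert set(causal) <= set(mask.members(enriched[0]))

    def test_every_enriched_set_contains_a_causal_snp(self, mask):
        cfg = SimulationConfig(
            n_snps=1400, pct_enriched_sets=0.1, pct_causal_in_set=0.05, seed=4
        )
        enriched, causal = select_causal(mask, cfg)
        cset = set(causal.tolist())
        for g in enriched:
            assert cset & set(mask.members(g))

    def test_full_fractions_select_every_snp(self, mask):
        cfg = SimulationConfig(
            n_snps=1400, pct_enriched_sets=1.0, pct_causal_in_set=1.0, seed=4
        )
        _, causal = select_causal(mask, cfg)
        assert len(causal) == mask.n_snps

    def test_fixed_seed_reproducible(self, mask):
        cfg = SimulationConfig(n_snps=1400, pct_enriched_sets=0.05, seed=9)
        a = select_causal(mask, cfg)
        b = select_causal(mask, cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestTrait:
    def test_pure_additive_has_zero_interaction_component(self):
        X, _, mask, trait = simulate_dataset(SimulationConfig(300, 400, rho=1.0, seed=6))
        assert np.all(trait.interaction_component == 0)

    def test_components_sum_to_phenotype_exactly(self):
        _, _, _, trait = simulate_dataset(
            SimulationConfig(300, 400, rho=0.5, pct_causal_in_set=0.2, seed=6)
        )
        recon = (
            trait.additive_component
            + trait.interaction_component
            + trait.noise_component
        )
        np.testing.assert_allclose(trait.y, recon, rtol=0, atol=0)

    def test_equal_contribution_split_h2_06_rho_05(self):
        _, _, _, trait = simulate_dataset(
            SimulationConfig(500, 400, h2=0.6, rho=0.5, pct_causal_in_set=0.2, seed=8)
        )
        assert np.var(trait.additive_component) == pytest.approx(0.3, abs=1e-10)
        assert np.var(trait.interaction_component) == pytest.approx(0.3, abs=1e-10)
        assert np.var(trait.noise_component) == pytest.approx(0.4, abs=1e-10)

    def test_zero_heritability_gives_pure_unit_noise(self):
        _, _, _, trait = simulate_dataset(SimulationConfig(300, 400, h2=0.0, seed=6))
        assert np.all(trait.additive_component == 0)
        assert np.var(trait.y) == pytest.approx(1.0, abs=1e-10)

    def test_rho_below_one_requires_two_causal_snps(self):
        cfg = SimulationConfig(300, 400, rho=0.5, seed=6)
        X, _ = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="rho < 1"):
            simulate_trait(X, (np.array([0]), np.array([3])), cfg)

    def test_variance_budget_over_replicates(self):
        """Mean realized shares converge to rho*H2 / H2 / 1 across replicates."""
        shares = []
        for s in range(25):
            _, _, _, trait = simulate_dataset(
                SimulationConfig(400, 600, h2=0.6, rho=0.5, pct_enriched_sets=0.05,
                                 pct_causal_in_set=0.2, seed=s)
            )
            shares.append(
                [
                    np.var(trait.y),
                    np.var(trait.additive_component + trait.interaction_component),
                    np.var(trait.additive_component),
                ]
            )
        total, genetic, additive = np.mean(shares, axis=0)
        assert total == pytest.approx(1.0, abs=0.03)
        assert genetic == pytest.approx(0.6, abs=0.03)
        assert additive / genetic == pytest.approx(0.5, abs=0.02)


class TestCovariateStructure:
    def test_zero_pcs_is_identity_up_to_restandardization(self, rng):
        y = rng.standard_normal(200) * 3 + 1
        X = rng.standard_normal((200, 50))
        out, scores, w = simulate_covariate_structure(y, X, 0)
        expect = (y - y.mean()) / y.std()
        np.testing.assert_allclose(out, expect, atol=1e-12)
        assert scores.shape == (200, 0)

    def test_output_unit_variance_and_orthogonal_scores(self, rng):
        y = rng.standard_normal(300)
        X = rng.binomial(2, 0.3, size=(300, 80)).astype(float)
        out, scores, w = simulate_covariate_structure(y, X, 5, seed=1)
        assert np.var(out) == pytest.approx(1.0, abs=1e-10)
        cc = np.corrcoef(scores, rowvar=False)
        off = cc[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_negative_pcs_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_covariate_structure(rng.standard_normal(50), rng.standard_normal((50, 10)), -1)
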