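"""Generator behavior: Balding-Nichols structure, genotype sampling and the
additive phenotype model."""

import numpy as np
import pytest
from scipy import stats

from fedgen.datatypes import MISSING
from fedgen.synthetic import (
    NodeSpec,
    PopulationModel,
    TraitModel,
    draw_causal_effects,
    draw_population_frequencies,
    simulate_genotypes,
    simulate_phenotype,
    simulate_phenotypes,
    thousand_genomes_like_regime,
    ukb_like_regime,
)


def flat_model(n_pops, fst, n_variants=1000):
    return PopulationModel(
        n_populations=n_pops,
        fst=fst,
        ancestral_freq_range=(0.1, 0.9),
        n_variants=n_variants,
        superpop_assignment={k: "ANY" for k in range(n_pops)},
    )


def hudson_fst(p1, p2):
    """Independent ratio-of-averages Hudson estimator on true population
    frequencies (no sampling correction needed)."""
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return num / den


class TestPopulationFrequencies:
    def test_zero_fst_returns_ancestral_exactly(self):
        freqs = draw_population_frequencies(flat_model(3, [0.0, 0.0, 0.0]), seed=1)
        assert np.array_equal(freqs[0], freqs[1])
        assert np.array_equal(freqs[1], freqs[2])

    def test_divergence_matches_hudson_fst(self):
        # two populations at F = 0.1: the Hudson estimator over many
        # variants recovers the divergence dial
        freqs = draw_population_frequencies(flat_model(2, [0.1, 0.1], 5000), seed=2)
        assert hudson_fst(freqs[0], freqs[1]) == pytest.approx(0.1, abs=0.02)

    def test_deterministic_given_seed(self):
        model = flat_model(4, [0.05] * 4)
        a = draw_population_frequencies(model, seed=7)
        b = draw_population_frequencies(model, seed=7)
        assert np.array_equal(a, b)

    def test_rejects_fst_outside_range(self):
        with pytest.raises(ValueError):
            flat_model(2, [0.5, 1.0])
        with pytest.raises(ValueError):
            flat_model(2, [-0.1, 0.2])

    def test_hierarchical_nesting_orders_divergence(self):
        # subpopulations within a superpopulation are closer to each other
        # than populations of different superpopulations
        model, _ = thousand_genomes_like_regime(n_variants=3000)
        freqs = draw_population_frequencies(model, seed=3)
        same, diff = [], []
        labels = [model.superpop_assignment[k] for k in range(model.n_populations)]
        for i in range(model.n_populations):
            for j in range(i + 1, model.n_populations):
                (same if labels[i] == labels[j] else diff).append(
                    hudson_fst(freqs[i], freqs[j])
                )
        assert np.mean(same) < np.mean(diff)


class TestSimulateGenotypes:
    def test_no_missing_when_rate_zero(self):
        model = flat_model(1, [0.0], 50)
        freqs = draw_population_frequencies(model, 1)
        nodes = simulate_genotypes(freqs, [NodeSpec("a", 30, [1.0])], 0.0, 5)
        assert not (nodes[0].block.dosages == MISSING).any()

    def test_fixed_frequency_forces_dosage(self):
        freqs = np.array([[1.0, 0.0, 0.5]])
        nodes = simulate_genotypes(freqs, [NodeSpec("a", 20, [1.0])], 0.0, 5)
        assert (nodes[0].block.dosages[:, 0] == 2).all()
        assert (nodes[0].block.dosages[:, 1] == 0).all()

    def test_disjoint_mixtures_give_disjoint_labels(self):
        model = flat_model(2, [0.1, 0.1], 20)
        freqs = draw_population_frequencies(model, 1)
        nodes = simulate_genotypes(
            freqs,
            [NodeSpec("A", 25, [1.0, 0.0]), NodeSpec("B", 25, [0.0, 1.0])],
            0.0,
            6,
        )
        assert set(nodes[0].phenotypes["population"]) == {"POP00"}
        assert set(nodes[1].phenotypes["population"]) == {"POP01"}

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(np.array([[0.5]]), [], 0.0, 1)

    def test_determinism_bit_identical(self):
        model = flat_model(2, [0.05, 0.1], 100)
        freqs = draw_population_frequencies(model, 4)
        specs = [NodeSpec("a", 40, [0.5, 0.5])]
        n1 = simulate_genotypes(freqs, specs, 0.05, 9)
        n2 = simulate_genotypes(freqs, specs, 0.05, 9)
        assert np.array_equal(n1[0].block.dosages, n2[0].block.dosages)

    def test_allele_frequency_conservation(self):
        # empirical node frequency converges to the mixture-weighted
        # population frequency (within 3 standard errors at n = 5000)
        model = flat_model(2, [0.1, 0.1], 200)
        freqs = draw_population_frequencies(model, 11)
        mix = np.array([0.3, 0.7])
        nodes = simulate_genotypes(freqs, [NodeSpec("a", 5000, mix)], 0.0, 12)
        expected = mix @ freqs
        observed = nodes[0].block.allele_frequency()
        se = np.sqrt(expected * (1 - expected) / (2 * 5000))
        assert (np.abs(observed - expected) < 3 * se).mean() > 0.95


class TestPhenotype:
    def _nodes(self, n=2000, m=300, seed=0):
        model = flat_model(1, [0.0], m)
        freqs = draw_population_frequencies(model, seed)
        return simulate_genotypes(freqs, [NodeSpec("a", n, [1.0])], 0.0, seed + 1)

    def test_zero_noise_zero_covariates_equals_genetic_score(self):
        nodes = self._nodes(n=50)
        effects = draw_causal_effects(300, 10, 3)
        trait = TraitModel(10, 1.0, covariate_effects=(0.0, 0.0))
        node = simulate_phenotype(nodes[0], trait, effects, 4)
        g = node.block.dosages_float("mean") @ effects
        np.testing.assert_allclose(node.phenotypes["phenotype"], g, atol=1e-12)

    def test_heritability_calibration(self):
        # variance explained by the true genetic score near the target
        nodes = self._nodes(n=20000)
        effects = draw_causal_effects(300, 100, 5)
        nodes = simulate_phenotypes(nodes, TraitModel(100, 0.5), effects, 6)
        g = nodes[0].block.dosages_float("mean") @ effects
        y = nodes[0].phenotypes["phenotype"].to_numpy()
        ratio = np.var(g) / np.var(y)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_zero_heritability_null_gwas(self):
        # phenotype independent of genotype: association p-values uniform
        from fedgen.assoc import gwas_node

        nodes = self._nodes(n=500, m=400, seed=7)
        effects = draw_causal_effects(400, 50, 8)
        nodes = simulate_phenotypes(nodes, TraitModel(50, 0.0), effects, 9)
        stats_df = gwas_node(nodes[0], n_pcs=0)
        ks = stats.kstest(stats_df["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_heritability_one_with_zero_effects_rejected(self):
        nodes = self._nodes(n=50)
        effects = np.zeros(300)
        with pytest.raises(ValueError):
            simulate_phenotypes(nodes, TraitModel(0, 0.5), effects, 1)

    def test_heterogeneity_dial_separates_superpopulations(self):
        # leading PCs cluster disjoint single-population nodes at F = 0.1
        from sklearn.metrics import silhouette_score

        from fedgen.fedpca import centralized_pca, project

        model = PopulationModel(
            n_populations=5,
            fst=[0.1] * 5,
            ancestral_freq_range=(0.1, 0.9),
            n_variants=500,
            superpop_assignment={k: f"SP{k}" for k in range(5)},
        )
        freqs = draw_population_frequencies(model, 13)
        specs = [
            NodeSpec(f"n{k}", 500, np.eye(5)[k]) for k in range(5)
        ]
        nodes = simulate_genotypes(freqs, specs, 0.0, 14, model)
        blocks = [n.block for n in nodes]
        pca = centralized_pca(blocks, n_pcs=2)
        scores = np.vstack([project(pca, b) for b in blocks])
        labels = np.concatenate(
            [n.phenotypes["superpopulation"].to_numpy() for n in nodes]
        )
        assert silhouette_score(scores, labels) > 0.5


def test_ukb_like_regime_shape():
    model, specs = ukb_like_regime(n_nodes=19, samples_per_node=100, n_variants=50)
    assert len(specs) == 19
    assert all(s.population_mixture.sum() == 1.0 for s in specs)
    assert len(set(model.superpop_assignment.values())) == 1


def test_thousand_genomes_like_regime_structure():
    model, specs = thousand_genomes_like_regime(n_variants=10)
    assert model.n_populations == 26
    assert len(specs) == 5
    assert sorted(set(model.superpop_assignment.values())) == [
        "AFR", "AMR", "EAS", "EUR", "SAS",
    ]
    # each node draws only from its own superpopulation
    for spec in specs:
        pops = np.flatnonzero(spec.population_mixture)
        assert {model.superpop_assignment[int(k)] for k in pops} == {spec.node_id}
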