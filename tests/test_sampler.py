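"""Gibbs sampler: full conditionals, bookkeeping, restrictions, prediction."""

import numpy as np
import pytest

from farmbayes import simdata
from farmbayes.genotypes import GenotypeMatrix
from farmbayes.sampler import (
    ChainConfig,
    ModelSpec,
    predict_gebv,
    run_chain,
    snp_component_posterior,
    summarize,
)


# ---------------------------------------------------------------------- #
class TestComponentPosterior:
    def test_prior_mass_concentrated_on_zero_component(self):
        p = snp_component_posterior(5.0, 100.0, 1.0, (0.0, 1e-4, 1e-3, 1e-2),
                                    (1.0, 0.0, 0.0, 0.0))
        np.testing.assert_allclose(p, [1.0, 0.0, 0.0, 0.0])

    def test_zero_signal_favors_small_variance_components(self):
        p = snp_component_posterior(0.0, 100.0, 1.0, (0.0, 1e-3, 1e-2, 1e-1),
                                    (0.25, 0.25, 0.25, 0.25))
        assert np.all(np.diff(p) < 0)  # monotone decreasing in variance
        assert p.sum() == pytest.approx(1.0)

    def test_equal_variance_components_symmetric(self):
        p = snp_component_posterior(3.0, 50.0, 1.0, (1e-3, 1e-3), (0.5, 0.5))
        assert p[0] == pytest.approx(p[1])

    def test_all_zero_prior_mass_rejected(self):
        with pytest.raises(ValueError):
            snp_component_posterior(1.0, 10.0, 1.0, (0.0, 1e-3), (0.0, 0.0))


# ---------------------------------------------------------------------- #
class TestModelSpecValidation:
    def test_bayesc_is_two_component_restriction(self):
        spec = ModelSpec(prior_kind="bayesc")
        assert spec.multipliers == (0.0, 1.0)
        with pytest.raises(ValueError):
            ModelSpec(prior_kind="bayesc", mixture_multipliers=(0.0, 1e-3, 1e-2))

    def test_rrblup_has_single_component(self):
        assert ModelSpec(prior_kind="rrblup").multipliers == (1.0,)
        with pytest.raises(ValueError):
            ModelSpec(prior_kind="rrblup", mixture_multipliers=(0.0, 1.0))

    def test_bayesr_needs_zero_first_component(self):
        with pytest.raises(ValueError):
            ModelSpec(prior_kind="bayesr", mixture_multipliers=(1e-4, 1e-3))

    def test_retention_formula(self):
        assert ChainConfig(25000, 5000, 5).n_retained == 4000
        assert ChainConfig(100, 40, 7).n_retained == 8


# ---------------------------------------------------------------------- #
class TestRunChain:
    def test_single_snp_matches_conjugate_posterior(self):
        # fixed variances, no farm, weights off: the SNP effect's posterior is
        # the closed-form normal with mean z'y / (z'z + s_e2/s_b2)
        rng = np.random.default_rng(12)
        dos = rng.binomial(2, 0.4, size=(50, 1)).astype(np.int8)
        dos[0, 0] = 0 if dos[0, 0] != 0 else 2  # ensure polymorphic
        G = GenotypeMatrix.from_dosages(dos)
        z = G.standardized(order="C")[:, 0]
        beta_true = 0.6
        y = beta_true * z + rng.standard_normal(50)
        s_b2, s_e2 = 0.5, 1.0
        spec = ModelSpec(prior_kind="rrblup", farm_effects=False,
                         fixed_variances={"sigma_g2": s_b2, "sigma_e2": s_e2})
        samples = run_chain(y, None, None, G, spec=spec,
                            config=ChainConfig(6000, 1000, 1, seed=13))
        post_mean = float(z @ y) / (float(z @ z) + s_e2 / s_b2)
        post_sd = np.sqrt(s_e2 / (float(z @ z) + s_e2 / s_b2))
        est = summarize(samples).snp_effect_mean[0]
        assert est == pytest.approx(post_mean, abs=3 * post_sd / np.sqrt(500))

    def test_null_phenotype_yields_near_zero_heritability(self):
        # n must comfortably exceed the weak-identification floor at which
        # the mixture prior alone props up a small apparent genetic variance
        rng = np.random.default_rng(14)
        G = simdata.simulate_genotypes(800, 500, seed=14)
        y = rng.standard_normal(800)
        samples = run_chain(y, None, None, G,
                            spec=ModelSpec(farm_effects=False),
                            config=ChainConfig(800, 300, 2, seed=14))
        assert summarize(samples).h2_mean < 0.1

    def test_unit_weights_equal_disabled_weights(self, small_dataset):
        G, d = small_dataset
        cfg = ChainConfig(200, 50, 2, seed=15)
        a = run_chain(d.y, None, d.farms.farm_of_animal, G,
                      weights=np.ones(G.n_animals), config=cfg)
        b = run_chain(d.y, None, d.farms.farm_of_animal, G,
                      weights=None, config=cfg)
        np.testing.assert_array_equal(a.sigma_e2, b.sigma_e2)
        np.testing.assert_array_equal(a.snp_effect_sum, b.snp_effect_sum)

    def test_incremental_residual_matches_recomputation(self, small_dataset):
        G, d = small_dataset
        samples = run_chain(d.y, None, d.farms.farm_of_animal, G,
                            weights=d.weights, config=ChainConfig(300, 100, 2, seed=16))
        st = samples.final_states[0]
        Z = G.standardized(order="C")
        recomputed = (d.y - st["X"] @ st["b"] - Z @ st["g"]
                      - st["f"][st["farm_index"]])
        scale = np.abs(d.y).max()
        assert np.abs(recomputed - st["e"]).max() / scale < 1e-8

    def test_deterministic_given_seed(self, small_dataset):
        G, d = small_dataset
        cfg = ChainConfig(150, 50, 2, seed=17)
        a = run_chain(d.y, None, d.farms.farm_of_animal, G, weights=d.weights, config=cfg)
        b = run_chain(d.y, None, d.farms.farm_of_animal, G, weights=d.weights, config=cfg)
        np.testing.assert_array_equal(a.h2, b.h2)

    def test_pi_draws_on_simplex_and_variances_positive(self, small_dataset):
        G, d = small_dataset
        samples = run_chain(d.y, None, d.farms.farm_of_animal, G,
                            weights=d.weights, config=ChainConfig(300, 100, 2, seed=18))
        np.testing.assert_allclose(samples.pi.sum(axis=2), 1.0, atol=1e-12)
        assert (samples.sigma_e2 > 0).all()
        assert (samples.sigma_f2 > 0).all()
        assert ((samples.h2 > 0) & (samples.h2 < 1)).all()

    def test_nonpositive_weights_rejected(self, small_dataset):
        G, d = small_dataset
        with pytest.raises(ValueError):
            run_chain(d.y, None, d.farms.farm_of_animal, G,
                      weights=np.zeros(G.n_animals), config=ChainConfig(50, 10, 1))


# ---------------------------------------------------------------------- #
class TestSummaries:
    def test_pip_bounds_and_zero_effect_markers(self, small_dataset):
        G, d = small_dataset
        samples = run_chain(d.y, None, d.farms.farm_of_animal, G,
                            weights=d.weights, config=ChainConfig(300, 100, 2, seed=19))
        s = summarize(samples)
        assert ((s.pip >= 0) & (s.pip <= 1)).all()
        never = s.pip == 0
        if never.any():
            assert np.all(s.snp_effect_mean[never] == 0)

    def test_empty_samples_rejected(self, small_dataset):
        G, d = small_dataset
        samples = run_chain(d.y, None, d.farms.farm_of_animal, G,
                            config=ChainConfig(60, 50, 20, seed=20))
        if samples.n_retained_total == 0:
            with pytest.raises(ValueError):
                summarize(samples)


# ---------------------------------------------------------------------- #
@pytest.fixture(scope="module")
def fitted(small_dataset):
    G, d = small_dataset
    samples = run_chain(d.y, None, d.farms.farm_of_animal, G,
                        weights=d.weights, config=ChainConfig(400, 100, 2, seed=21))
    return G, d, summarize(samples)


class TestPrediction:
    def test_training_genotypes_reproduce_fitted_values(self, fitted):
        G, d, summ = fitted
        gebv = predict_gebv(G, summ)
        Z = G.standardized(order="C")
        np.testing.assert_allclose(gebv, Z @ summ.snp_effect_mean, atol=1e-10)

    def test_zero_effects_give_zero_gebv(self, fitted):
        G, d, summ = fitted
        import copy

        s0 = copy.deepcopy(summ)
        s0.snp_effect_mean = np.zeros_like(s0.snp_effect_mean)
        np.testing.assert_array_equal(predict_gebv(G, s0), 0.0)

    def test_gebv_linear_in_single_marker_effect(self, fitted):
        G, d, summ = fitted
        import copy

        s2 = copy.deepcopy(summ)
        j = int(np.argmax(np.abs(summ.snp_effect_mean)))
        s2.snp_effect_mean = summ.snp_effect_mean.copy()
        s2.snp_effect_mean[j] *= 2.0
        zj = (G.dosages[:, j] - summ.center[j]) / summ.scale[j]
        delta = predict_gebv(G, s2) - predict_gebv(G, summ)
        np.testing.assert_allclose(delta, zj * summ.snp_effect_mean[j], atol=1e-10)

    def test_marker_mismatch_policy(self, fitted):
        G, d, summ = fitted
        sub = GenotypeMatrix.from_dosages(
            G.dosages[:, :100], marker_ids=G.marker_ids[:100],
            chrom=G.chrom[:100], pos=G.pos[:100], animal_ids=G.animal_ids,
        )
        with pytest.raises(ValueError):
            predict_gebv(sub, summ)
        gebv = predict_gebv(sub, summ, allow_partial=True)
        assert len(gebv) == G.n_animals
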