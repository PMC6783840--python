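"""Whole-genome regression samplers, genomic variance and genetic gain."""

import numpy as np
import pytest

from hapgs import bayes
from hapgs.pedigree import McmcConfig


def toy_regression(seed=1, n=120, p=25, signal=0.3):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * signal
    y = z @ beta + rng.standard_normal(n)
    return y, np.ones((n, 1)), z, beta


def batch_se(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte Carlo standard error (autocorrelation-robust)."""
    s = len(draws)
    b = s // n_batches
    means = draws[: b * n_batches].reshape(n_batches, b, -1).mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


class TestSamplerOracles:
    def test_brr_fixed_variances_matches_ridge(self):
        y, x, z, _ = toy_regression(seed=5)
        s2m, s2e = 0.2, 1.0
        spec = bayes.ModelSpec("BRR", fix_sigma2_m=s2m, fix_sigma2_e=s2e,
                               mcmc=McmcConfig(8000, 1000, 2))
        s = bayes.fit_whole_regression(y, x, z, spec, seed=5)
        w = np.hstack([x, z])
        prec = np.diag([0.0] + [s2e / s2m] * z.shape[1])
        sol = np.linalg.solve(w.T @ w + prec, w.T @ y)[1:]
        mc = s.effects.mean(axis=0)
        se = batch_se(s.effects).ravel()
        assert (np.abs(mc - sol) <= 3 * np.maximum(se, 1e-8)).mean() > 0.9
        assert np.abs(mc - sol).max() < 0.05

    def test_bayes_a_approaches_brr_in_large_df_limit(self):
        y, x, z, _ = toy_regression(seed=7)
        s2m, s2e = 0.2, 1.0
        mc = McmcConfig(4000, 800, 2)
        brr = bayes.fit_whole_regression(
            y, x, z, bayes.ModelSpec("BRR", fix_sigma2_m=s2m, fix_sigma2_e=s2e,
                                     mcmc=mc), seed=9)
        ba = bayes.fit_whole_regression(
            y, x, z, bayes.ModelSpec("BA", nu_m=1e8, s_m=s2m, fix_sigma2_e=s2e,
                                     mcmc=mc), seed=9)
        diff = np.abs(brr.effects.mean(0) - ba.effects.mean(0)).max()
        assert diff < 0.03

    def test_bc_null_inclusion_matches_fixed_prior(self):
        rng = np.random.default_rng(11)
        n, p = 250, 80
        z = rng.standard_normal((n, p))
        y = rng.standard_normal(n)  # independent of markers
        spec = bayes.ModelSpec("BC", pi=0.7, pi_fixed=True,
                               mcmc=McmcConfig(3000, 500, 5))
        s = bayes.fit_whole_regression(y, np.ones((n, 1)), z, spec, seed=13)
        assert s.inclusion.mean() == pytest.approx(0.3, abs=0.07)

    def test_sparse_signal_shrinkage_ordering(self):
        rng = np.random.default_rng(17)
        n, p = 300, 150
        z = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:10] = 1.0
        y = z @ beta + rng.standard_normal(n)
        mc = McmcConfig(2000, 400, 4)
        fits = {
            m: bayes.fit_whole_regression(
                y, np.ones((n, 1)), z, bayes.ModelSpec(m, mcmc=mc), seed=19)
            for m in ("BRR", "BB", "BC")
        }
        null_mean = {m: np.abs(f.effects.mean(0)[10:]).mean()
                     for m, f in fits.items()}
        assert null_mean["BB"] < null_mean["BRR"]
        assert null_mean["BC"] < null_mean["BRR"]

    def test_seed_determinism(self):
        y, x, z, _ = toy_regression(seed=3)
        spec = bayes.ModelSpec("BL", mcmc=McmcConfig(500, 100, 2))
        a = bayes.fit_whole_regression(y, x, z, spec, seed=21)
        b = bayes.fit_whole_regression(y, x, z, spec, seed=21)
        assert np.array_equal(a.effects, b.effects)
        assert np.array_equal(a.sigma2_e, b.sigma2_e)

    def test_column_permutation_of_stored_chain_is_exact(self):
        y, x, z, _ = toy_regression(seed=23)
        spec = bayes.ModelSpec("BRR", mcmc=McmcConfig(800, 200, 3))
        s = bayes.fit_whole_regression(y, x, z, spec, seed=25)
        perm = np.random.default_rng(0).permutation(z.shape[1])
        gebv = z @ s.effects.mean(0)
        gebv_p = z[:, perm] @ s.effects.mean(0)[perm]
        assert np.allclose(gebv, gebv_p)

    def test_zero_variance_phenotype_rejected(self):
        _, x, z, _ = toy_regression()
        with pytest.raises(ValueError):
            bayes.fit_whole_regression(np.ones(len(z)), x, z,
                                       bayes.ModelSpec("BRR"))

    @pytest.mark.parametrize("model", bayes.MODELS)
    def test_all_models_run_and_fit_signal(self, model):
        y, x, z, beta = toy_regression(seed=29, n=150, p=40, signal=0.5)
        s = bayes.fit_whole_regression(
            y, x, z, bayes.ModelSpec(model, mcmc=McmcConfig(1000, 200, 4)),
            seed=31)
        r = np.corrcoef(z @ s.effects.mean(0), z @ beta)[0, 1]
        assert r > 0.8
        assert np.all(s.sigma2_e > 0)


class TestGenomicVariance:
    def test_brr_direct_formula(self):
        s = bayes.PosteriorSamples("BRR", np.zeros((1, 2)), np.zeros((1, 1)),
                                   np.array([1.0]), sigma2_m=np.array([0.3]))
        sg = bayes.genomic_variance(s, np.array([0.5, 0.2]))
        assert sg[0] == pytest.approx(2 * 0.3 * (0.25 + 0.16))

    def test_bl_direct_formula(self):
        s = bayes.PosteriorSamples("BL", np.zeros((1, 2)), np.zeros((1, 1)),
                                   np.array([1.0]),
                                   tau2=np.array([[0.5, 0.2]]),
                                   lambda2=np.array([1.0]))
        sg = bayes.genomic_variance(s, np.array([0.5, 0.5]))
        assert sg[0] == pytest.approx(2 * (0.5 * 0.25 + 0.2 * 0.25))

    def test_bb_excluded_markers_contribute_zero(self):
        s = bayes.PosteriorSamples(
            "BB", np.zeros((1, 2)), np.zeros((1, 1)), np.array([1.0]),
            sigma2_mi=np.array([[0.4, 0.4]]),
            inclusion=np.array([[True, False]]))
        sg = bayes.genomic_variance(s, np.array([0.5, 0.5]))
        assert sg[0] == pytest.approx(2 * 0.4 * 0.25)

    def test_near_monomorphic_column_contribution_vanishes(self):
        s = bayes.PosteriorSamples("BA", np.zeros((1, 1)), np.zeros((1, 1)),
                                   np.array([1.0]),
                                   sigma2_mi=np.array([[100.0]]))
        sg = bayes.genomic_variance(s, np.array([1e-9]))
        assert sg[0] == pytest.approx(0.0, abs=1e-5)

    def test_model_mismatch_rejected(self):
        s = bayes.PosteriorSamples("BRR", np.zeros((1, 1)), np.zeros((1, 1)),
                                   np.array([1.0]), sigma2_m=np.array([1.0]))
        with pytest.raises(ValueError):
            bayes.genomic_variance(s, np.array([0.5]), model="BL")


class TestHeritabilityAndGain:
    def test_constant_draw_ratio(self):
        h2, summ = bayes.heritability_posterior(np.ones(10), np.full(10, 3.0))
        assert np.allclose(h2, 0.25)
        assert summ["mean"] == pytest.approx(0.25)

    def test_zero_genomic_variance(self):
        h2, _ = bayes.heritability_posterior(np.zeros(5), np.ones(5))
        assert np.allclose(h2, 0.0)

    def test_nonpositive_residual_rejected(self):
        with pytest.raises(ValueError):
            bayes.heritability_posterior(np.ones(3), np.zeros(3))

    def test_selection_count_at_study_intensity(self):
        bv = np.arange(646, dtype=float)
        gg = bayes.genetic_gain(bv, 0.1006, phenotypic_mean=100.0)
        # top 65 of 646: mean of 581..645 vs overall mean 322.5
        n_sel = round(0.1006 * 646)
        assert n_sel == 65
        expected = (np.arange(581, 646).mean() - 322.5) / 100.0 * 100
        assert gg == pytest.approx(expected)

    def test_hand_case(self):
        gg = bayes.genetic_gain(np.array([1.0, 2, 3, 4]), 0.5, 10.0)
        assert gg == pytest.approx(10.0)

    def test_no_variation_gives_zero_gain(self):
        assert bayes.genetic_gain(np.full(10, 2.0), 0.3, 5.0) == 0.0

    def test_zero_phenotypic_mean_rejected(self):
        with pytest.raises(ValueError):
            bayes.genetic_gain(np.arange(4.0), 0.5, 0.0)
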