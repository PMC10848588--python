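"""Gibbs samplers: bookkeeping, equivalences, shrinkage, and family-specific kernels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ducksel import bayes, lmm
from ducksel.bayes import (
    BayesModelSpec,
    MCMCConfig,
    gebv_from_effects,
    make_windows,
    run_sampler,
)
from ducksel.genio import GenotypeMatrix
from ducksel.simdata import (
    PhenotypeTable,
    TraitArchitecture,
    make_study_fixture,
    simulate_effects,
    simulate_phenotypes,
)

SHORT = MCMCConfig(n_iterations=1200, burn_in=200, thin=1, seed=3)


class TestBookkeeping:
    def test_default_protocol_retains_2000_samples(self):
        assert MCMCConfig().n_retained == 2000

    def test_chain_lengths_match_config(self, small_study):
        cfg = MCMCConfig(n_iterations=900, burn_in=100, thin=4, seed=1)
        post = run_sampler(small_study.genotyped, small_study.phenotypes, "trait",
                           BayesModelSpec("Cpi"), cfg)
        assert len(post.pi_samples) == cfg.n_retained == 200
        assert len(post.sigma_e2_samples) == 200

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            BayesModelSpec("A")
        with pytest.raises(ValueError):
            BayesModelSpec("R", gamma=(0.1, 0.2, 0.3, 0.4))

    def test_seeded_determinism(self, small_study):
        a = run_sampler(small_study.genotyped, small_study.phenotypes, "trait",
                        BayesModelSpec("B"), SHORT)
        b = run_sampler(small_study.genotyped, small_study.phenotypes, "trait",
                        BayesModelSpec("B"), SHORT)
        np.testing.assert_array_equal(a.effect_means, b.effect_means)
        np.testing.assert_array_equal(a.gebv.to_numpy(), b.gebv.to_numpy())

    def test_constant_phenotype_rejected(self, small_study):
        df = small_study.phenotypes.df.copy()
        df["trait"] = 1.0
        flat = PhenotypeTable(df, trait_cols=["trait"])
        with pytest.raises(ValueError, match="constant"):
            run_sampler(small_study.genotyped, flat, "trait",
                        BayesModelSpec("Cpi"), SHORT)


class TestEquivalences:
    def test_cpi_with_pi_one_matches_gblup(self, small_study):
        post = run_sampler(small_study.genotyped, small_study.phenotypes, "trait",
                           BayesModelSpec("Cpi", pi=1.0),
                           MCMCConfig(2100, 100, 1, seed=5))
        fit = lmm.fit_model("gblup", small_study.phenotypes, "trait",
                            genotypes=small_study.genotyped)
        gebv_g = fit.breeding_values.loc[post.gebv.index]
        assert np.corrcoef(post.gebv, gebv_g)[0, 1] > 0.98

    def test_gebv_invariant_to_phenotype_shift(self, small_study):
        post1 = run_sampler(small_study.genotyped, small_study.phenotypes, "trait",
                            BayesModelSpec("Cpi"), SHORT)
        df = small_study.phenotypes.df.copy()
        df["trait"] = df["trait"] + 1000.0
        shifted = PhenotypeTable(df, trait_cols=["trait"])
        post2 = run_sampler(small_study.genotyped, shifted, "trait",
                            BayesModelSpec("Cpi"), SHORT)
        np.testing.assert_allclose(post1.gebv, post2.gebv, atol=1e-8)


class TestShrinkage:
    def test_pure_noise_effects_shrink_toward_zero(self, small_study):
        g = small_study.genotyped
        eff = simulate_effects(TraitArchitecture("polygenic"), g, seed=1)
        ph_sig = simulate_phenotypes(g, eff, 0.5, seed=2)
        ph_null = simulate_phenotypes(g, eff, 0.0, seed=2)
        post_sig = run_sampler(g, ph_sig, "trait", BayesModelSpec("Cpi"), SHORT)
        post_null = run_sampler(g, ph_null, "trait", BayesModelSpec("Cpi"), SHORT)
        # compare on a common scale: phenotypes are standardized per fit
        scale_sig = np.std(ph_sig.df["trait"])
        scale_null = np.std(ph_null.df["trait"])
        m_sig = np.mean(np.abs(post_sig.effect_means)) / scale_sig
        m_null = np.mean(np.abs(post_null.effect_means)) / scale_null
        sd_sig = np.std(post_sig.effect_means) / scale_sig
        assert m_null < 0.05 * sd_sig * np.sqrt(2 / np.pi) + 0.05 * m_sig + 1e-12 \
            or m_null < 0.25 * m_sig

    @pytest.mark.parametrize("family", bayes.FAMILIES)
    def test_mean_abs_effect_monotone_in_h2(self, family, small_study):
        g = small_study.genotyped
        eff = simulate_effects(TraitArchitecture("polygenic"), g, seed=4)
        means = []
        for h2 in (0.5, 0.2, 0.05):
            ph = simulate_phenotypes(g, eff, h2, seed=9)
            scale = np.std(ph.df["trait"].to_numpy())
            post = run_sampler(g, ph, "trait", BayesModelSpec(family),
                               MCMCConfig(800, 200, 1, seed=7))
            means.append(np.mean(np.abs(post.effect_means)) / scale)
        assert means[0] >= means[1] >= means[2]


class TestSparseSignal:
    def test_true_qtl_rank_top_of_inclusion_probability(self):
        """BayesB puts every variance-carrying simulated QTL in the top tail of
        inclusion probability (a scaled-t draw can be ~0; those are undetectable
        in principle, so the check is on QTL holding >= 5% of genetic variance)."""
        for rep in range(2):
            fx = make_study_fixture(
                n_f2=400, markers_per_chromosome=200, n_chromosomes=5, h2=0.5,
                architecture=TraitArchitecture("sparse_t", n_qtl=10), seed=900 + rep)
            g = fx.genotyped
            post = run_sampler(g, fx.phenotypes, "trait", BayesModelSpec("B"),
                               MCMCConfig(2100, 100, 1, seed=rep))
            qtl = np.flatnonzero(fx.effects != 0)
            p = g.allele_frequency()
            contrib = np.var((g.dosage() - 2 * p) * fx.effects, axis=0)
            major = qtl[contrib[qtl] / contrib.sum() >= 0.05]
            cutoff = np.quantile(post.inclusion_prob, 0.95)
            assert len(major) >= 3
            assert np.all(post.inclusion_prob[major] >= cutoff)


class TestFamilyKernels:
    def test_bayesr_null_weights_assign_all_to_null_component(self):
        rng = np.random.default_rng(0)
        m, n = 50, 40
        Wt = np.ascontiguousarray(rng.standard_normal((m, n)))
        e = rng.standard_normal(n)
        alpha = np.zeros(m)
        comp = np.zeros(m, dtype=np.int64)
        var_k = np.array([0.0, 0.0, 0.0, 0.0])  # zero residual variance contribution
        logw = np.log(np.array([1 - 3e-12, 1e-12, 1e-12, 1e-12]))
        bayes._seed_rng(1)
        bayes._sweep_r(Wt, e, alpha, comp, np.einsum("ji,ji->j", Wt, Wt),
                       var_k, 1.0, logw)
        assert np.all(comp == 0)
        assert not np.any(alpha)

    def test_bayess_prior_recovered_when_maf_flat(self):
        """With every marker at the same MAF, S is unidentified and its chain
        should reproduce the N(0,1) prior."""
        rng = np.random.default_rng(12)
        n, m = 200, 100
        base = np.array([0] * 50 + [1] * 100 + [2] * 50, dtype=np.int8)
        codes = np.column_stack([rng.permutation(base) for _ in range(m)])
        marker_map = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, m + 1) * 1000,
                                   "a1": "A", "a2": "G"})
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        g = GenotypeMatrix(codes, ids, marker_map)
        assert np.allclose(g.allele_frequency(), 0.5)
        df = pd.DataFrame({"id": ids, "sex": "M", "feed_room": "room1",
                           "trait": rng.standard_normal(n)})
        ph = PhenotypeTable(df, trait_cols=["trait"], factor_cols=[])
        post = run_sampler(g, ph, "trait", BayesModelSpec("S"),
                           MCMCConfig(21_000, 1_000, 10, seed=2), factor_cols=[])
        ks = stats.kstest(post.S_samples, "norm")
        assert ks.pvalue > 0.01

    def test_bayesn_window_limit_is_one_per_chromosome(self, small_study):
        mm = small_study.genotyped.marker_map
        win = make_windows(mm, window_bp=10**12)
        assert len(np.unique(win)) == mm["chrom"].nunique()

    def test_bayesn_default_windows_are_bounded_tiles(self, small_study):
        mm = small_study.genotyped.marker_map
        win = make_windows(mm, window_bp=200_000)
        for w in np.unique(win):
            sel = win == w
            assert mm.loc[sel, "chrom"].nunique() == 1
            span = mm.loc[sel, "pos"].max() - mm.loc[sel, "pos"].min()
            assert span < 200_000


class TestGEBV:
    def test_zero_effects_give_zero_gebv(self, small_study):
        g = small_study.genotyped
        gebv = gebv_from_effects(g, np.zeros(g.n_markers), g.allele_frequency())
        assert not np.any(gebv.to_numpy())

    def test_single_marker_hand_computation(self):
        codes = np.array([[0], [1], [2]], dtype=np.int8)
        mm = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "a1": "A", "a2": "G"})
        g = GenotypeMatrix(codes, np.array(["a", "b", "c"], dtype=object), mm)
        gebv = gebv_from_effects(g, np.array([1.0]), np.array([0.5]))
        np.testing.assert_allclose(gebv.to_numpy(), [-1.0, 0.0, 1.0])

    def test_mismatched_effect_vector_rejected(self, small_study):
        g = small_study.genotyped
        with pytest.raises(ValueError):
            gebv_from_effects(g, np.zeros(g.n_markers + 1), g.allele_frequency())
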