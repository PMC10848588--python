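"""Founder/cross simulation, trait architectures, phenotypes, derived traits."""

import numpy as np
import pandas as pd
import pytest

from ducksel import kinship, lmm
from ducksel.simdata import (
    CrossDesign,
    FixedEffectSpec,
    FounderPopulationSpec,
    Pedigree,
    TraitArchitecture,
    UNKNOWN,
    derive_traits,
    make_study_fixture,
    simulate_cross,
    simulate_effects,
    simulate_founders,
    simulate_phenotypes,
)


def _r2(a, b):
    c = np.corrcoef(a, b)[0, 1]
    return c * c


class TestFounders:
    def test_seeded_determinism(self):
        spec = FounderPopulationSpec(n_founders_per_line=100, n_chromosomes=1,
                                     markers_per_chromosome=250, seed=7)
        a = simulate_founders(spec)
        b = simulate_founders(spec)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_forced_frequency_half(self):
        spec = FounderPopulationSpec(n_founders_per_line=400, n_chromosomes=1,
                                     markers_per_chromosome=100,
                                     maf_low=0.5, maf_high=0.5, seed=1)
        g = simulate_founders(spec)
        line1 = g.subset_individuals([i for i in g.individual_ids if i.startswith("L1_")])
        assert abs(np.nanmean(line1.maf()) - 0.5) < 0.02

    def test_large_decay_rate_gives_no_ld(self):
        spec = FounderPopulationSpec(n_founders_per_line=300, n_chromosomes=1,
                                     markers_per_chromosome=60,
                                     ld_decay_rate=1.0, seed=2)
        g = simulate_founders(spec)
        codes = g.codes[:300].astype(float)  # one line only (uniform frequencies)
        r2s = [
            _r2(codes[:, j], codes[:, j + 1])
            for j in range(codes.shape[1] - 1)
            if codes[:, j].std() > 0 and codes[:, j + 1].std() > 0
        ]
        assert np.mean(r2s) < 0.02

    def test_small_decay_rate_gives_adjacent_ld(self):
        spec = FounderPopulationSpec(n_founders_per_line=300, n_chromosomes=1,
                                     markers_per_chromosome=60,
                                     ld_decay_rate=1e-9, seed=2)
        g = simulate_founders(spec)
        codes = g.codes[:300].astype(float)
        r2s = [_r2(codes[:, j], codes[:, j + 1]) for j in range(codes.shape[1] - 1)]
        assert np.mean(r2s) > 0.2

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            FounderPopulationSpec(markers_per_chromosome=0)
        with pytest.raises(ValueError):
            FounderPopulationSpec(maf_low=0.3, maf_high=0.2)


class TestCross:
    def test_mendelian_consistency_exhaustive(self, small_study):
        g = small_study.genotypes
        idx = {v: k for k, v in enumerate(g.individual_ids)}
        for ind, sire, dam in small_study.pedigree.records:
            if sire == UNKNOWN:
                continue
            off, s, d = (g.codes[idx[k]] for k in (ind, sire, dam))
            for parent in (s, d):
                # an offspring cannot be homozygous for an allele absent in a parent
                assert not np.any((off == 2) & (parent == 0))
                assert not np.any((off == 0) & (parent == 2))

    def test_zero_recombination_transmits_whole_haplotypes(self):
        founders = simulate_founders(FounderPopulationSpec(
            n_founders_per_line=5, n_chromosomes=2, markers_per_chromosome=50, seed=3))
        ped, g = simulate_cross(founders, CrossDesign(n_f1=4, n_f2=10,
                                                      crossover_rate_per_bp=0.0, seed=4))
        idx = {v: k for k, v in enumerate(g.individual_ids)}
        chroms = g.marker_map["chrom"].to_numpy()
        for ind, sire, dam in ped.records:
            if sire == UNKNOWN:
                continue
            for hap_i in range(2):
                parent = sire if hap_i == 0 else dam
                for c in pd.unique(chroms):
                    sl = chroms == c
                    child_hap = g.haplotypes[idx[ind]][hap_i][sl]
                    par_haps = g.haplotypes[idx[parent]][:, sl]
                    assert (np.array_equal(child_hap, par_haps[0])
                            or np.array_equal(child_hap, par_haps[1]))

    def test_parent_offspring_genomic_relationship(self):
        """Mean parent-offspring G entry ~ half the mean diagonal over replicates."""
        ratios = []
        for rep in range(10):
            # large founder pools keep the average relatedness (and hence the
            # observed-frequency centering bias of G) small
            founders = simulate_founders(FounderPopulationSpec(
                n_founders_per_line=100, n_chromosomes=3,
                markers_per_chromosome=150, seed=100 + rep))
            ped, g = simulate_cross(founders, CrossDesign(n_f1=100, n_f2=100, seed=rep))
            G = kinship.build_G(g)
            po = []
            for i, s, d in ped.records:
                if s != UNKNOWN:
                    po += [G.loc(i, s), G.loc(i, d)]
            ratios.append(np.mean(po) / np.mean(np.diag(G.values)))
        assert abs(np.mean(ratios) - 0.5) < 0.05

    def test_f2_without_f1_material_rejected(self, tiny_geno):
        with pytest.raises(ValueError):
            simulate_cross(tiny_geno, CrossDesign())


class TestEffects:
    def test_pi_zero_gives_all_zero_vector(self):
        arch = TraitArchitecture("normal_mixture_pi", pi=0.0, h2_target=0.0)
        assert not np.any(simulate_effects(arch, 500, seed=0))

    def test_null_component_weights_give_zero_effects(self):
        arch = TraitArchitecture("four_component_R", component_weights=(1, 0, 0, 0),
                                 h2_target=0.0)
        assert not np.any(simulate_effects(arch, 500, seed=0))

    def test_pi_zero_with_positive_h2_rejected(self):
        arch = TraitArchitecture("normal_mixture_pi", pi=0.0, h2_target=0.5)
        with pytest.raises(ValueError):
            simulate_effects(arch, 500, seed=0)

    def test_maf_decoupled_at_s_zero(self, small_study):
        """S = 0 leaves |effect| uncorrelated with MAF over replicates."""
        g = small_study.genotyped
        maf = g.maf()
        cors = []
        for rep in range(100):
            eff = simulate_effects(
                TraitArchitecture("maf_coupled_S", S=0.0, pi=1.0), g, seed=rep)
            cors.append(np.corrcoef(np.abs(eff), maf)[0, 1])
        assert abs(np.mean(cors)) < 0.02

    def test_maf_coupling_at_negative_s(self, small_study):
        """S < 0 concentrates variance on rare alleles."""
        g = small_study.genotyped
        maf = g.maf()
        cors = []
        for rep in range(50):
            eff = simulate_effects(
                TraitArchitecture("maf_coupled_S", S=-1.0, pi=1.0), g, seed=rep)
            cors.append(np.corrcoef(np.abs(eff), maf)[0, 1])
        assert np.mean(cors) < -0.1

    def test_architecture_contrast_sparse_vs_polygenic(self):
        g = simulate_founders(FounderPopulationSpec(
            n_founders_per_line=100, n_chromosomes=5,
            markers_per_chromosome=400, seed=8))
        p = g.allele_frequency()
        Z = g.dosage() - 2 * p

        def top10_share(eff):
            contrib = np.var(Z * eff, axis=0)
            order = np.argsort(np.abs(eff))[::-1]
            return contrib[order[:10]].sum() / contrib.sum()

        sparse = simulate_effects(TraitArchitecture("sparse_t", n_qtl=10), g, seed=1)
        poly = simulate_effects(TraitArchitecture("polygenic"), g, seed=1)
        assert top10_share(sparse) > 0.99
        assert top10_share(poly) < 0.05


class TestPhenotypes:
    def test_zero_h2_is_independent_of_genotype(self, small_study):
        g = small_study.genotyped
        eff = simulate_effects(TraitArchitecture("polygenic"), g, seed=0)
        ph = simulate_phenotypes(g, eff, 0.0, seed=1)
        assert float(ph.true_genetic_values.abs().max()) == 0.0

    def test_sex_shift_recovered_in_means(self):
        fx = make_study_fixture(n_f2=1000, markers_per_chromosome=40, n_chromosomes=2,
                                fixed=FixedEffectSpec(sex_shift=100.0), seed=3)
        df = fx.phenotypes.df
        means = df.groupby("sex")["trait"].mean()
        assert abs(abs(means.diff().iloc[-1]) - 100.0) < 5.0

    def test_realized_heritability_close_to_target(self):
        """Realized var(g)/var(g+e) tracks the target across replicates."""
        vals = []
        for rep in range(10):
            fx = make_study_fixture(n_f2=1000, markers_per_chromosome=80,
                                    n_chromosomes=2, h2=0.4, seed=400 + rep)
            df = fx.phenotypes.df
            g = fx.true_genetic_values.loc[df["id"]].to_numpy()
            shift = df["trait"].to_numpy() - g
            # remove the simulated fixed effects to isolate g + e
            X, _ = lmm.build_design(df, ["sex", "feed_room"])
            resid = (g + (shift - X @ np.linalg.lstsq(X, shift, rcond=None)[0]))
            vals.append(np.var(g) / np.var(resid))
        assert abs(np.mean(vals) - 0.4) < 0.03

    def test_all_zero_effects_with_h2_rejected(self, small_study):
        with pytest.raises(ValueError):
            simulate_phenotypes(small_study.genotyped, np.zeros(small_study.genotyped.n_markers),
                                0.5, seed=0)


class TestDerivedTraits:
    def test_average_daily_gain_convention(self):
        out = derive_traits(weights={1: 45.7, 19: 680.1, 28: 1149.4})
        assert out["ADG_1-19"] == pytest.approx(33.4, abs=0.05)
        assert out["ADG_1-28"] == pytest.approx(39.4, abs=0.05)

    def test_breast_muscle_volume_unit_cube(self):
        assert derive_traits(morphology=(10.0, 10.0, 1.0))["BMV"] == pytest.approx(100.0)

    def test_missing_later_weight_gives_missing_adg(self):
        out = derive_traits(weights={1: 45.7, 56: float("nan")})
        assert np.isnan(out["ADG_1-56"])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            derive_traits(weights={1: -5.0, 19: 600.0})


class TestPedigreeContainer:
    def test_unordered_parent_rejected(self):
        with pytest.raises(ValueError, match="not listed before"):
            Pedigree([("kid", "mom", UNKNOWN), ("mom", UNKNOWN, UNKNOWN)])

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Pedigree([("a", UNKNOWN, UNKNOWN), ("a", UNKNOWN, UNKNOWN)])
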