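"""Population simulator: pedigree structure, gene dropping, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from canineqg import simpop
from canineqg.errors import ConfigError


class TestSimulatePedigree:
    def test_founders_only(self):
        cfg = simpop.SimConfig(n_founders=10, n_generations=0)
        ped = simpop.simulate_pedigree(cfg)
        assert len(ped) == 10
        assert all(r.sire_id is None and r.dam_id is None for r in ped.records)

    def test_sized_to_study_pedigree(self):
        # 72 founders + 5 generations x 80 matings x 2 pups = 872 animals
        cfg = simpop.SimConfig(
            n_founders=72, n_generations=5, matings_per_generation=80,
            offspring_per_mating=2,
        )
        assert len(simpop.simulate_pedigree(cfg)) == 872

    def test_default_config_gives_378_animals(self):
        assert len(simpop.simulate_pedigree(simpop.SimConfig())) == 378

    def test_same_seed_identical(self, small_config):
        p1 = simpop.simulate_pedigree(small_config)
        p2 = simpop.simulate_pedigree(small_config)
        assert p1.records == p2.records

    def test_parents_from_earlier_generations(self, small_population):
        ped, *_ = small_population
        gen = {r.animal_id: r.generation for r in ped.records}
        for r in ped.records:
            for p in (r.sire_id, r.dam_id):
                if p is not None:
                    assert gen[p] < r.generation

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            simpop.simulate_pedigree(simpop.SimConfig(n_founders=0))
        with pytest.raises(ConfigError):
            simpop.simulate_pedigree(
                simpop.SimConfig(n_generations=2, matings_per_generation=0)
            )


class TestSimulateGenotypes:
    def test_snp_bookkeeping(self):
        cfg = simpop.SimConfig(
            n_founders=6, n_generations=1, matings_per_generation=3,
            n_chromosomes=38, snps_per_chromosome=100, genotyped_fraction=1.0,
        )
        ped = simpop.simulate_pedigree(cfg)
        gm = simpop.simulate_genotypes(ped, cfg)
        assert gm.n_snps == 3800

    def test_determinism(self, small_config):
        ped = simpop.simulate_pedigree(small_config)
        g1 = simpop.simulate_genotypes(ped, small_config)
        g2 = simpop.simulate_genotypes(ped, small_config)
        assert g1.equals(g2)

    def test_mendelian_consistency(self, small_config):
        ped = simpop.simulate_pedigree(small_config)
        gm = simpop.simulate_genotypes(ped, small_config, include_all=True)
        idx = {a: i for i, a in enumerate(gm.animal_ids)}
        X = gm.dosage
        for r in ped.records:
            if r.sire_id is None or r.dam_id is None:
                continue
            child, s, d = X[idx[r.animal_id]], X[idx[r.sire_id]], X[idx[r.dam_id]]
            # each parent transmits 1 allele iff heterozygous or forced
            lo = np.floor(s / 2) + np.floor(d / 2)
            hi = np.ceil(s / 2) + np.ceil(d / 2)
            assert ((child >= lo) & (child <= hi)).all()

    def test_founder_frequency_half_mean_dosage_one(self):
        cfg = simpop.SimConfig(
            n_founders=2000, n_generations=0, founder_maf_range=(0.5, 0.5),
            n_chromosomes=1, snps_per_chromosome=1, genotyped_fraction=1.0,
            missing_rate=0.0, seed=5,
        )
        ped = simpop.simulate_pedigree(cfg)
        gm = simpop.simulate_genotypes(ped, cfg)
        # mean dosage ~ Binomial(2, 0.5): SE = sqrt(0.5/2000)
        se = np.sqrt(2 * 0.5 * 0.5 / 2000)
        assert abs(gm.dosage.mean() - 1.0) < 3 * se

    def test_genotyped_fraction_takes_youngest(self, small_config):
        ped = simpop.simulate_pedigree(small_config)
        gm = simpop.simulate_genotypes(ped, small_config)
        n_geno = round(small_config.genotyped_fraction * len(ped))
        assert gm.animal_ids == ped.ids[-n_geno:]


class TestSimulatePhenotypes:
    def test_noise_free_limit_phenotype_equals_bv(self):
        fx = simpop.FixedEffectsConfig(
            intercept=0.0, sex_effect=0.0, date_effect_sd=0.0, age_slope=0.0
        )
        cfg = simpop.SimConfig(
            sigma_e2=0.0, fixed_effects=fx, n_founders=10, n_generations=2,
            matings_per_generation=5,
        )
        ped = simpop.simulate_pedigree(cfg)
        phen, truth = simpop.simulate_phenotypes(ped, None, cfg)
        bv = truth.true_breeding_values.loc[phen["animal_id"]].to_numpy()
        np.testing.assert_allclose(phen["trait"].to_numpy(), bv, atol=1e-12)

    def test_true_h2_from_study_components(self):
        cfg = simpop.SimConfig(sigma_a2=4.430, sigma_e2=5.323)
        ped = simpop.simulate_pedigree(cfg)
        _, truth = simpop.simulate_phenotypes(ped, None, cfg)
        assert truth.true_h2 == pytest.approx(0.454, abs=5e-4)

    def test_degenerate_variances_rejected(self):
        cfg = simpop.SimConfig(sigma_a2=0.0, sigma_e2=0.0)
        ped = simpop.simulate_pedigree(cfg)
        with pytest.raises(ConfigError):
            simpop.simulate_phenotypes(ped, None, cfg)

    def test_founder_bv_variance_calibrated(self):
        # across 50 replicates the founder BV variance matches sigma_a2
        draws = []
        for rep in range(50):
            cfg = simpop.SimConfig(
                seed=900 + rep, n_founders=40, n_generations=0, sigma_a2=2.0
            )
            ped = simpop.simulate_pedigree(cfg)
            _, truth = simpop.simulate_phenotypes(ped, None, cfg)
            draws.append(truth.true_breeding_values.to_numpy())
        var = np.var(np.concatenate(draws), ddof=1)
        assert abs(var - 2.0) / 2.0 < 0.10

    def test_midparent_regression_recovers_h2(self):
        # offspring phenotype on mid-parent phenotype slope ~ h2, averaged
        # over replicates (the single-replicate slope is noisy even at n=800)
        slopes = []
        for seed in range(20, 26):
            cfg = simpop.SimConfig(
                seed=seed, n_founders=1600, n_generations=1,
                matings_per_generation=800, offspring_per_mating=1,
                sigma_a2=4.0, sigma_e2=6.0,
                fixed_effects=simpop.FixedEffectsConfig(
                    intercept=0.0, sex_effect=0.0, date_effect_sd=0.0,
                    age_slope=0.0,
                ),
            )
            ped = simpop.simulate_pedigree(cfg)
            phen, truth = simpop.simulate_phenotypes(ped, None, cfg)
            y = phen.set_index("animal_id")["trait"]
            mid = [
                0.5 * (y[r.sire_id] + y[r.dam_id])
                for r in ped.records if r.sire_id is not None
            ]
            off = [y[r.animal_id] for r in ped.records if r.sire_id is not None]
            slopes.append(np.polyfit(mid, off, 1)[0])
        assert np.mean(slopes) == pytest.approx(0.4, abs=0.05)

    def test_qtl_contribution_included(self):
        cfg = simpop.SimConfig(
            seed=3, n_founders=100, n_generations=0, n_chromosomes=2,
            snps_per_chromosome=50, n_qtl=10, qtl_variance_fraction=0.5,
            sigma_a2=4.0, genotyped_fraction=1.0, missing_rate=0.0,
        )
        ped = simpop.simulate_pedigree(cfg)
        gm = simpop.simulate_genotypes(ped, cfg, include_all=True)
        _, truth = simpop.simulate_phenotypes(ped, gm, cfg)
        assert len(truth.qtl_positions) == 10
        var = truth.true_breeding_values.var(ddof=1)
        assert var == pytest.approx(4.0, rel=0.5)  # loose: one replicate

    def test_qtl_without_genotypes_rejected(self):
        cfg = simpop.SimConfig(n_qtl=5, qtl_variance_fraction=0.2)
        ped = simpop.simulate_pedigree(cfg)
        with pytest.raises(ConfigError):
            simpop.simulate_phenotypes(ped, None, cfg)


class TestMakeBinaryTrait:
    def _liabilities(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(n)], "trait": rng.normal(size=n)}
        )

    def test_study_incidence_on_378_gives_224_ones(self):
        phen = self._liabilities(378)
        out = simpop.make_binary_trait(phen, 0.593)
        assert out["trait_bin"].sum() == 224

    def test_half_incidence_balanced(self):
        out = simpop.make_binary_trait(self._liabilities(101), 0.5)
        ones = out["trait_bin"].sum()
        assert abs(ones - (101 - ones)) <= 1

    def test_threshold_preserves_ranking(self):
        out = simpop.make_binary_trait(self._liabilities(200, seed=4), 0.3)
        ones = out.loc[out["trait_bin"] == 1, "trait"]
        zeros = out.loc[out["trait_bin"] == 0, "trait"]
        assert ones.min() >= zeros.max()

    @pytest.mark.parametrize("incidence", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_incidence(self, incidence):
        with pytest.raises(ConfigError):
            simpop.make_binary_trait(self._liabilities(10), incidence)


def test_full_population_deterministic(small_config):
    a = simpop.simulate_population(small_config)
    b = simpop.simulate_population(small_config)
    assert a[0].records == b[0].records
    assert a[1].equals(b[1])
    pd.testing.assert_frame_equal(a[2], b[2])
    pd.testing.assert_series_equal(
        a[3].true_breeding_values, b[3].true_breeding_values
    )
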