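import numpy as np
import pandas as pd
import pytest

from microevo import (
    ArchitectureSpec,
    StudyConfig,
    TraitModel,
    assign_architecture,
    simulate_breeding_values,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)
from microevo.simulate import SimulationError, default_genetic_map


class TestPedigreeSimulation:
    def test_one_year_gives_founders_plus_one_cohort(self):
        ped = simulate_pedigree(n_founders=20, n_years=1, seed=0, max_population=60)
        assert (ped.birth_year >= ped.birth_year.min()).all()
        assert set(ped.birth_year[~ped.is_founder]) <= {1990}

    def test_every_cohort_non_empty_with_full_survival(self):
        ped = simulate_pedigree(n_founders=10, n_years=5, survival_prob=1.0,
                                mean_offspring_per_female_per_year=1.0, seed=1,
                                max_population=200)
        years = set(ped.birth_year)
        assert {1990, 1991, 1992, 1993, 1994} <= years

    def test_default_pedigree_passes_validation_round_trip(self, tmp_path):
        from microevo import read_pedigree

        ped = simulate_pedigree(n_founders=30, n_years=6, seed=2, max_population=100)
        path = tmp_path / "ped.tsv"
        ped.write(path)
        ped2 = read_pedigree(path)
        assert ped2.n == ped.n

    def test_extinction_raises_helpful_error(self):
        with pytest.raises(SimulationError, match="survival_prob|founders"):
            simulate_pedigree(n_founders=4, n_years=12, survival_prob=0.05, seed=3)


class TestFounderHaplotypes:
    def test_forced_frequency_half(self):
        gmap = default_genetic_map(120, 3, 0.05)
        pool, freqs = simulate_founder_haplotypes(
            100, gmap, maf_beta_params=(2000, 2000), seed=0
        )
        # Beta(2000,2000) concentrates at 0.5; realised frequencies binomial
        realised = pool.mean(axis=0)
        assert abs(realised.mean() - 0.5) < 0.03
        assert np.all(np.abs(freqs - 0.5) < 0.1)

    def test_unlinked_adjacent_snps_uncorrelated(self):
        gmap = default_genetic_map(40, 40, 0.5)   # one SNP per chromosome
        pool, _ = simulate_founder_haplotypes(150, gmap, seed=1)
        r = np.corrcoef(pool.T)
        off = r[np.triu_indices_from(r, 1)]
        assert np.nanmean(np.abs(off)) < 0.12

    def test_ld_decays_with_recombination_fraction(self):
        """Adjacent-pair LD of the full map process vs a direct two-locus run
        of the same copying process: tightly linked pairs show strong LD, and
        the two-locus oracle sits at the same level; unlinked pairs do not."""

        def mean_r2(gmap, seeds):
            vals = []
            for seed in seeds:
                pool, _ = simulate_founder_haplotypes(
                    200, gmap, maf_beta_params=(5, 5), seed=seed,
                    innovation=0.02, n_seed_haplotypes=10,
                )
                keep = (pool.mean(axis=0) > 0.05) & (pool.mean(axis=0) < 0.95)
                if keep.sum() < 2:
                    continue
                r = np.corrcoef(pool[:, keep].T)
                vals.append(np.nanmean(np.diag(r, 1) ** 2))
            return float(np.mean(vals))

        two_locus = mean_r2(default_genetic_map(2, 1, 1e-4), range(10))
        many_locus = mean_r2(default_genetic_map(50, 1, 1e-4), range(3))
        unlinked = mean_r2(default_genetic_map(2, 2, 0.5), range(10))
        assert two_locus > 0.05
        assert many_locus > 0.05
        assert unlinked < 0.02
        assert abs(two_locus - many_locus) < 0.1   # same stationary LD scale
        assert two_locus > 5 * unlinked


class TestArchitecture:
    def test_all_null_component_gives_zero_effects(self):
        spec = ArchitectureSpec(n_snps=50, proportions=(1.0, 0.0, 0.0, 0.0), sigma2_a=0.0)
        beta = assign_architecture(spec, np.full(50, 0.5), seed=0)
        assert np.all(beta == 0.0)

    def test_all_null_with_positive_target_raises(self):
        spec = ArchitectureSpec(n_snps=50, proportions=(1.0, 0.0, 0.0, 0.0), sigma2_a=1.0)
        with pytest.raises(SimulationError):
            assign_architecture(spec, np.full(50, 0.5), seed=0)

    def test_single_causal_snp_carries_whole_variance(self):
        spec = ArchitectureSpec(n_snps=1, proportions=(0.0, 0.0, 0.0, 1.0), sigma2_a=2.0)
        p = np.array([0.3])
        beta = assign_architecture(spec, p, seed=1)
        assert 2 * p[0] * (1 - p[0]) * beta[0] ** 2 == pytest.approx(2.0)

    def test_realised_genic_variance_hits_target_exactly(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 1000)
        spec = ArchitectureSpec(n_snps=1000, sigma2_a=2.6)
        beta = assign_architecture(spec, p, seed=3)
        # direct summation oracle
        assert np.sum(2 * p * (1 - p) * beta**2) == pytest.approx(2.6, rel=1e-12)


class TestPhenotypeSimulation:
    def test_zero_variances_give_deterministic_weights(self, small_study):
        model = TraitModel(sigma2_a=0, sigma2_pe=0, sigma2_by=0, sigma2_cy=0,
                          sigma2_e=0)
        rec, truth = simulate_phenotypes(
            small_study.pedigree, small_study.genotypes,
            np.zeros(small_study.genotypes.n_snps), model,
            years_measured=range(1995, 1999), seed=0,
        )
        expect = (model.mu
                  + np.where(rec["sex"] == "M", model.sex_effect, 0.0)
                  + model.age_effect(rec["capture_age"].to_numpy()))
        assert np.allclose(rec["weight"], expect)

    def test_heritability_identity(self):
        """With only additive and residual variance, phenotype regressed on
        true BV has slope ~1 and R^2 ~ h^2."""
        study = simulate_study(StudyConfig(
            n_founders=60, n_years=10, max_population=250, seed=9,
            architecture=ArchitectureSpec(n_snps=200),
            trait=TraitModel(sigma2_pe=0, sigma2_by=0, sigma2_cy=0,
                             sigma2_a=2.6, sigma2_e=7.8),
        ))
        rec = study.records
        bv = study.true_bv.reindex(rec["id"]).to_numpy()
        y = (rec["weight"].to_numpy()
             - np.where(rec["sex"] == "M", study.config.trait.sex_effect, 0.0)
             - study.config.trait.age_effect(rec["capture_age"].to_numpy()))
        slope, intercept = np.polyfit(bv, y, 1)
        r2 = np.corrcoef(bv, y)[0, 1] ** 2
        h2 = np.var(bv) / np.var(y)
        assert slope == pytest.approx(1.0, abs=0.15)
        assert r2 == pytest.approx(h2, abs=0.1)

    def test_mendelian_consistency(self, small_study):
        """Every offspring allele is one of the parental alleles, per locus."""
        ped = small_study.pedigree
        hap = small_study.genotypes.haplotypes
        children = np.nonzero((ped.sire_idx >= 0) & (ped.dam_idx >= 0))[0]
        for i in children[:100]:
            for slot, parent in ((0, ped.sire_idx[i]), (1, ped.dam_idx[i])):
                child = hap[i, slot]
                par = hap[parent]
                assert np.all((child == par[0]) | (child == par[1]))

    def test_neutral_regime_has_no_expected_trend(self):
        slopes = [
            simulate_study(StudyConfig(n_founders=60, n_years=10,
                                       max_population=200, seed=s,
                                       architecture=ArchitectureSpec(n_snps=150))
                           ).true_cohort_slope()
            for s in range(12)
        ]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3.5 * se + 0.01

    def test_viability_selection_induces_positive_trend(self):
        slopes = []
        for s in range(6):
            study = simulate_study(StudyConfig(
                n_founders=60, n_years=12, max_population=250, seed=s,
                architecture=ArchitectureSpec(n_snps=150),
                trait=TraitModel(selection="viability", selection_strength=0.3),
            ))
            slopes.append(study.true_cohort_slope())
        assert np.mean(slopes) > 0.02
        assert sum(sl > 0 for sl in slopes) >= 5

    def test_seed_determinism(self):
        a = simulate_study(StudyConfig(n_founders=40, n_years=6,
                                       max_population=120, seed=11,
                                       architecture=ArchitectureSpec(n_snps=100)))
        b = simulate_study(StudyConfig(n_founders=40, n_years=6,
                                       max_population=120, seed=11,
                                       architecture=ArchitectureSpec(n_snps=100)))
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert a.records.equals(b.records)
        assert np.array_equal(a.true_bv.to_numpy(), b.true_bv.to_numpy())


class TestInfinitesimalBreedingValues:
    def test_founder_variance_matches_sigma2a(self):
        ped = simulate_pedigree(n_founders=400, n_years=1, seed=0, max_population=500)
        bv = simulate_breeding_values(ped, 3.0, seed=1)
        founders = ped.is_founder
        assert np.var(bv.to_numpy()[founders], ddof=1) == pytest.approx(3.0, rel=0.25)

    def test_zero_variance_gives_zero_values(self, small_study):
        bv = simulate_breeding_values(small_study.pedigree, 0.0, seed=2)
        assert np.all(bv.to_numpy() == 0.0)
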