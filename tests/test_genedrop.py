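import numpy as np
import pandas as pd
import pytest

from microevo import (
    DriftResult,
    GeneDropConfig,
    Pedigree,
    TrendPosterior,
    drift_null_genomic,
    drift_null_pedigree,
    gene_drop,
    p_drift,
    simulate_pedigree,
)
from microevo.genedrop import DriftError
from microevo.genotypes import GeneticMap
from microevo.simulate import default_genetic_map, simulate_founder_haplotypes


@pytest.fixture(scope="module")
def drop_setup(small_study_shared):
    study = small_study_shared
    ped = study.pedigree
    g = study.genotypes
    idx = ped.index_of(g.ids)
    pool = g.haplotypes[ped.birth_year[idx] < 1990].reshape(-1, g.n_snps)
    return ped, g, pool


@pytest.fixture(scope="module")
def small_study_shared(request):
    return request.getfixturevalue("small_study")


class TestGeneDrop:
    def test_zero_recombination_transmits_intact_haplotypes(self, drop_setup):
        ped, g, pool = drop_setup
        gmap = GeneticMap(pd.DataFrame({
            "chrom": ["1"] * g.n_snps, "snp_id": g.snp_ids,
            "pos": np.arange(g.n_snps, dtype=float), "rec_next": 0.0,
        }))
        sim = gene_drop(ped, pool, gmap, GeneDropConfig(), seed=1)
        hap = sim.haplotypes
        children = np.nonzero((ped.sire_idx >= 0) & (ped.dam_idx >= 0))[0]
        for i in children[:60]:
            for slot, par in ((0, ped.sire_idx[i]), (1, ped.dam_idx[i])):
                child = hap[i, slot]
                assert (np.array_equal(child, hap[par, 0])
                        or np.array_equal(child, hap[par, 1]))

    def test_mendelian_consistency_everywhere(self, drop_setup):
        ped, g, pool = drop_setup
        sim = gene_drop(ped, pool, g.gmap, GeneDropConfig(), seed=2)
        hap = sim.haplotypes
        for i in np.nonzero((ped.sire_idx >= 0) & (ped.dam_idx >= 0))[0]:
            for slot, par in ((0, ped.sire_idx[i]), (1, ped.dam_idx[i])):
                child = hap[i, slot]
                assert np.all((child == hap[par, 0]) | (child == hap[par, 1]))

    def test_no_missing_genotypes(self, drop_setup):
        ped, g, pool = drop_setup
        sim = gene_drop(ped, pool, g.gmap, GeneDropConfig(), seed=3)
        assert np.all(sim.genotypes >= 0) and np.all(sim.genotypes <= 2)

    def test_allele_frequency_conserved_in_expectation(self, drop_setup):
        """Drift conserves the expected allele frequency: the mean final-
        cohort frequency over replicate drops matches the founder pool."""
        ped, g, pool = drop_setup
        j = int(np.argmin(np.abs(pool.mean(axis=0) - 0.3)))
        p0 = pool[:, j].mean()
        last = ped.birth_year >= ped.birth_year.max() - 1
        freqs = []
        for s in range(150):
            sim = gene_drop(ped, pool, g.gmap, GeneDropConfig(), seed=100 + s)
            freqs.append(sim.genotypes[last, j].mean() / 2)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - p0) <= 3 * se + 0.005

    def test_empty_founder_pool_raises(self, drop_setup):
        ped, g, pool = drop_setup
        with pytest.raises(DriftError):
            gene_drop(ped, np.empty((0, g.n_snps), dtype=np.int8), g.gmap,
                      GeneDropConfig(), seed=1)

    def test_missing_parent_uses_same_sex_earlier_donor(self):
        """An individual without parents born after the cutoff gets donor
        haplotypes rather than pool haplotypes."""
        rows = []
        for k in range(10):
            rows.append((f"f{k}", "0", "0", "M" if k % 2 else "F", 1985))
        rows.append(("x", "0", "0", "M", 1996))   # orphan after cutoff
        ped = Pedigree(pd.DataFrame(
            rows, columns=["id", "sire", "dam", "sex", "birth_year"]))
        gmap = default_genetic_map(20, 1, 0.0)
        pool, _ = simulate_founder_haplotypes(10, gmap, seed=1)
        sim = gene_drop(ped, pool, gmap, GeneDropConfig(), seed=4)
        hap = sim.haplotypes
        x = list(ped.ids).index("x")
        for slot, want in ((0, "M"), (1, "F")):
            donors = [k for k in range(10) if ped.sex[k] == want]
            assert any(
                np.array_equal(hap[x, slot], hap[d, h])
                for d in donors for h in (0, 1)
            )


class TestDriftNullGenomic:
    def test_zero_effects_give_zero_slopes(self, drop_setup, small_study_pipeline):
        ped, g, pool = drop_setup
        chain = small_study_pipeline["fit"].chain
        import dataclasses

        zero_chain = dataclasses.replace(
            chain, beta=np.zeros_like(chain.beta),
            classes=np.zeros_like(chain.classes),
        )
        null = drift_null_genomic(ped, pool, g.gmap, zero_chain,
                                  GeneDropConfig(seed=5), None, 5, ids=g.ids)
        assert np.all(null == 0.0)

    def test_neutral_null_mean_near_zero(self, drop_setup, small_study_pipeline):
        ped, g, pool = drop_setup
        chain = small_study_pipeline["fit"].chain
        null = drift_null_genomic(ped, pool, g.gmap, chain,
                                  GeneDropConfig(seed=6), None, 5, ids=g.ids)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 4 * se + 0.002

    def test_fewer_founders_give_wider_null(self):
        """Stronger drift (fewer founders) widens the null slope spread."""
        from microevo import ArchitectureSpec, StudyConfig, simulate_study
        from microevo.pipeline import analyse_study

        spreads = []
        for nf, cap in ((120, 300), (16, 300)):
            study = simulate_study(StudyConfig(
                n_founders=nf, n_years=12, max_population=cap, seed=17,
                architecture=ArchitectureSpec(n_snps=150),
                mean_offspring_per_female_per_year=1.3 if nf == 16 else 1.0,
            ))
            res = analyse_study(study, min_cohort_size=5, n_samples=60,
                                seed=17, drift=True)
            spreads.append(res["null_slopes"].std(ddof=1))
        assert spreads[1] > spreads[0]


class TestDriftNullPedigree:
    def test_zero_variance_gives_zero_slopes(self, drop_setup):
        ped, g, _ = drop_setup
        null = drift_null_pedigree(ped, np.zeros(20), seed=1,
                                   min_cohort_size=5, ids=g.ids)
        assert np.all(null == 0.0)

    def test_negative_variance_raises(self, drop_setup):
        ped, _, _ = drop_setup
        with pytest.raises(DriftError):
            drift_null_pedigree(ped, np.array([-1.0]), seed=1)

    def test_cohort_variance_grows_with_depth(self):
        """Drift accumulates: cohort-mean BV variance over replicates grows
        down the pedigree."""
        ped = simulate_pedigree(n_founders=40, n_years=12, seed=8,
                                max_population=150, first_cohort_year=2000)
        reps = 400
        by = ped.birth_year
        years = np.arange(2000, 2012)
        from microevo.simulate import simulate_breeding_values

        cohort_means = np.zeros((reps, len(years)))
        for r in range(reps):
            bv = simulate_breeding_values(ped, 1.0, seed=r).to_numpy()
            for k, y in enumerate(years):
                cohort_means[r, k] = bv[by == y].mean()
        var_by_year = cohort_means.var(axis=0)
        early = var_by_year[:4].mean()
        late = var_by_year[-4:].mean()
        assert late > early

    def test_null_sd_scales_with_sigma(self, drop_setup):
        ped, g, _ = drop_setup
        n1 = drift_null_pedigree(ped, np.full(100, 1.0), seed=2,
                                 min_cohort_size=5, ids=g.ids)
        n4 = drift_null_pedigree(ped, np.full(100, 4.0), seed=2,
                                 min_cohort_size=5, ids=g.ids)
        assert n4.std() == pytest.approx(2 * n1.std(), rel=0.05)


class TestPDrift:
    def make_trend(self, slopes):
        slopes = np.asarray(slopes, dtype=float)
        return TrendPosterior(slopes=slopes, years=np.array([0, 1]),
                              cohort_sizes=np.array([1, 1]),
                              cohort_mean_values=np.zeros((2, len(slopes))))

    def test_null_always_below_real_gives_zero(self):
        dr = p_drift(self.make_trend([1.0, 2.0]), np.array([0.0, 0.5]))
        assert dr.p_drift == 0.0

    def test_ties_count_against_rejection(self):
        dr = p_drift(self.make_trend([1.0, 2.0]), np.array([1.0, 2.0]))
        assert dr.p_drift == 0.0

    def test_four_pair_worked_example(self):
        dr = p_drift(self.make_trend([1, 2, 3, 4]), np.array([2, 1, 4, 3]))
        assert dr.p_drift == 0.5
        assert np.allclose(dr.differences, [-1, 1, -1, 1])

    def test_count_mismatch_raises(self):
        with pytest.raises(DriftError):
            p_drift(self.make_trend([1, 2]), np.array([1.0]))


class TestConsistencyWithPredict:
    def test_gene_drop_gebvs_equal_predict_on_simulated_set(
            self, drop_setup, small_study_pipeline):
        """The drift pipeline's genotype-to-GEBV conversion is the same code
        path as predict(): applying predict to a gene-dropped GenotypeSet
        reproduces the null computation."""
        ped, g, pool = drop_setup
        fit = small_study_pipeline["fit"]
        sim = gene_drop(ped, pool, g.gmap, GeneDropConfig(), seed=9)
        pred = fit.predict(sim)
        W = sim.genotypes.astype(float) - 2.0 * fit.chain.freqs
        assert np.allclose(pred.values, W @ fit.chain.beta.T)
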