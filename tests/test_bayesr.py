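import numpy as np
import pandas as pd
import pytest

from microevo import (
    BayesRModel,
    EbvPosterior,
    GenotypeSet,
    McmcSettings,
    MixturePrior,
    cv_accuracy,
    leave_one_cohort_out,
)
from microevo.bayesr import BayesRError
from conftest import make_iid_genotypes

FAST = McmcSettings(n_iter=1200, burn_in=400, n_samples=80, seed=1)


def phenos(g, y):
    return pd.DataFrame({"id": g.ids, "value": y})


class TestSettingsAndPriors:
    def test_settings_arithmetic(self):
        s = McmcSettings(n_iter=120_000, burn_in=20_000, n_samples=1000)
        kept = s.kept_iterations()
        assert len(kept) == 1000
        assert kept[0] >= 20_000 and kept[-1] == 119_999
        assert len(np.unique(np.diff(kept))) == 1   # evenly spaced

    def test_invalid_settings_raise(self):
        with pytest.raises(BayesRError):
            McmcSettings(n_iter=100, burn_in=100)
        with pytest.raises(BayesRError):
            McmcSettings(n_iter=100, burn_in=50, n_samples=100)

    def test_prior_validation(self):
        with pytest.raises(BayesRError):
            MixturePrior(variance_fractions=(0.0, 1e-3, 1e-4, 1e-2))
        with pytest.raises(BayesRError):
            MixturePrior(variance_fractions=(1e-5, 1e-4, 1e-3, 1e-2))
        with pytest.raises(BayesRError):
            MixturePrior(reference="other")

    def test_degenerate_phenotype_raises(self):
        g = make_iid_genotypes(20, 10)
        with pytest.raises(BayesRError, match="degenerate"):
            BayesRModel(phenos(g, np.ones(20)), g)


class TestSampler:
    def test_single_large_effect_matches_ridge_oracle(self):
        """Posterior mean effect of one SNP explaining ~50% of variance lies
        within 2 posterior SD of the conjugate ridge estimate."""
        rng = np.random.default_rng(3)
        g = make_iid_genotypes(500, 50, seed=3, maf=(0.3, 0.7))
        W = g.centered_matrix()
        j = 7
        y = W[:, j] + rng.normal(0, W[:, j].std(), 500)
        fit = BayesRModel(phenos(g, y), g).fit(
            McmcSettings(n_iter=3000, burn_in=1000, n_samples=200, seed=2)
        )
        bhat = fit.chain.beta[:, j]
        # ridge/BLUP oracle with the largest component's prior variance
        v = 0.01 * np.var(y, ddof=1)
        yc = y - y.mean()
        ridge = (W[:, j] @ yc) / (W[:, j] @ W[:, j] + np.var(yc) * (1 - 0.5) / v)
        assert abs(bhat.mean() - ridge) <= 2 * bhat.std()

    def test_null_component_effects_exactly_zero(self, small_study_pipeline):
        chain = small_study_pipeline["fit"].chain
        assert np.all(chain.beta[chain.classes == 0] == 0.0)
        nz = (chain.classes != 0).sum(axis=1)
        assert np.array_equal(nz, (chain.beta != 0).sum(axis=1))

    def test_pure_noise_concentrates_in_null_class(self):
        rng = np.random.default_rng(4)
        g = make_iid_genotypes(500, 200, seed=4, maf=(0.1, 0.9))
        fit = BayesRModel(phenos(g, rng.normal(0, 1, 500)), g).fit(
            McmcSettings(n_iter=2000, burn_in=1000, n_samples=100, seed=5)
        )
        null_frac = (fit.chain.classes == 0).mean()
        assert null_frac > 0.5
        # genomic variance explained ~ 0
        gebv = fit.predict().values.mean(axis=1)
        assert np.var(gebv) < 0.05

    def test_snp_order_permutation_invariance(self):
        rng = np.random.default_rng(6)
        g = make_iid_genotypes(300, 60, seed=6)
        W = g.centered_matrix()
        beta = np.zeros(60)
        beta[[3, 30]] = [0.4, -0.4]
        y = W @ beta + rng.normal(0, 1, 300)
        perm = rng.permutation(60)
        g_perm = GenotypeSet(
            ids=g.ids, snp_ids=g.snp_ids[perm],
            counted_allele=np.asarray(g.counted_allele)[perm],
            other_allele=np.asarray(g.other_allele)[perm],
            genotypes=g.genotypes[:, perm],
        )
        s = McmcSettings(n_iter=2500, burn_in=500, n_samples=200, seed=7)
        m1 = BayesRModel(phenos(g, y), g).fit(s).predict().values.mean(axis=1)
        m2 = BayesRModel(phenos(g_perm, y), g_perm).fit(s).predict().values.mean(axis=1)
        assert np.corrcoef(m1, m2)[0, 1] > 0.95
        assert np.abs(m1 - m2).mean() < 0.2

    def test_forced_null_component_gives_zero_gebvs(self):
        rng = np.random.default_rng(8)
        g = make_iid_genotypes(100, 30, seed=8)
        prior = MixturePrior(dirichlet=(1e12, 1e-9, 1e-9, 1e-9))
        fit = BayesRModel(phenos(g, rng.normal(0, 1, 100)), g, prior).fit(FAST)
        assert np.all(fit.predict().values == 0.0)


class TestPrediction:
    def test_hand_worked_matrix_product(self):
        """3 individuals x 2 SNPs against a hand computation."""
        g = GenotypeSet(
            ids=["a", "b", "c"], snp_ids=["s1", "s2"],
            counted_allele=["B", "B"], other_allele=["A", "A"],
            genotypes=np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8),
        )
        from microevo.bayesr import PosteriorChain

        chain = PosteriorChain(
            snp_ids=np.array(["s1", "s2"]),
            beta=np.array([[0.5, -1.0], [0.0, 0.0]]),
            classes=np.array([[3, 3], [0, 0]], dtype=np.int8),
            sigma2_g=np.ones(2), sigma2_e=np.ones(2),
            pi=np.full((2, 4), 0.25), mu=np.zeros(2),
            freqs=np.array([0.5, 0.5]),
        )
        model = BayesRModel.__new__(BayesRModel)
        model.genotypes = g
        model.train_ids = np.array(["a"])
        from microevo.bayesr import BayesRResults

        res = BayesRResults(model=model, chain=chain, settings=FAST)
        ebv = res.predict(g)
        # centred dosages: [[-1,0],[0,1],[1,-1]]
        expected = np.array([[-0.5, 0.0], [-1.0, 0.0], [1.5, 0.0]])
        assert np.allclose(ebv.values, expected)
        # single copy at p=0.5 with effect b contributes exactly b ... (2-1)b
        assert ebv.values[2, 0] - ebv.values[0, 0] == pytest.approx(2 * 0.5 + 1.0)

    def test_unknown_id_raises(self, small_study_pipeline):
        with pytest.raises(Exception, match="not genotyped"):
            small_study_pipeline["fit"].predict(ids=["nope"])


class TestLeaveOneCohortOut:
    def make_data(self, seed=0, n=120, m=40, n_cohorts=3):
        rng = np.random.default_rng(seed)
        g = make_iid_genotypes(n, m, seed=seed)
        years = np.repeat(np.arange(2000, 2000 + n_cohorts), n // n_cohorts)[:n]
        y = g.centered_matrix() @ rng.normal(0, 0.2, m) + rng.normal(0, 1, n)
        cohorts = pd.Series(years, index=g.ids)
        return g, phenos(g, y), cohorts

    def test_two_cohorts_each_predicted_from_other(self):
        g, ph, cohorts = self.make_data(n_cohorts=2)
        ebv = leave_one_cohort_out(ph, g, cohorts, settings=FAST)
        assert ebv.n_samples == FAST.n_samples
        assert set(ebv.ids) == set(g.ids)

    def test_focal_phenotype_perturbation_leaves_own_gebv_unchanged(self):
        g, ph, cohorts = self.make_data()
        ebv1 = leave_one_cohort_out(ph, g, cohorts, settings=FAST)
        ph2 = ph.copy()
        focal = ph2.index[0]
        fid = ph2.loc[focal, "id"]
        ph2.loc[focal, "value"] += 10.0
        ebv2 = leave_one_cohort_out(ph2, g, cohorts, settings=FAST)
        k = list(ebv1.ids).index(fid)
        assert np.allclose(ebv1.values[k], ebv2.values[k])

    def test_single_cohort_raises(self):
        g, ph, cohorts = self.make_data(n_cohorts=1)
        with pytest.raises(BayesRError, match="two phenotyped cohorts"):
            leave_one_cohort_out(ph, g, cohorts, settings=FAST)


class TestCvAccuracy:
    def test_noise_free_dense_signal_gives_high_accuracy(self):
        rng = np.random.default_rng(9)
        g = make_iid_genotypes(600, 60, seed=9, maf=(0.2, 0.8))
        beta = rng.normal(0, 0.3, 60)
        y = g.centered_matrix() @ beta        # phenotype == genetic value
        acc = cv_accuracy(phenos(g, y), g, k_folds=2,
                          settings=McmcSettings(n_iter=2000, burn_in=500,
                                                n_samples=100, seed=10), seed=1)
        assert acc > 0.8

    def test_pure_noise_accuracy_near_zero(self):
        rng = np.random.default_rng(10)
        g = make_iid_genotypes(300, 80, seed=10)
        acc = cv_accuracy(phenos(g, rng.normal(0, 1, 300)), g, k_folds=2,
                          settings=FAST, seed=2)
        assert abs(acc) < 0.25

    def test_accuracy_matches_effective_segment_formula(self):
        """Independent SNPs, infinitesimal truth: predicted accuracy is
        sqrt(n h2 / (n h2 + m_e)) with m_e = the SNP count (every SNP its
        own segment); mean over replicates within 0.1 of the formula."""
        n, m, h2 = 800, 400, 0.25
        accs = []
        for seed in range(4):
            rng = np.random.default_rng(300 + seed)
            g = make_iid_genotypes(n, m, seed=400 + seed, maf=(0.2, 0.8))
            gval = g.centered_matrix() @ rng.normal(0, 1, m)
            gval *= np.sqrt(h2 / np.var(gval))
            y = gval + rng.normal(0, np.sqrt(1 - h2), n)
            accs.append(cv_accuracy(
                phenos(g, y), g, k_folds=2,
                settings=McmcSettings(n_iter=6000, burn_in=2000,
                                      n_samples=100, seed=seed), seed=seed))
        n_train = n / 2
        expected = np.sqrt(n_train * h2 / (n_train * h2 + m))
        # cv_accuracy correlates GEBVs with held-out *phenotypes*, which is
        # the accuracy on the true-genetic-value scale times sqrt(h2)
        assert np.mean(accs) / np.sqrt(h2) == pytest.approx(expected, abs=0.1)
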