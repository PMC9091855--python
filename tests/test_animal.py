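import numpy as np
import pandas as pd
import pytest

from microevo import (
    AnimalMcmcSettings,
    AnimalModel,
    simulate_breeding_values,
    simulate_pedigree,
)
from microevo.animal import AnimalModelError

FAST = AnimalMcmcSettings(n_iter=4000, burn_in=1500, n_samples=100, seed=3)


def make_records(ped, bv, seed, s2_pe=1.0, s2_by=0.5, s2_cy=0.5, s2_e=5.0,
                 n_years=6, first_year=2012, p_measured=0.6, mu=24.0):
    """Records from the animal model's own generating process."""
    rng = np.random.default_rng(seed)
    pe = rng.normal(0, np.sqrt(s2_pe), ped.n)
    years = np.arange(first_year, first_year + n_years)
    u_cy = dict(zip(years, rng.normal(0, np.sqrt(s2_cy), n_years)))
    byl = np.unique(ped.birth_year)
    u_by = dict(zip(byl, rng.normal(0, np.sqrt(s2_by), len(byl))))
    rows = []
    for y in years:
        idx = np.nonzero(ped.birth_year <= y - 3)[0]
        keep = idx[rng.random(len(idx)) < p_measured]
        age = 12 * (y - ped.birth_year[keep]) + 4
        w = (mu + np.where(ped.sex[keep] == "M", 3.0, 0.0) + bv[keep] + pe[keep]
             + np.array([u_by[b] for b in ped.birth_year[keep]]) + u_cy[y]
             + rng.normal(0, np.sqrt(s2_e), len(keep)))
        for k, i in enumerate(keep):
            rows.append((ped.ids[i], w[k], int(age[k]), int(y), 8, ped.sex[i]))
    return pd.DataFrame(rows, columns=["id", "weight", "capture_age",
                                       "capture_year", "capture_month", "sex"])


@pytest.fixture(scope="module")
def medium_ped():
    return simulate_pedigree(n_founders=60, n_years=10, seed=5, max_population=220,
                             first_cohort_year=2005)


class TestFitBasics:
    def test_unknown_phenotyped_id_raises(self, medium_ped):
        rec = pd.DataFrame({
            "id": ["ghost"], "weight": [20.0], "capture_age": [40],
            "capture_year": [2012], "capture_month": [8], "sex": ["F"],
        })
        with pytest.raises(AnimalModelError, match="not in pedigree"):
            AnimalModel(rec, medium_ped)

    def test_no_signal_posterior_h2_near_zero(self, medium_ped):
        bv = np.zeros(medium_ped.n)
        rec = make_records(medium_ped, bv, seed=1, s2_e=6.0)
        res = AnimalModel(rec, medium_ped).fit(FAST)
        assert res.chain.heritability().mean() < 0.08

    def test_identical_full_sibs_get_equal_ebvs(self):
        """Duplicated full sibs with identical records have exchangeable
        posteriors: posterior-mean EBVs agree within Monte-Carlo error."""
        rows = [("s", "0", "0", "M", 2000), ("d", "0", "0", "F", 2000)]
        for k in range(2):
            rows.append((f"t{k}", "s", "d", "F", 2002))
        for k in range(30):   # unrelated background individuals
            rows.append((f"u{k}", "0", "0", "F" if k % 2 else "M", 2002))
        from microevo import Pedigree

        ped = Pedigree(pd.DataFrame(
            rows, columns=["id", "sire", "dam", "sex", "birth_year"]))
        rng = np.random.default_rng(0)
        rec_rows = []
        for i in ped.ids:
            if i.startswith("t"):
                w = 27.0
            elif i.startswith("u"):
                w = float(24 + rng.normal(0, 2))
            else:
                continue
            for y in (2005, 2006):
                rec_rows.append((i, w, 12 * (y - 2002) + 4, y, 8,
                                 ped.sex[list(ped.ids).index(i)]))
        rec = pd.DataFrame(rec_rows, columns=["id", "weight", "capture_age",
                                              "capture_year", "capture_month", "sex"])
        res = AnimalModel(rec, ped).fit(
            AnimalMcmcSettings(n_iter=12000, burn_in=2000, n_samples=500, seed=1))
        ebv = res.ebv(["t0", "t1"])
        m = ebv.values.mean(axis=1)
        mc_se = ebv.values.std(axis=1).max() / np.sqrt(100)   # conservative ESS
        assert abs(m[0] - m[1]) < 4 * mc_se + 0.05


class TestPosteriorStructure:
    def test_unphenotyped_founder_ebvs_shrink_toward_zero(self, medium_ped):
        bv = simulate_breeding_values(medium_ped, 3.0, seed=2).to_numpy()
        rec = make_records(medium_ped, bv, seed=3)
        res = AnimalModel(rec, medium_ped).fit(FAST)
        phen = set(rec["id"])
        no_rec_founders = [
            i for k, i in enumerate(medium_ped.ids)
            if medium_ped.is_founder[k] and i not in phen
        ]
        if no_rec_founders:
            ebv = res.ebv(no_rec_founders).posterior_mean()
            assert np.abs(ebv).mean() < np.sqrt(3.0)

    def test_offspring_ebv_tracks_midparent(self, medium_ped):
        bv = simulate_breeding_values(medium_ped, 3.0, seed=4).to_numpy()
        rec = make_records(medium_ped, bv, seed=5)
        res = AnimalModel(rec, medium_ped).fit(FAST)
        pm = res.ebv().posterior_mean()
        both = (medium_ped.sire_idx >= 0) & (medium_ped.dam_idx >= 0)
        unphen = both & ~pd.Series(medium_ped.ids).isin(set(rec["id"])).to_numpy()
        target = unphen if unphen.sum() >= 20 else both
        kid = pm.to_numpy()[target]
        mid = 0.5 * (pm.to_numpy()[medium_ped.sire_idx[target]]
                     + pm.to_numpy()[medium_ped.dam_idx[target]])
        slope = np.polyfit(mid, kid, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.35)

    def test_chain_arithmetic(self):
        s = AnimalMcmcSettings(n_iter=600_000, burn_in=100_000, n_samples=1000)
        kept = s.kept_iterations()
        assert len(kept) == 1000
        assert kept[-1] == 599_999
        assert np.all(np.diff(kept) == 500)   # 500000 / 1000 exactly


class TestSamplerCrossCheck:
    def test_single_site_and_block_agree(self):
        """The two location samplers target the same posterior: posterior
        means agree within Monte-Carlo error on a small dataset."""
        ped = simulate_pedigree(n_founders=30, n_years=6, seed=7,
                                max_population=90, first_cohort_year=2005)
        bv = simulate_breeding_values(ped, 3.0, seed=8).to_numpy()
        rec = make_records(ped, bv, seed=9, n_years=4)
        model = AnimalModel(rec, ped)
        s1 = AnimalMcmcSettings(n_iter=12000, burn_in=4000, n_samples=400,
                                seed=10, location_sampler="single_site")
        s2 = AnimalMcmcSettings(n_iter=6000, burn_in=2000, n_samples=400,
                                seed=11, location_sampler="block")
        r1 = model.fit(s1)
        r2 = model.fit(s2)
        h1 = r1.chain.heritability()
        h2 = r2.chain.heritability()
        se = np.sqrt(h1.var() / 50 + h2.var() / 50)
        assert abs(h1.mean() - h2.mean()) < 5 * se + 0.03
        e1 = r1.ebv().posterior_mean()
        e2 = r2.ebv().posterior_mean()
        assert np.corrcoef(e1, e2)[0, 1] > 0.95


class TestRecovery:
    def test_h2_recovered_with_honest_interval(self):
        """h2 = 0.3 design: truth inside the 95% credible interval."""
        hits = 0
        for rep in range(3):
            ped = simulate_pedigree(n_founders=150, n_years=12, seed=rep,
                                    max_population=450, first_cohort_year=2005)
            bv = simulate_breeding_values(ped, 3.0, seed=100 + rep).to_numpy()
            rec = make_records(ped, bv, seed=200 + rep)
            res = AnimalModel(rec, ped).fit(
                AnimalMcmcSettings(n_iter=8000, burn_in=3000, n_samples=100,
                                   seed=rep))
            lo, hi = np.percentile(res.chain.heritability(), [2.5, 97.5])
            hits += lo <= 0.3 <= hi
        assert hits >= 2
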