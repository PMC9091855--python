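import numpy as np
import pandas as pd
import pytest

from microevo import (
    ArchitectureSpec,
    GenotypeSet,
    Pedigree,
    StudyConfig,
    simulate_study,
)


@pytest.fixture
def trio_df():
    return pd.DataFrame({
        "id": ["s1", "d1", "c1"],
        "sire": ["0", "0", "s1"],
        "dam": ["0", "0", "d1"],
        "sex": ["M", "F", "F"],
        "birth_year": [2000, 2000, 2003],
    })


@pytest.fixture
def trio_ped(trio_df):
    return Pedigree(trio_df)


def make_iid_genotypes(n, m, seed=0, maf=(0.1, 0.5)):
    """Independent binomial genotypes (no LD), handy for sampler tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, m)
    G = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return GenotypeSet(
        ids=np.array([f"i{i:04d}" for i in range(n)]),
        snp_ids=np.array([f"s{j:04d}" for j in range(m)]),
        counted_allele=np.array(["B"] * m),
        other_allele=np.array(["A"] * m),
        genotypes=G,
    )


@pytest.fixture(scope="session")
def small_study():
    """One compact neutral synthetic study shared across unit tests."""
    cfg = StudyConfig(
        n_founders=50, n_years=10, max_population=160,
        architecture=ArchitectureSpec(n_snps=200), seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_pipeline(small_study):
    """Adjusted phenotypes + a short genomic chain for the shared study."""
    from microevo import BayesRModel, McmcSettings, RepeatabilityModel
    from microevo.phenotypes import filter_phenotypes

    kept = filter_phenotypes(small_study.records)
    adj = RepeatabilityModel(kept).fit(compute_se=False)
    fit = BayesRModel(adj.adjusted[["id", "value"]], small_study.genotypes).fit(
        McmcSettings(n_iter=1200, burn_in=400, n_samples=80, seed=7)
    )
    ped = small_study.pedigree
    gebv = fit.predict(
        birth_years=ped.birth_year[ped.index_of(small_study.genotypes.ids)]
    )
    return {"records": kept, "adjusted": adj, "fit": fit, "gebv": gebv}
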