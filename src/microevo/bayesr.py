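"""Genomic prediction with a four-component normal-mixture (BayesR-style) Gibbs sampler.

The model for the adjusted phenotype y_i of a training individual is

    y_i = mu + sum_j w_ij beta_j + e_i,     w_ij = g_ij - 2 p_j,

with each SNP effect beta_j drawn from a mixture of a point mass at zero and
three normal components whose variances are fixed fractions (1e-4, 1e-3,
1e-2 by default) of a reference variance.  The mixture proportions get a
Dirichlet prior; genetic and residual variances get scaled-inverse-chi-squared
priors.  Posterior GEBVs are linear in the sampled effects, so the retained
chain yields a full posterior over every individual's breeding value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernels import bayesr_gibbs
from .ebv import EbvPosterior
from .genotypes import GenotypeSet

logger = logging.getLogger(__name__)


class BayesRError(ValueError):
    pass


@dataclass(frozen=True)
class MixturePrior:
    """Prior settings of the mixture model.

    ``variance_fractions`` are the component variances as fractions of the
    reference variance; ``reference`` selects whether that reference is the
    (fixed) phenotypic variance of the training phenotypes or the current
    genetic variance of the chain.  ``dirichlet`` pseudo-counts are aligned
    with the ascending variance fractions; the default places the large
    pseudo-count (5) on the zero-effect class, the conservative prior that
    pulls assignments toward the null component.
    """

    variance_fractions: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    dirichlet: tuple = (5.0, 1.0, 1.0, 1.0)
    genetic_scale: float = 1.2
    genetic_df: float = 10.0
    residual_scale: float = 2.5
    residual_df: float = 10.0
    reference: str = "phenotypic"

    def __post_init__(self):
        if list(self.variance_fractions) != sorted(self.variance_fractions):
            raise BayesRError("variance fractions must ascend from zero")
        if self.variance_fractions[0] != 0.0:
            raise BayesRError("first mixture component must have zero variance")
        if any(a <= 0 for a in self.dirichlet):
            raise BayesRError("Dirichlet pseudo-counts must be positive")
        if self.reference not in ("phenotypic", "genetic"):
            raise BayesRError("reference must be 'phenotypic' or 'genetic'")


@dataclass(frozen=True)
class McmcSettings:
    """Chain settings; the retained chain is evenly subsampled post burn-in
    down to exactly ``n_samples`` draws."""

    n_iter: int = 120_000
    burn_in: int = 20_000
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise BayesRError("burn_in must be smaller than n_iter")
        if self.n_iter - self.burn_in < self.n_samples:
            raise BayesRError("post burn-in chain shorter than requested sample count")

    def kept_iterations(self) -> np.ndarray:
        post = self.n_iter - self.burn_in
        # evenly spaced, last retained iteration is the final one
        pos = np.floor(np.linspace(post / self.n_samples, post, self.n_samples)).astype(np.int64)
        return self.burn_in + pos - 1


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples of the mixture model."""

    snp_ids: np.ndarray
    beta: np.ndarray        # (S, m) SNP effects, kg per allele
    classes: np.ndarray     # (S, m) mixture component per SNP (0 = null)
    sigma2_g: np.ndarray    # (S,)
    sigma2_e: np.ndarray    # (S,)
    pi: np.ndarray          # (S, 4)
    mu: np.ndarray          # (S,)
    freqs: np.ndarray       # (m,) training allele frequencies used for centring

    def __post_init__(self):
        if not (np.isfinite(self.beta).all() and np.isfinite(self.sigma2_e).all()):
            bad = np.nonzero(~np.isfinite(self.beta).all(axis=1))[0]
            raise BayesRError(f"chain diverged (non-finite draw at stored sample {bad[:1]})")
        if (self.beta[self.classes == 0] != 0.0).any():
            raise BayesRError("null-component effects must be exactly zero")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.snp_ids)
        df.insert(0, "mu", self.mu)
        df.insert(0, "sigma2_e", self.sigma2_e)
        df.insert(0, "sigma2_g", self.sigma2_g)
        for k in range(self.pi.shape[1] - 1, -1, -1):
            df.insert(0, f"pi{k}", self.pi[:, k])
        df.insert(0, "sample", np.arange(self.n_samples))
        return df

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#freqs\t" + "\t".join(f"{p:.8g}" for p in self.freqs) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


class BayesRModel:
    """Mixture-model genomic prediction, statsmodels-style.

    Parameters
    ----------
    phenotypes : DataFrame with columns id, value (the adjusted phenotypes of
        the training individuals), or a Series indexed by id.
    genotypes : GenotypeSet covering at least the training individuals.
    prior : MixturePrior, optional.
    """

    def __init__(self, phenotypes, genotypes: GenotypeSet, prior: MixturePrior | None = None):
        if isinstance(phenotypes, pd.Series):
            phenotypes = phenotypes.rename("value").rename_axis("id").reset_index()
        phenotypes = phenotypes[["id", "value"]].copy()
        phenotypes["id"] = phenotypes["id"].astype(str)
        if phenotypes["id"].duplicated().any():
            raise BayesRError("one adjusted phenotype per individual expected")
        self.prior = prior or MixturePrior()
        self.genotypes = genotypes
        self.train_ids = phenotypes["id"].to_numpy()
        self.y = phenotypes["value"].to_numpy(dtype=float)
        if len(self.y) < 2 or np.var(self.y) == 0.0:
            raise BayesRError("degenerate training phenotype (zero variance)")
        train_set = genotypes.select_ids(self.train_ids)
        self.freqs = train_set.allele_frequencies()
        self._W_train = train_set.centered_matrix(self.freqs)

    def fit(self, settings: McmcSettings | None = None) -> "BayesRResults":
        settings = settings or McmcSettings()
        prior = self.prior
        ref_mode = 1 if prior.reference == "genetic" else 0
        ref_fixed = float(np.var(self.y, ddof=1))
        keep = settings.kept_iterations()
        beta, classes, s2g, s2e, pi, mu = bayesr_gibbs(
            np.ascontiguousarray(self._W_train.T),
            self.y,
            np.array(prior.variance_fractions, dtype=float),
            np.array(prior.dirichlet, dtype=float),
            ref_mode,
            ref_fixed,
            prior.genetic_scale, prior.genetic_df,
            prior.residual_scale, prior.residual_df,
            settings.n_iter,
            keep,
            int(settings.seed) % (2**31),
        )
        chain = PosteriorChain(
            snp_ids=self.genotypes.snp_ids.copy(), beta=beta, classes=classes,
            sigma2_g=s2g, sigma2_e=s2e, pi=pi, mu=mu, freqs=self.freqs,
        )
        logger.info(
            "BayesR chain: %d retained samples, mean null-class fraction %.3f",
            chain.n_samples, float((classes == 0).mean()),
        )
        return BayesRResults(model=self, chain=chain, settings=settings)


@dataclass
class BayesRResults:
    """Posterior chain plus prediction methods."""

    model: BayesRModel
    chain: PosteriorChain
    settings: McmcSettings

    def predict(self, genotypes: GenotypeSet | None = None, ids=None,
                birth_years=None, is_training=None) -> EbvPosterior:
        """Posterior GEBVs: value[i, s] = sum_j (g_ij - 2 p_j) beta_j^(s).

        Centring frequencies are always those of the training set.
        """
        g = genotypes if genotypes is not None else self.model.genotypes
        if ids is not None:
            g = g.select_ids(ids)
        W = g.centered_matrix(self.chain.freqs)
        values = W @ self.chain.beta.T
        if birth_years is None:
            birth_years = np.zeros(len(g.ids), dtype=np.int64)
        else:
            birth_years = np.asarray(birth_years, dtype=np.int64)
        train = set(self.model.train_ids)
        if is_training is None:
            is_training = np.array([i in train for i in g.ids])
        return EbvPosterior(ids=g.ids, birth_year=birth_years, values=values,
                            provenance="genomic", is_training=is_training)

    def summary(self) -> str:
        c = self.chain
        lines = [
            "BayesR mixture model results",
            "=" * 46,
            f"training individuals:   {len(self.model.y)}",
            f"SNPs:                   {len(c.snp_ids)}",
            f"retained samples:       {c.n_samples}",
            f"posterior mean sigma2_g:{c.sigma2_g.mean():10.4f}",
            f"posterior mean sigma2_e:{c.sigma2_e.mean():10.4f}",
            f"mean mixture proportions: "
            + ", ".join(f"{v:.4f}" for v in c.pi.mean(axis=0)),
            f"mean non-null SNPs per sample: {(c.classes != 0).sum(axis=1).mean():.1f}",
        ]
        return "\n".join(lines)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic sub-seeds below 2^31."""
    ss = np.random.SeedSequence(int(seed))
    return np.array([int(s) % (2**31) for s in ss.generate_state(n)], dtype=np.int64)


def leave_one_cohort_out(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeSet,
    cohorts: pd.Series,
    prior: MixturePrior | None = None,
    settings: McmcSettings | None = None,
) -> EbvPosterior:
    """Leave-one-cohort-out GEBVs.

    For every cohort (birth year) among the genotyped individuals, the model
    is refitted excluding all phenotypes of that cohort, and the cohort's
    GEBVs are taken from that fit, so no individual's GEBV uses its own or
    its cohort-mates' phenotypes.

    Parameters
    ----------
    cohorts : Series mapping individual id -> birth year, covering all
        genotyped individuals.
    """
    settings = settings or McmcSettings()
    cohorts = cohorts.copy()
    cohorts.index = cohorts.index.astype(str)
    ids = genotypes.ids
    years = cohorts.reindex(ids)
    if years.isna().any():
        raise BayesRError("every genotyped individual needs a cohort year")
    years = years.astype(int).to_numpy()
    pheno_years = set(
        cohorts.reindex(phenotypes["id"].astype(str)).astype(int).tolist()
    )
    unique_years = np.unique(years)
    if len(set(unique_years) & pheno_years) < 2:
        raise BayesRError("leave-one-cohort-out needs at least two phenotyped cohorts")

    seeds = _spawn_seeds(settings.seed, len(unique_years))
    values = np.zeros((len(ids), settings.n_samples))
    full_fit = None
    for k, year in enumerate(unique_years):
        test_mask = years == year
        train = phenotypes.loc[
            cohorts.reindex(phenotypes["id"].astype(str)).astype(int).to_numpy() != year
        ]
        if train.empty:
            raise BayesRError("training set empty after excluding a cohort")
        if len(train) == len(phenotypes):
            if full_fit is None:
                full_fit = BayesRModel(phenotypes, genotypes, prior).fit(
                    replace(settings, seed=int(seeds[k]))
                )
            fit = full_fit
        else:
            fit = BayesRModel(train, genotypes, prior).fit(
                replace(settings, seed=int(seeds[k]))
            )
        pred = fit.predict(genotypes, ids=ids[test_mask])
        values[test_mask] = pred.values
    train_ids = set(phenotypes["id"].astype(str))
    return EbvPosterior(
        ids=ids, birth_year=years, values=values, provenance="genomic",
        is_training=np.array([i in train_ids for i in ids]),
    )


def cv_accuracy(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeSet,
    k_folds: int = 5,
    prior: MixturePrior | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> float:
    """K-fold cross-validated prediction accuracy.

    Returns the correlation between held-out individuals' posterior-mean
    GEBVs and their adjusted phenotypes, averaged over folds.
    """
    if k_folds < 2:
        raise BayesRError("k_folds must be at least 2")
    settings = settings or McmcSettings()
    phenotypes = phenotypes[["id", "value"]].copy()
    phenotypes["id"] = phenotypes["id"].astype(str)
    rng = np.random.default_rng(seed)
    n = len(phenotypes)
    fold = rng.permutation(np.arange(n) % k_folds)
    seeds = _spawn_seeds(settings.seed + 1, k_folds)
    accs = []
    for f in range(k_folds):
        test = phenotypes.loc[fold == f]
        train = phenotypes.loc[fold != f]
        if test.empty or train.empty:
            raise BayesRError(f"fold {f} has no phenotypes")
        fit = BayesRModel(train, genotypes, prior).fit(replace(settings, seed=int(seeds[f])))
        pred = fit.predict(genotypes, ids=test["id"].to_numpy())
        gebv = pred.values.mean(axis=1)
        accs.append(float(np.corrcoef(gebv, test["value"].to_numpy(float))[0, 1]))
    return float(np.mean(accs))
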