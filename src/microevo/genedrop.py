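"""Drift nulls for breeding-value trends.

Two null-generating mechanisms, paired one-to-one with the posterior chain:

* gene dropping — founder haplotypes are dropped through the pedigree with
  recombination, simulation s converts the simulated genotypes to GEBVs with
  the SNP effects of posterior sample s, and the same weighted cohort
  regression gives a null slope d^(s);
* midparent breeding-value dropping — founders draw breeding values from
  Normal(0, sigma2_A^(s)) and descendants from Normal(midparent, sigma2_A^(s)/2),
  one sigma2_A per posterior sample of the animal model.

p_drift is the proportion of pairs whose null slope strictly exceeds the
real posterior slope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import gene_drop_kernel
from .bayesr import PosteriorChain, _spawn_seeds
from .ebv import EbvPosterior
from .genotypes import GeneticMap, GenotypeSet
from .pedigree import Pedigree
from .trend import TrendPosterior, cohort_means, weighted_slope

logger = logging.getLogger(__name__)


class DriftError(ValueError):
    pass


@dataclass(frozen=True)
class GeneDropConfig:
    """Gene-dropping rules.

    Individuals born before ``founder_year_cutoff`` are treated as founders
    and receive two haplotypes from the pool: by default a random
    *permutation* (each pool haplotype used once per pass, reshuffled if the
    pool runs out), so the simulated founder generation carries exactly the
    real founders' haplotypes and no extra resampling variance;
    ``founder_assignment="with_replacement"`` switches to independent
    draws.  A missing parent's gamete is a haplotype copied from a same-sex
    individual born ``donor_window`` years earlier (window widened
    symmetrically when empty, then the founder pool as last resort).
    """

    founder_year_cutoff: int = 1990
    donor_window: tuple = (2, 10)
    seed: int = 0
    founder_assignment: str = "permutation"

    def __post_init__(self):
        lo, hi = self.donor_window
        if hi <= lo or lo < 0:
            raise DriftError("donor window must have positive length")
        if self.founder_assignment not in ("permutation", "with_replacement"):
            raise DriftError(
                "founder_assignment must be 'permutation' or 'with_replacement'"
            )


def _donor_candidates(ped: Pedigree, cfg: GeneDropConfig):
    """Per missing-parent slot, candidate donor indices.

    Slot 2i is individual i's sire, 2i+1 its dam.  Candidates are same-sex
    individuals born within the donor window before i; an empty window is
    widened symmetrically one year at a time and, if it never fills, the
    slot falls back to the founder pool (empty candidate list).
    """
    n = ped.n
    lo, hi = cfg.donor_window
    by = ped.birth_year
    offsets = np.zeros(2 * n + 1, dtype=np.int64)
    chunks: list[np.ndarray] = []
    total = 0
    is_founder = by < cfg.founder_year_cutoff
    max_span = int(by.max() - by.min()) + 1
    for i in range(n):
        for slot, (pidx, want_sex) in enumerate(
            ((ped.sire_idx[i], "M"), (ped.dam_idx[i], "F"))
        ):
            if is_founder[i] or pidx >= 0:
                cand = np.empty(0, dtype=np.int64)
            else:
                widen = 0
                while True:
                    wlo, whi = max(lo - widen, 1), hi + widen
                    cand = np.nonzero(
                        (ped.sex == want_sex)
                        & (by >= by[i] - whi) & (by <= by[i] - wlo)
                    )[0].astype(np.int64)
                    if len(cand) or widen > max_span:
                        break
                    widen += 1
                if widen and len(cand):
                    logger.info(
                        "donor window for %s widened by %d years", ped.ids[i], widen
                    )
                elif not len(cand):
                    logger.info(
                        "no donor for %s; falling back to founder pool", ped.ids[i]
                    )
            total += len(cand)
            offsets[2 * i + slot + 1] = total
            chunks.append(cand)
    donor_list = (np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64))
    return offsets, donor_list.astype(np.int64)


def gene_drop(
    ped: Pedigree,
    founder_haplotypes: np.ndarray,
    gmap: GeneticMap,
    cfg: GeneDropConfig | None = None,
    seed: int | None = None,
) -> GenotypeSet:
    """One gene-dropped genotype set for the whole pedigree (no missingness)."""
    cfg = cfg or GeneDropConfig()
    pool = np.asarray(founder_haplotypes, dtype=np.int8)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise DriftError("founder haplotype pool is empty")
    if pool.shape[1] != len(gmap):
        raise DriftError("map does not cover the pool's SNPs")
    is_founder = ped.birth_year < cfg.founder_year_cutoff
    if not is_founder.any():
        raise DriftError(
            f"no founders: nobody born before {cfg.founder_year_cutoff}"
        )
    offsets, donors = _donor_candidates(ped, cfg)
    hap = gene_drop_kernel(
        ped.topological_order.astype(np.int64),
        ped.sire_idx, ped.dam_idx, is_founder,
        pool, gmap.rec_next.astype(np.float64),
        offsets, donors,
        int(cfg.seed if seed is None else seed) % (2**31),
        cfg.founder_assignment == "permutation",
    )
    return GenotypeSet(
        ids=ped.ids, snp_ids=gmap.snp_ids,
        counted_allele=np.array(["B"] * len(gmap)),
        other_allele=np.array(["A"] * len(gmap)),
        genotypes=hap.sum(axis=1, dtype=np.int8), haplotypes=hap, gmap=gmap,
    )


def drift_null_genomic(
    ped: Pedigree,
    founder_haplotypes: np.ndarray,
    gmap: GeneticMap,
    chain: PosteriorChain,
    cfg: GeneDropConfig | None = None,
    year_range: tuple[int, int] | None = None,
    min_cohort_size: int = 100,
    ids=None,
) -> np.ndarray:
    """Null slopes from gene dropping, one per posterior sample.

    Simulation s uses the SNP effects of posterior sample s, centring with
    the training allele frequencies of the chain (the real-data code path).
    ``ids`` restricts the cohort regression to a subset of the pedigree
    (e.g. the genotyped individuals).
    """
    cfg = cfg or GeneDropConfig()
    S = chain.n_samples
    seeds = _spawn_seeds(cfg.seed, S)
    if ids is None:
        sel = np.arange(ped.n)
    else:
        sel = ped.index_of(np.asarray(ids, dtype=str))

    pool = np.asarray(founder_haplotypes, dtype=np.int8)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise DriftError("founder haplotype pool is empty")
    is_founder = ped.birth_year < cfg.founder_year_cutoff
    if not is_founder.any():
        raise DriftError(f"no founders: nobody born before {cfg.founder_year_cutoff}")
    offsets, donors = _donor_candidates(ped, cfg)   # identical across simulations
    order = ped.topological_order.astype(np.int64)
    rec = gmap.rec_next.astype(np.float64)

    # cohort structure is fixed across simulations: precompute it once
    by = ped.birth_year[sel]
    mask = np.ones(len(by), bool)
    if year_range is not None:
        mask &= (by >= year_range[0]) & (by <= year_range[1])
    uyears, inv = np.unique(by[mask], return_inverse=True)
    sizes = np.bincount(inv)
    keep = sizes >= min_cohort_size
    if keep.sum() < 2:
        raise DriftError("fewer than 2 cohorts meet the size threshold")
    sel_masked = sel[mask]

    null_slopes = np.empty(S)
    for s in range(S):
        hap = gene_drop_kernel(order, ped.sire_idx, ped.dam_idx, is_founder,
                               pool, rec, offsets, donors, int(seeds[s]),
                               cfg.founder_assignment == "permutation")
        geno = hap.sum(axis=1, dtype=np.int8)
        gebv = (geno[sel_masked].astype(np.float64) - 2.0 * chain.freqs) @ chain.beta[s]
        means = np.bincount(inv, weights=gebv) / sizes
        null_slopes[s] = weighted_slope(uyears[keep], means[keep], sizes[keep])
    return null_slopes


def drift_null_pedigree(
    ped: Pedigree,
    sigma2_a_samples: np.ndarray,
    seed: int = 0,
    year_range: tuple[int, int] | None = None,
    min_cohort_size: int = 100,
    ids=None,
) -> np.ndarray:
    """Null slopes from midparent breeding-value dropping.

    Per simulation s (one per posterior sigma2_A): pedigree founders draw
    BV ~ Normal(0, sigma2_A); a gamete from a known parent contributes half
    the parent's BV plus Normal(0, sigma2_A/4) Mendelian sampling; a gamete
    from a missing parent contributes Normal(0, sigma2_A/2) — together these
    give descendants Normal(midparent, sigma2_A/2) when both parents are
    known and keep the marginal variance at sigma2_A throughout.
    """
    s2 = np.asarray(sigma2_a_samples, dtype=float)
    if (s2 < 0).any():
        raise DriftError("negative additive variance sample")
    rng = np.random.default_rng(seed)
    S = len(s2)
    n = ped.n
    sd_full = np.sqrt(s2)
    sd_half = np.sqrt(s2 / 2.0)
    sd_quarter = np.sqrt(s2 / 4.0)
    bv = np.zeros((n, S))
    for i in ped.topological_order:
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 and di < 0:
            bv[i] = rng.standard_normal(S) * sd_full
            continue
        val = np.zeros(S)
        for p in (si, di):
            if p >= 0:
                val += 0.5 * bv[p] + rng.standard_normal(S) * sd_quarter
            else:
                val += rng.standard_normal(S) * sd_half
        bv[i] = val
    if ids is None:
        sel = np.arange(n)
    else:
        sel = ped.index_of(np.asarray(ids, dtype=str))
    ebv = EbvPosterior(
        ids=ped.ids[sel], birth_year=ped.birth_year[sel], values=bv[sel],
        provenance="pedigree",
    )
    years, means, sizes = cohort_means(ebv, year_range, min_cohort_size)
    return np.asarray(weighted_slope(years, means, sizes))


@dataclass
class DriftResult:
    """Paired real and null slopes, their differences, and p_drift."""

    real_slopes: np.ndarray
    null_slopes: np.ndarray
    null_source: str = "genomic"     # which null mechanism generated the slopes
    ebv_source: str = "genomic"      # which EBV chain the real slopes come from

    def __post_init__(self):
        if len(self.real_slopes) != len(self.null_slopes):
            raise DriftError(
                f"{len(self.real_slopes)} real vs {len(self.null_slopes)} null "
                "slopes; pairing requires equal counts"
            )

    @property
    def differences(self) -> np.ndarray:
        return self.real_slopes - self.null_slopes

    @property
    def p_drift(self) -> float:
        """Proportion of pairs where the null slope strictly exceeds the
        real slope (ties count against rejection)."""
        return float((self.null_slopes > self.real_slopes).mean())

    def summary(self) -> str:
        d = self.differences
        return "\n".join([
            f"Drift test: {self.ebv_source} EBV slopes vs {self.null_source} null",
            "=" * 52,
            f"paired simulations:      {len(d)}",
            f"mean real slope (kg/yr): {self.real_slopes.mean(): .5f}",
            f"mean null slope (kg/yr): {self.null_slopes.mean(): .5f}",
            f"mean difference:         {d.mean(): .5f}",
            f"p_drift:                 {self.p_drift:.3f}",
        ])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": np.arange(len(self.real_slopes)),
            "real_slope": self.real_slopes,
            "null_slope": self.null_slopes,
            "diff": self.differences,
        })


def p_drift(real: TrendPosterior | np.ndarray, null_slopes: np.ndarray,
            null_source: str = "genomic", ebv_source: str = "genomic") -> DriftResult:
    """Pair posterior trend slopes with null slopes by sample index."""
    real_slopes = real.slopes if isinstance(real, TrendPosterior) else np.asarray(real, float)
    return DriftResult(
        real_slopes=np.asarray(real_slopes, dtype=float),
        null_slopes=np.asarray(null_slopes, dtype=float),
        null_source=null_source, ebv_source=ebv_source,
    )
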