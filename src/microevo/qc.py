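"""Genotype quality control: call-rate, missingness, MAF and HWE filters.

Individuals failing the call-rate threshold are removed first; SNP-level
statistics (missingness, minor allele frequency, Hardy-Weinberg exact test)
are then computed on the surviving individuals.  The HWE test is the exact
conditional test on heterozygote counts (the standard GWAS-QC test): the
p-value sums the probabilities of all heterozygote configurations, given the
observed allele counts, that are no more probable than the observed one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeSet

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditional on the minor-allele count, the heterozygote count under HWE
    follows the distribution of Levene/Haldane; the two-sided p-value is the
    total probability of configurations at most as probable as the observed
    one.  Probabilities are built by the usual stable recurrence.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    minor = 2 * n_hom_minor + n_het
    major = 2 * n_hom_major + n_het
    if minor > major:
        minor, major = major, minor
    # possible heterozygote counts share parity with the minor allele count
    het_max = minor
    probs = np.zeros(het_max + 1)
    # start from the largest heterozygote count and recurse downwards:
    # P(h-2)/P(h) = h(h-1) / (4 (n_aa+1)(n_AA+1)) with the homozygote counts
    # implied by h
    h = het_max
    probs[h] = 1.0
    while h >= 2:
        n_aa = (minor - h) // 2
        n_AA = n - n_aa - h
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (n_aa + 1) * (n_AA + 1))
        h -= 2
    parity = het_max % 2
    support = np.arange(parity, het_max + 1, 2)
    p = probs[support]
    p /= p.sum()
    obs = probs[n_het] / probs[support].sum() if n_het % 2 == parity else None
    if obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


@dataclass
class QCReport:
    """Counts removed at each stage of genotype QC."""

    n_individuals_in: int
    n_snps_in: int
    individuals_removed_callrate: int
    snps_removed_missingness: int
    snps_removed_maf: int
    snps_removed_hwe: int
    thresholds: dict = field(default_factory=dict)

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.individuals_removed_callrate

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - self.snps_removed_missingness
                - self.snps_removed_maf - self.snps_removed_hwe)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individuals_in", self.n_individuals_in),
            ("individuals_removed_callrate", self.individuals_removed_callrate),
            ("individuals_out", self.n_individuals_out),
            ("snps_in", self.n_snps_in),
            ("snps_removed_missingness", self.snps_removed_missingness),
            ("snps_removed_maf", self.snps_removed_maf),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_out", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["criterion", "count"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_filter(
    g: GenotypeSet,
    max_snp_missing: float = 0.02,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-5,
    min_ind_callrate: float = 0.95,
) -> tuple[GenotypeSet, QCReport]:
    """Apply the standard SNP/individual QC filters.

    Order: individuals below ``min_ind_callrate`` are dropped first; SNPs are
    then dropped (on the surviving individuals) if their missingness exceeds
    ``max_snp_missing``, their minor allele frequency is below ``min_maf``,
    or their HWE exact-test p-value is below ``hwe_alpha``.  Each SNP is
    attributed to the first criterion it fails, in that order.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise QCError("genotype set must contain at least one SNP and one individual")

    ind_keep = g.individual_call_rate() >= min_ind_callrate
    g1 = g.subset(ind_mask=ind_keep)
    if g1.n_individuals == 0:
        raise QCError("all individuals removed by call-rate filter")

    miss = g1.snp_missing_rate()
    p = g1.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    fail_miss = miss > max_snp_missing
    fail_maf = ~fail_miss & (maf < min_maf)

    fail_hwe = np.zeros(g1.n_snps, dtype=bool)
    gt = g1.genotypes
    for j in np.nonzero(~fail_miss & ~fail_maf)[0]:
        col = gt[:, j]
        het = int((col == 1).sum())
        hom1 = int((col == 2).sum())
        hom0 = int((col == 0).sum())
        if hom1 > hom0:
            hom1, hom0 = hom0, hom1
        if hwe_exact_pvalue(het, hom1, hom0) < hwe_alpha:
            fail_hwe[j] = True

    snp_keep = ~(fail_miss | fail_maf | fail_hwe)
    if not snp_keep.any():
        raise QCError("all SNPs removed by QC filters")

    report = QCReport(
        n_individuals_in=g.n_individuals,
        n_snps_in=g.n_snps,
        individuals_removed_callrate=int((~ind_keep).sum()),
        snps_removed_missingness=int(fail_miss.sum()),
        snps_removed_maf=int(fail_maf.sum()),
        snps_removed_hwe=int(fail_hwe.sum()),
        thresholds=dict(
            max_snp_missing=max_snp_missing, min_maf=min_maf,
            hwe_alpha=hwe_alpha, min_ind_callrate=min_ind_callrate,
        ),
    )
    logger.info(
        "QC: %d/%d individuals, %d/%d SNPs retained",
        report.n_individuals_out, report.n_individuals_in,
        report.n_snps_out, report.n_snps_in,
    )
    return g1.subset(snp_mask=snp_keep), report
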