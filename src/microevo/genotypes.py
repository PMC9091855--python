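"""Genotype and genetic-map containers plus readers/writers.

Supported genotype dialects:

* PLINK-style text ``.ped``/``.map`` pair (biallelic, whitespace separated);
* a documented id x SNP allele-count matrix TSV (counts 0/1/2, ``NA``
  missing, optional ``#REF``/``#ALT`` comment rows carrying alleles);
* VCF (biallelic records only; requires the optional ``cyvcf2`` dependency).

Counts are always oriented to a declared "counted" allele per SNP: the ALT
allele for VCF, and the lexicographically greater of the two observed alleles
for PLINK text (deterministic and orientation is immaterial downstream
because genotypes are centred before use).
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)


class GenotypeError(ValueError):
    pass


class GeneticMap:
    """Per-SNP chromosome, position and recombination fraction to the next SNP.

    The last SNP of each chromosome carries ``rec_next = 0.5`` so that a
    single concatenated SNP order segregates chromosomes independently.
    """

    def __init__(self, df: pd.DataFrame):
        required = ("chrom", "snp_id", "pos", "rec_next")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GenotypeError(f"genetic map missing columns: {missing}")
        df = df.copy().reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["snp_id"] = df["snp_id"].astype(str)
        df["pos"] = df["pos"].astype(float)
        df["rec_next"] = df["rec_next"].astype(float)
        if ((df["rec_next"] < 0) | (df["rec_next"] > 0.5)).any():
            raise GenotypeError("recombination fractions must lie in [0, 0.5]")
        # sorted by (chromosome block, position); chromosome blocks stay in
        # first-appearance order
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise GenotypeError("map positions must increase within a chromosome")
        # enforce 0.5 at chromosome boundaries
        last = df.groupby("chrom", sort=False).tail(1).index
        df.loc[last, "rec_next"] = 0.5
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def rec_next(self) -> np.ndarray:
        return self.df["rec_next"].to_numpy()

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        sub = self.df.loc[np.asarray(keep)].reset_index(drop=True)
        return GeneticMap(sub)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_centimorgans(cls, df: pd.DataFrame) -> "GeneticMap":
        """Build from per-interval distances in cM via Haldane's map function."""
        d = df["cm_next"].astype(float).to_numpy()
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        out = df.copy()
        out["rec_next"] = r
        logger.info("converted map distances from cM via Haldane's map function")
        return cls(out.drop(columns=["cm_next"]))


@dataclass
class GenotypeSet:
    """Individuals x SNPs allele counts, optionally phased.

    ``genotypes`` holds counts of the counted allele in {0,1,2} (int8, -1 for
    missing).  ``haplotypes`` (if present) has shape (n, 2, m) with binary
    entries whose sum reproduces the genotype at every non-missing site.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    gmap: GeneticMap | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=str)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.ids), len(self.snp_ids)):
            raise GenotypeError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        if len(np.unique(self.ids)) != len(self.ids):
            raise GenotypeError("duplicate individual ids in genotype set")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.ids), 2, len(self.snp_ids)):
                raise GenotypeError("haplotype array shape mismatch")
            hsum = self.haplotypes.sum(axis=1, dtype=np.int8)
            ok = (self.genotypes == MISSING) | (hsum == self.genotypes)
            if not ok.all():
                raise GenotypeError("phased haplotypes do not sum to genotype counts")
        if self.gmap is not None and len(self.gmap) != len(self.snp_ids):
            raise GenotypeError("genetic map does not cover all SNPs")

    # -- summaries ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele, ignoring missing calls."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=0) / 2.0
        return np.where(np.isnan(p), 0.0, p)

    def snp_missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - (self.genotypes == MISSING).mean(axis=1)

    def centered_matrix(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Mean-imputed, centred dosage matrix (g - 2p), float64.

        Missing genotypes are imputed at twice the allele frequency (the
        mean), i.e. they contribute 0 after centring.
        """
        if freqs is None:
            freqs = self.allele_frequencies()
        W = self.genotypes.astype(np.float64)
        miss = self.genotypes == MISSING
        if miss.any():
            W[miss] = np.take(2.0 * freqs, np.nonzero(miss)[1])
        return W - 2.0 * freqs

    # -- subsetting -----------------------------------------------------
    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeSet":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeSet(
            ids=self.ids[ind_mask],
            snp_ids=self.snp_ids[snp_mask],
            counted_allele=np.asarray(self.counted_allele)[snp_mask],
            other_allele=np.asarray(self.other_allele)[snp_mask],
            genotypes=self.genotypes[np.ix_(ind_mask, snp_mask)],
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[np.ix_(ind_mask, np.array([0, 1]), snp_mask)],
            gmap=None if self.gmap is None else self.gmap.subset(snp_mask),
        )

    def select_ids(self, ids) -> "GenotypeSet":
        ids = np.asarray(ids, dtype=str)
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise GenotypeError(f"ids not genotyped: {missing[:10]}")
        take = np.array([pos[i] for i in ids], dtype=np.int64)
        return GenotypeSet(
            ids=self.ids[take],
            snp_ids=self.snp_ids,
            counted_allele=self.counted_allele,
            other_allele=self.other_allele,
            genotypes=self.genotypes[take],
            haplotypes=None if self.haplotypes is None else self.haplotypes[take],
            gmap=self.gmap,
        )

    def write_haplotypes(self, path) -> None:
        """Phased haplotypes as id <TAB> hap <TAB> 0/1 string (one row per
        haplotype)."""
        if self.haplotypes is None:
            raise GenotypeError("no phased haplotypes to write")
        with open(path, "w") as fh:
            fh.write("#snps\t" + "\t".join(self.snp_ids) + "\n")
            for i, ind in enumerate(self.ids):
                for h in (0, 1):
                    fh.write(ind + "\t" + str(h) + "\t"
                             + "".join(map(str, self.haplotypes[i, h])) + "\n")

    def read_haplotypes(self, path) -> "GenotypeSet":
        """Attach phased haplotypes written by :meth:`write_haplotypes`."""
        haps = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                ind, h, s = line.rstrip("\n").split("\t")
                haps.setdefault(ind, [None, None])[int(h)] = np.frombuffer(
                    s.encode(), dtype=np.uint8
                ) - ord("0")
        arr = np.zeros((self.n_individuals, 2, self.n_snps), dtype=np.int8)
        for i, ind in enumerate(self.ids):
            if ind not in haps:
                raise GenotypeError(f"no haplotypes for individual {ind}")
            arr[i, 0] = haps[ind][0]
            arr[i, 1] = haps[ind][1]
        return GenotypeSet(
            ids=self.ids, snp_ids=self.snp_ids, counted_allele=self.counted_allele,
            other_allele=self.other_allele, genotypes=self.genotypes,
            haplotypes=arr, gmap=self.gmap,
        )

    def write_plink_text(self, prefix) -> None:
        """Write a .ped/.map pair (alleles as stored; missing as '0 0')."""
        prefix = str(prefix)
        with open(prefix + ".map", "w") as fh:
            if self.gmap is not None:
                for _, row in self.gmap.df.iterrows():
                    fh.write(f"{row.chrom} {row.snp_id} 0 {int(row.pos)}\n")
            else:
                for j, sid in enumerate(self.snp_ids):
                    fh.write(f"1 {sid} 0 {j + 1}\n")
        with open(prefix + ".ped", "w") as fh:
            for i, ind in enumerate(self.ids):
                fields = ["FAM", ind, "0", "0", "0", "0"]
                for j in range(self.n_snps):
                    g = self.genotypes[i, j]
                    a, b = str(self.counted_allele[j]), str(self.other_allele[j])
                    if g == MISSING:
                        fields += ["0", "0"]
                    else:
                        fields += [a] * int(g) + [b] * (2 - int(g))
                fh.write(" ".join(fields) + "\n")

    # -- matrix dialect -------------------------------------------------
    def write_matrix(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#REF\t" + "\t".join(map(str, self.counted_allele)) + "\n")
            fh.write("#ALT\t" + "\t".join(map(str, self.other_allele)) + "\n")
            fh.write("id\t" + "\t".join(self.snp_ids) + "\n")
            for i, row in zip(self.ids, self.genotypes):
                vals = ["NA" if v == MISSING else str(int(v)) for v in row]
                fh.write(i + "\t" + "\t".join(vals) + "\n")


def _read_matrix(path) -> GenotypeSet:
    ref = alt = None
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            tag, *vals = line.rstrip("\n").split("\t")
            if tag == "#REF":
                ref = np.array(vals)
            elif tag == "#ALT":
                alt = np.array(vals)
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        snp_ids = np.array(header[1:])
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ids.append(parts[0])
            rows.append([MISSING if v in ("NA", "") else np.int8(int(v)) for v in parts[1:]])
    if not ids:
        raise GenotypeError(f"no genotype rows in {path}")
    if ref is None:
        ref = np.array(["B"] * len(snp_ids))
        alt = np.array(["A"] * len(snp_ids))
    return GenotypeSet(
        ids=np.array(ids), snp_ids=snp_ids, counted_allele=ref, other_allele=alt,
        genotypes=np.array(rows, dtype=np.int8),
    )


def _read_plink_text(path) -> GenotypeSet:
    """Read a .ped/.map pair; ``path`` may be either file or the prefix."""
    base, ext = os.path.splitext(str(path))
    if ext in (".ped", ".map"):
        ped_path, map_path = base + ".ped", base + ".map"
    else:
        ped_path, map_path = str(path) + ".ped", str(path) + ".map"
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    snp_ids = mp["snp_id"].to_numpy()
    m = len(snp_ids)
    ids, allele_rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError(
                    f".ped row for '{parts[1] if len(parts) > 1 else '?'}' has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not ids:
        raise GenotypeError(f"empty .ped file: {ped_path}")
    if len(set(ids)) != len(ids):
        raise GenotypeError("duplicate individual ids in .ped file")
    alleles = np.array(allele_rows).reshape(len(ids), m, 2)

    geno = np.full((len(ids), m), MISSING, dtype=np.int8)
    counted = np.empty(m, dtype=object)
    other = np.empty(m, dtype=object)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            logger.warning("SNP %s has >2 alleles (%s); skipped", snp_ids[j], observed)
            keep[j] = False
            continue
        if len(observed) == 0:
            observed = ["A", "B"]
        if len(observed) == 1:
            observed = [observed[0], observed[0] + "_alt"]
        ref = max(observed)  # counted allele: lexicographically greater
        counted[j], other[j] = ref, min(observed)
        called = (col != "0").all(axis=1)
        geno[called, j] = (col[called] == ref).sum(axis=1).astype(np.int8)
    g = GenotypeSet(
        ids=np.array(ids), snp_ids=snp_ids[keep],
        counted_allele=counted[keep].astype(str), other_allele=other[keep].astype(str),
        genotypes=geno[:, keep],
    )
    return g


def _read_vcf(path) -> GenotypeSet:
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover - optional dependency
        raise GenotypeError("reading VCF requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    snp_ids, ref, alt, rows = [], [], [], []
    for k, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            logger.warning("non-biallelic VCF record %s skipped", variant.ID or variant.POS)
            continue
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        ref.append(variant.ALT[0])  # counted allele = ALT
        alt.append(variant.REF)
        gt = np.array(variant.genotypes)[:, :2]
        row = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1)).astype(np.int8)
        rows.append(row)
    if not rows:
        raise GenotypeError(f"no biallelic records in {path}")
    return GenotypeSet(
        ids=ids, snp_ids=np.array(snp_ids), counted_allele=np.array(ref),
        other_allele=np.array(alt), genotypes=np.array(rows, dtype=np.int8).T,
    )


def read_genotypes(path, format: str = "matrix") -> GenotypeSet:
    """Read genotypes from one of the supported dialects.

    Parameters
    ----------
    format : {"matrix", "plink_text", "vcf"}
    """
    if os.path.exists(str(path)) and os.path.getsize(str(path)) == 0:
        raise GenotypeError(f"empty genotype file: {path}")
    if format == "matrix":
        return _read_matrix(path)
    if format == "plink_text":
        return _read_plink_text(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")
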