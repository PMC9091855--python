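"""End-to-end orchestration: QC -> adjust -> EBVs -> trends -> drift nulls.

One RunConfig (YAML or dict) drives the whole analysis, on either synthetic
or user-supplied data.  Every stage writes its artifact (TSV/JSON) into the
output directory so any stage can be re-run or resumed from disk, and the
final report carries the full config echo and all derived seeds.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .animal import AnimalMcmcSettings, AnimalModel
from .bayesr import BayesRModel, McmcSettings, MixturePrior, _spawn_seeds
from .ebv import EbvPosterior
from .genedrop import GeneDropConfig, drift_null_genomic, drift_null_pedigree, p_drift
from .genotypes import GeneticMap, read_genotypes
from .pedigree import Pedigree, read_pedigree
from .phenotypes import filter_phenotypes, read_phenotypes
from .qc import qc_filter
from .repeatability import RepeatabilityModel
from .simulate import SimulatedStudy, StudyConfig, simulate_study
from .trend import haldane_rate, phenotypic_trend, posterior_trend

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` (a StudyConfig parameter dict) and
    ``inputs`` (paths to pedigree/genotypes/phenotypes/map files) must be
    given.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    year_ranges: list = field(default_factory=list)   # [] -> full span
    min_cohort_size: int = 100
    bayesr_mcmc: dict = field(default_factory=dict)
    animal_mcmc: dict = field(default_factory=dict)
    prior: dict = field(default_factory=dict)
    genedrop: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    min_age_months: float = 28.0
    generation_time: float | None = None
    seed: int = 0
    outdir: str = "microevo_run"
    write_data: bool = False

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' and 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic, "inputs": self.inputs,
            "year_ranges": self.year_ranges, "min_cohort_size": self.min_cohort_size,
            "bayesr_mcmc": self.bayesr_mcmc, "animal_mcmc": self.animal_mcmc,
            "prior": self.prior, "genedrop": self.genedrop, "qc": self.qc,
            "min_age_months": self.min_age_months,
            "generation_time": self.generation_time,
            "seed": self.seed, "outdir": self.outdir, "write_data": self.write_data,
        }


def load_inputs(cfg: RunConfig):
    """Load or simulate the study data.  Returns (pedigree, genotypes,
    records, study-or-None)."""
    if cfg.synthetic is not None:
        params = dict(cfg.synthetic)
        params.setdefault("seed", cfg.seed)
        study = simulate_study(StudyConfig.from_dict(params))
        return study.pedigree, study.genotypes, study.records, study
    paths = cfg.inputs
    ped = read_pedigree(paths["pedigree"])
    g = read_genotypes(paths["genotypes"], format=paths.get("genotype_format", "matrix"))
    if "haplotypes" in paths:
        g = g.read_haplotypes(paths["haplotypes"])
    if "map" in paths:
        g.gmap = GeneticMap.read(paths["map"])
    records = read_phenotypes(paths["phenotypes"])
    return ped, g, records, None


def write_study(study: SimulatedStudy, outdir) -> None:
    """Serialize a synthetic study in the standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.pedigree.write(outdir / "pedigree.tsv")
    study.genotypes.write_matrix(outdir / "genotypes.tsv")
    study.genotypes.write_haplotypes(outdir / "haplotypes.tsv")
    study.genotypes.gmap.write(outdir / "map.tsv")
    study.records.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    study.true_bv.rename("true_bv").rename_axis("id").reset_index().to_csv(
        outdir / "true_breeding_values.tsv", sep="\t", index=False
    )
    with open(outdir / "study_config.yaml", "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh)


def analyse_study(
    study: SimulatedStudy,
    year_range: tuple[int, int] | None = None,
    min_cohort_size: int = 10,
    n_samples: int = 100,
    bayesr_iters: tuple[int, int] = (1500, 500),
    seed: int = 0,
    compute_se: bool = False,
    drift: bool = True,
) -> dict:
    """Adjust -> genomic prediction -> trend (-> gene-dropping drift test)
    for one synthetic study; the in-memory workhorse behind the calibration
    and power analyses.

    Returns a dict with the fitted pieces ("adjusted", "bayesr", "gebv",
    "trend", and with ``drift=True`` also "null_slopes" and "drift_result").
    """
    if year_range is None:
        y0 = study.config.first_cohort_year
        year_range = (y0, y0 + study.config.n_years - 1)
    seeds = _spawn_seeds(seed, 3)
    ped, g = study.pedigree, study.genotypes
    kept = filter_phenotypes(study.records)
    adj = RepeatabilityModel(kept).fit(compute_se=compute_se)
    n_iter, burn_in = bayesr_iters
    bres = BayesRModel(adj.adjusted[["id", "value"]], g).fit(
        McmcSettings(n_iter=n_iter, burn_in=burn_in, n_samples=n_samples,
                     seed=int(seeds[0]))
    )
    idx = ped.index_of(g.ids)
    gebv = bres.predict(birth_years=ped.birth_year[idx])
    tp = posterior_trend(gebv, year_range, min_cohort_size)
    out = {"records": kept, "adjusted": adj, "bayesr": bres, "gebv": gebv, "trend": tp}
    if drift:
        cfg = GeneDropConfig(founder_year_cutoff=study.config.first_cohort_year,
                             seed=int(seeds[1]))
        pool_mask = ped.birth_year[idx] < cfg.founder_year_cutoff
        pool = g.haplotypes[pool_mask].reshape(-1, g.n_snps)
        null = drift_null_genomic(ped, pool, g.gmap, bres.chain, cfg,
                                  year_range, min_cohort_size, ids=g.ids)
        out["null_slopes"] = null
        out["drift_result"] = p_drift(tp, null)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``outdir/report.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg.seed, 6)
    report: dict = {"config": cfg.to_dict(), "seeds": [int(s) for s in seeds]}

    stage = "load"
    try:
        ped, g_raw, records, study = load_inputs(cfg)
        if cfg.write_data and study is not None:
            write_study(study, out / "data")

        stage = "qc"
        g, qc_report = qc_filter(g_raw, **cfg.qc)
        qc_report.write(out / "qc_report.tsv")
        report["qc"] = {"n_individuals": qc_report.n_individuals_out,
                        "n_snps": qc_report.n_snps_out}

        stage = "adjust"
        kept = filter_phenotypes(records, min_age_months=cfg.min_age_months)
        adj_res = RepeatabilityModel(kept).fit()
        adj_res.write_adjusted(out / "adjusted_phenotypes.tsv")
        report["repeatability"] = {
            **adj_res.varcomp.as_dict(), "n_records": int(len(kept)),
            "n_individuals": int(len(adj_res.adjusted)),
        }

        stage = "gebv"
        genotyped = set(g.ids)
        train = adj_res.adjusted[adj_res.adjusted["id"].isin(genotyped)]
        if train.empty:
            raise ConfigError("no phenotyped individuals are genotyped")
        prior = MixturePrior(**cfg.prior)
        bsettings = McmcSettings(**{"seed": int(seeds[0]), **cfg.bayesr_mcmc})
        bres = BayesRModel(train[["id", "value"]], g, prior).fit(bsettings)
        bres.chain.write(out / "bayesr_chain.tsv")
        ped_idx = ped.index_of(g.ids)
        gebv = bres.predict(birth_years=ped.birth_year[ped_idx])
        gebv.write(out / "gebv.tsv")
        (out / "bayesr_summary.txt").write_text(bres.summary() + "\n")

        stage = "pebv"
        asettings = AnimalMcmcSettings(**{"seed": int(seeds[1]), **cfg.animal_mcmc})
        amodel = AnimalModel(kept, ped)
        ares = amodel.fit(asettings, store_ids=g.ids)
        pebv = ares.ebv(g.ids)       # genotyped individuals only, as in the GEBVs
        pebv.write(out / "pebv.tsv")
        (out / "animal_model_summary.txt").write_text(ares.summary() + "\n")

        stage = "trend"
        year_ranges = [tuple(r) for r in cfg.year_ranges] or [None]
        report["phenotypic_trend"] = phenotypic_trend(kept)
        trends: dict = {}
        trend_objs: dict = {}
        for ebv, src in ((gebv, "gebv"), (pebv, "pebv")):
            for yr in year_ranges:
                tp = posterior_trend(ebv, yr, cfg.min_cohort_size)
                key = f"{src}_{yr[0]}_{yr[1]}" if yr else f"{src}_all"
                trend_objs[key] = tp
                trends[key] = {
                    "slope_mean": tp.posterior_mean, "ci95": list(tp.ci95),
                    "p_stasis": tp.p_stasis, "n_cohorts": int(len(tp.years)),
                }
                tp.to_frame().to_csv(out / f"trend_{key}.tsv", sep="\t", index=False)
        report["trends"] = trends

        stage = "drift"
        gd_cfg = GeneDropConfig(**{"seed": int(seeds[2]), **cfg.genedrop})
        if g.haplotypes is None:
            raise ConfigError("gene dropping requires phased haplotypes")
        pool_mask = ped.birth_year[ped_idx] < gd_cfg.founder_year_cutoff
        pool = g.haplotypes[pool_mask].reshape(-1, g.n_snps)
        drift: dict = {}
        for yr in year_ranges:
            ykey = f"{yr[0]}_{yr[1]}" if yr else "all"
            null_gen = drift_null_genomic(
                ped, pool, g.gmap, bres.chain, gd_cfg, yr,
                cfg.min_cohort_size, ids=g.ids,
            )
            null_ped = drift_null_pedigree(
                ped, ares.chain.sigma2["sigma2_a"].to_numpy(),
                seed=int(seeds[3]), year_range=yr,
                min_cohort_size=cfg.min_cohort_size, ids=g.ids,
            )
            for src in ("gebv", "pebv"):
                tp = trend_objs[f"{src}_{ykey}"]
                for null, nsrc in ((null_gen, "genomic"), (null_ped, "pedigree")):
                    dr = p_drift(tp, null, null_source=nsrc, ebv_source=src)
                    key = f"{src}_vs_{nsrc}_{ykey}"
                    drift[key] = {"p_drift": dr.p_drift,
                                  "mean_null_slope": float(null.mean())}
                    dr.to_frame().to_csv(out / f"drift_{key}.tsv", sep="\t", index=False)
        report["drift"] = drift

        stage = "haldane"
        if cfg.generation_time is not None:
            mean_trait = float(kept["weight"].mean())
            hr = haldane_rate(
                trend_objs[[k for k in trend_objs if k.startswith("gebv")][0]],
                mean_trait, kept["weight"].to_numpy(float), cfg.generation_time,
            )
            report["haldane_rate"] = {
                "mean": hr.posterior_mean, "ci95": list(hr.ci95),
                "generation_time": cfg.generation_time, "mean_trait": mean_trait,
            }
    except Exception as e:
        logger.error("pipeline failed at stage '%s': %s", stage, e)
        report["failed_stage"] = stage
        report["error"] = str(e)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
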