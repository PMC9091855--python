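# microevo

Detecting microevolutionary change of a quantitative trait with genomic
prediction, in wild pedigreed populations.

Phenotypic time series in the wild routinely hide genetic change: a trait can
respond to selection while an opposing environmental trend masks the response
(*cryptic evolution*). Testing for such change requires (i) breeding values
with honest uncertainty, and (ii) an explicit null distribution for how much
the breeding-value trend could move by genetic drift alone. `microevo`
implements that framework end to end:

1. **Stage one — phenotype adjustment.** A repeatability mixed model
   `w = Xb + Z_id u_id + Z_by u_by + Z_cy u_cy + e` (REML) of repeated adult
   August weights, with sex and age as fixed effects and individual identity,
   birth year and capture year as random intercepts. The BLUP of the
   individual effect is the adjusted phenotype.
2. **Genomic prediction.** A four-component normal-mixture Gibbs sampler for
   SNP effects (`BayesRModel`): β_j ~ π₁·δ₀ + Σ_k π_k N(0, γ_k σ²_ref) with
   γ = (0, 10⁻⁴, 10⁻³, 10⁻²), Dirichlet prior on π, scaled-inverse-χ²
   priors on the genetic and residual variances. Posterior GEBVs are
   `Σ_j (g_ij − 2p_j) β_j^(s)` for every retained sample s, for phenotyped
   (training) and unphenotyped (test) individuals alike. Leave-one-cohort-out
   refitting and k-fold cross-validation accuracy are included.
3. **Pedigree animal model.** A Bayesian animal model on the raw repeated
   measures (`AnimalModel`) with the additive effect structured by the
   pedigree numerator relationship matrix A (sparse A⁻¹ by Henderson's rules
   with inbreeding), plus permanent-environment, birth-year and capture-year
   effects — posterior pedigree EBVs for comparison with the GEBVs.
4. **Trend inference.** For every posterior sample, cohort (birth-year) mean
   EBVs are regressed on year, weighting cohorts by size; the posterior of
   slopes gives a 95% credible interval, P(stasis) = P(slope ≤ 0), and a
   Haldane rate (log-trait SDs per generation).
5. **Drift nulls.** (a) *Gene dropping*: phased founder haplotypes are
   dropped through the pedigree with recombination (0.5 across chromosome
   boundaries); simulation s is scored with the SNP effects of posterior
   sample s. (b) *Midparent dropping*: founder BVs ~ N(0, σ²_A^(s)),
   descendants ~ N(midparent, σ²_A^(s)/2). In both,
   `p_drift = #{null slope > real slope}/S` over the paired samples.
6. **Synthetic data.** A forward simulator of an overlapping-generation
   study population (LD-structured founder haplotypes, mixture-architecture
   trait, repeated August measures, optional viability selection on weight
   that induces a genetic trend, plus an opposing environmental trend) so the
   whole pipeline is testable against known truth.

## Worked example

```python
from microevo import simulate_study, cryptic_config
from microevo.pipeline import analyse_study
from microevo.trend import phenotypic_trend

study = simulate_study(cryptic_config(seed=1))          # ~1300 sheep-like animals
res = analyse_study(study, seed=1)                      # adjust -> GEBVs -> trend -> drift
ph = phenotypic_trend(res["records"])
print("phenotypic slope: %.3f kg/yr (p=%.3g)" % (ph["slope"], ph["p_value"]))
print(res["trend"].summary())
print(res["drift_result"].summary())
```

prints:

```
phenotypic slope: -0.119 kg/yr (p=1.85e-27)
Cohort-mean EBV trend (genomic)
============================================
cohorts: 1990-2004 (15 retained, sizes 35-124)
posterior samples:     100
slope (kg/yr):          0.0089
95% credible interval: [ 0.0019,  0.0161]
P(stasis) = P(slope <= 0): 0.000
Drift test: genomic EBV slopes vs genomic null
====================================================
paired simulations:      100
mean real slope (kg/yr):  0.00886
mean null slope (kg/yr): -0.00114
mean difference:          0.01000
p_drift:                 0.180
```

The cryptic pattern: measured weights *decline* by 0.12 kg/yr while the
cohort-mean breeding values *rise* by ~0.009 kg/yr, with no posterior mass
on stasis. `p_drift` = 0.18 is the probability that genetic drift alone
would produce a trend at least this steep — evidence for selection here is
suggestive but, with 15 cohorts of this population size, not decisive
(detecting weak trends against drift needs long series; that is the point
of computing the null explicitly).

A shell-level run of the same pipeline:

```bash
microevo simulate --seed 3 --out data/
microevo run-all --config run.yaml
```

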