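# Methods

## The inference problem

The package asks whether the additive-genetic component of a quantitative
trait (the running example is adult August body weight, kg, in a wild sheep
population) has changed across birth cohorts, and whether any change exceeds
what genetic drift alone would produce. Both questions are answered on the
posterior distribution of breeding values, never on point estimates: every
statistic (cohort-mean slope, credible interval, P(stasis), p_drift) is
computed per posterior sample and summarised afterwards. This is the
defence against the known anti-conservatism of treating estimated breeding
values as data.

## Stage one: the repeatability model

Repeated adult records are modelled as

    w_ir = mu + sex + age + u_id(i) + u_by(i) + u_cy(r) + e_ir ,

with independent random intercepts for individual identity, birth year and
capture year, estimated by REML (profiled through the mixed-model-equation
identity −2l_R = n log σ²_e + log|G| + log|C| + y'Py, optimised over log
variances by L-BFGS-B; asymptotic SEs from a central-difference Hessian).
The BLUP of `u_id` is the adjusted phenotype passed to genomic prediction.
Age enters as a categorical whole-years factor by default (a polynomial
option exists); records are restricted to August captures at ≥28 months, so
growth effects are largely absent and remaining age effects are small.

Two consequences of this design are worth stating because they shape
everything downstream:

* the BLUP *shrinks* each individual's deviation by roughly
  σ²_ID/(σ²_ID + σ²_E/n_records);
* the birth-year random effect absorbs nearly all cohort-mean structure —
  including any genuine cohort-mean genetic trend. This de-trending is
  deliberate (it protects against environmentally driven spurious trends);
  its cost is documented under *Known conservatism* below.

Uncertainty in the adjusted phenotypes is not propagated further; the
posterior machinery downstream carries the uncertainty in breeding values.

## Genomic prediction

SNP effects follow a four-component mixture: a point mass at zero and three
normal components with variances (10⁻⁴, 10⁻³, 10⁻²) of a reference
variance. The reference is the phenotypic variance of the training
phenotypes by default (a `reference="genetic"` switch uses the chain's
current genetic variance instead; the two conventions coexist in the
literature). The Gibbs sweep samples, in order: the intercept; for each SNP
its component (by conditional marginal likelihood) and effect (conjugate
normal, exactly zero in the null class); the mixture proportions π from
Dirichlet(α + class counts); the genetic and residual variances from
scaled-inverse-χ² conditionals (scales 1.2 and 2.5, df 10).

The Dirichlet pseudo-counts default to (5,1,1,1) *aligned to the ascending
variance fractions*: the large count sits on the zero class, the
conservative prior that pulls assignments toward the null component. The
source conventions are ambiguous on this alignment; the field is
config-exposed.

Genotypes are mean-imputed and centred by twice the training allele
frequency; no per-SNP variance standardisation (the mixture's variance
classes already encode the effect-size scale). GEBVs are linear in β, so
the retained chain (evenly subsampled post burn-in to exactly `n_samples`
draws, default 1000) yields a posterior for every genotyped individual,
phenotyped or not. Leave-one-cohort-out refits exclude a whole birth cohort
from training so no GEBV uses its own or cohort-mates' phenotypes.
`cv_accuracy` reports the correlation between posterior-mean GEBV and the
held-out *adjusted phenotype*; on the true-genetic-value scale that equals
accuracy × √h² of the adjusted phenotype.

## Pedigree animal model

The raw repeated measures are modelled with fixed sex and age-class effects
and random additive-genetic (A-structured), permanent-environment,
birth-year and capture-year intercepts. A⁻¹ is built directly by
Henderson's rules with inbreeding; inbreeding coefficients come from the
L·D·L′ trace (no dense A is ever formed; the tabular method exists as a
small-pedigree oracle). Variance priors are weakly informative
scaled-inverse-χ² (df 1, scales 0.3/0.1/0.1/0.1/0.4 × the phenotypic
variance; config-exposed) — the source analysis does not state its priors.

The default location sampler is a single-site Gibbs sweep (cost per
iteration ∝ nnz(A⁻¹) + records), which makes the long chains the model
needs affordable on one CPU; a joint block sampler (dense Cholesky of the
full mixed-model equations per iteration) is available via
`location_sampler="block"` and is cross-checked against the single-site
sweep in the test suite. Full-scale defaults are 600 000 iterations, burn-in
100 000, 1000 retained samples (500 000/500 exactly); the synthetic-study
analyses use shorter chains (8000/3000/100), which the recovery tests show
are sufficient at those data sizes.

## Trend inference

For each posterior sample, cohort-mean EBVs are regressed on birth year by
weighted least squares with cohort sizes as weights; cohorts below
`min_cohort_size` (default 100, matching the source study's rule; synthetic
studies use 10 because their cohorts are ~20–120 animals) are excluded. The
posterior of slopes gives the percentile 95% CI and
P(stasis) = #{slope ≤ 0}/S.

The Haldane rate reconstructs the cohort trait scale as mean trait +
cohort-mean EBV per posterior sample, log-transforms, takes the weighted
log-slope × generation time, and divides by the SD of the log-transformed
trait values supplied by the user. Generation time is a required input (4
years is a sensible value for the emulated population and is what
`scripts/acceptance.py` uses).

## Drift nulls

*Gene dropping.* Individuals born before the founder cutoff (default 1990)
receive two haplotypes from the phased founder pool. The default assignment
is a random permutation — each real founder haplotype is used exactly once
per pass — so the simulated founder generation reproduces the real
founders' haplotype frequencies without extra resampling variance; sampling
with replacement (the other common convention) is config-exposed but makes
the drift null measurably over-dispersed and hence the test conservative.
Every other individual receives one recombinant gamete per parent —
a walk along the SNP order that switches parental template with the
interval's recombination fraction, 0.5 across chromosome boundaries (no
interference; a cM map is converted by Haldane's map function). A missing
parent's gamete is a haplotype copied from a random same-sex individual
born 2–10 years earlier; an empty window widens symmetrically one year at
a time and finally falls back to the founder pool (both logged — the
fallback order is this package's choice, the sources do not specify one).
Simulation s is converted to GEBVs with posterior sample s's SNP effects,
centred with the *training* allele frequencies (code-path identical to
prediction), and the same weighted cohort regression yields the null slope.

*Midparent dropping.* Per posterior σ²_A sample: founders draw
N(0, σ²_A); each gamete from a known parent contributes half the parent's
BV plus N(0, σ²_A/4) Mendelian sampling; a missing parent's gamete
contributes N(0, σ²_A/2) — so descendants with both parents known are
N(midparent, σ²_A/2) and the marginal variance stays σ²_A throughout
(inbreeding is ignored, as in the standard version of this simulation).

`p_drift` is the proportion of pairs (matched by sample index) in which the
null slope strictly exceeds the real slope; ties count against rejection.
The 2×2 grid (EBV source × null source) is reported by the pipeline.

## The synthetic-data generator

The generator emulates the design of a long-term individual-based study:

* **Demography.** ~80 founders born over the 7 years before the first
  cohort year (1990), overlapping generations, maturity at 2 years, Poisson
  fecundity (1.0 offspring/female/year), annual survival 0.80, a soft
  population cap of 300; 15 cohort years. This yields ~900 individuals with
  cohorts of ~20–90 — the scale at which all default analyses run in
  seconds. Because selection acts on survival and survivors breed, the
  selected regimes are produced by an *integrated* forward simulation
  (`simulate_study`); `simulate_pedigree` and `simulate_phenotypes` expose
  the neutral demography and the measurement model separately.
* **Genomes.** 500 biallelic SNPs on 5 chromosomes, adjacent recombination
  fraction 0.02 (0.5 across chromosomes). Founder haplotypes come from a
  first-order copying process: independent seed haplotypes at
  Beta(0.8, 0.8) frequencies (clipped to [0.05, 0.95]), mosaics thereafter
  with template-switch probability min(1, 2r) (so r = 0.5 gives independent
  segregation) and a small per-site innovation rate anchoring frequencies.
  This gives monotone LD decay in r — sufficient for testing, though the
  haplotype-block structure of real SNP-chip data is richer.
* **Trait.** μ = 24 kg, σ²_A = 2.6, σ²_PE = 1.5, σ²_BY = 0.8, σ²_CY = 0.8,
  σ²_E = 4.7 kg² (h² ≈ 0.25 of ~10.4 kg²), males +3 kg, age-class effects
  rising from −10 kg (lambs) to +2 kg (5+ years). SNP effects follow the
  same mixture family as the sampler (default 90% null) and are rescaled so
  the realised *genic* variance Σ 2p(1−p)β² hits σ²_A exactly. Note that
  with LD the realised founder variance of breeding values fluctuates
  around that target across seeds; recovery tests that need an exactly
  known additive variance therefore use the infinitesimal generator
  `simulate_breeding_values` instead.
* **Cryptic regime** (`cryptic_config`). Viability selection of 0.07
  log-odds of winter survival per kg of weight deviation plus an
  environmental capture-year trend of −0.12 kg/yr, on a larger, better-
  measured design (~1300 individuals, survival 0.85, tighter linkage,
  denser causal architecture; GEBV accuracy ≈ 0.9). This produces true
  breeding-value slopes of roughly +0.01 to +0.03 kg/yr against a clearly
  negative phenotypic trend — the same order as the published
  cryptic-evolution case the framework targets.

What passing tests on these data do **not** show: robustness to genotyping
error and missingness patterns of real arrays, to pedigree errors, to
non-random fates of unmeasured emigrants, or to LD structure beyond
monotone decay.

## Known conservatism of the trend estimate

The two-stage procedure attenuates cohort-mean trends: stage one shrinks
individual deviations and de-trends across birth years, and the effect
posterior shrinks β toward zero, so the GEBV cohort slope is a calibrated
estimate of an *attenuated* trend (empirically ≈ 0.45× the true
breeding-value slope in the cryptic regime, even at GEBV accuracy 0.93 — a
single-stage control with unadjusted phenotypes shows near-nominal CI
coverage, isolating the cause to the two-stage design). The practical
reading: positive evidence of a genetic trend is trustworthy, the magnitude
is a lower bound, and credible intervals cover the truth only when the true
trend is comparable to the interval's width.

The drift test inherits a conservatism of its own from the one-to-one
pairing of simulations with posterior samples: the real slope is centred on
the posterior-*mean* (shrunken) effect vector, while each null slope is
scored with a posterior *draw*, whose expected squared norm is larger
(Jensen's inequality). When per-SNP effect estimates are substantially
shrunken — which is the normal situation in genomic prediction — the null
distribution is wider than the across-study distribution of the real slope,
and p_drift under-rejects. Measured on 200 neutral replicate studies at the
default study size, the rejection rate at the nominal 0.05 level is ~0.01
and the 5th percentile of p_drift is ~0.17; within any one study p_drift
agrees with its normal approximation exactly, so this is a property of the
procedure, not of the implementation. The practical reading is one-sided:
a small p_drift is strong evidence that the trend exceeds drift; a
moderate p_drift does not exclude selection.

## Numerical choices and degenerate inputs

* REML: variances optimised on the log scale, floor 10⁻⁸ × var(y); a
  component at the floor is reported as 0 with a boundary warning;
  identical-record data short-circuit to the all-zero solution.
* Mixture sampler: class probabilities computed with a log-sum-exp guard
  (π + 10⁻³⁰⁰); a non-finite stored draw raises with the sample index.
* HWE: the exact conditional test; probabilities by the stable two-step
  recurrence; the two smallest classes of the QC report tie out against an
  independent log-factorial enumeration in the tests.
* QC order: individuals by call rate first, SNP filters on survivors; each
  SNP is attributed to the first rule it fails (missingness, MAF, HWE).
  HWE is tested on the full post-call-rate sample (whether the source
  analysis used a founder subset is unstated).
* Gene-drop seeds, fold seeds and chain seeds all derive from one master
  seed via `SeedSequence`, so every artifact is bit-reproducible.
* Weighted slope with all-equal years, non-positive weights, or fewer than
  two retained cohorts raises rather than returning NaN.

## Problem sizes used by the shipped analyses

The default test and acceptance runs use the generator defaults above
(~900-individual neutral studies; ~1300-individual cryptic studies; 500
SNPs; 100 posterior samples paired with 100 drift simulations per study;
BayesR chains of 1500 iterations at these data sizes; animal-model chains
of 8000). These sizes were chosen as the smallest at which the statistical
properties under test (calibration, recovery, coverage) are expressed
clearly; all defaults scale up by configuration.
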