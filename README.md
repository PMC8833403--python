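# twinprs

Twin-cohort polygenic risk scores and liability-threshold variance
decomposition, with a synthetic twin-registry generator so the whole
pipeline is testable without any external data.

The package covers four stages that compose into one reproducible pipeline:

1. **`twinprs.simdata`** — synthetic twin cohorts: block-LD haplotype pools
   (latent-Gaussian AR(1) within blocks), mendelian MZ/DZ genotype
   transmission, APOE-like two-marker epsilon haplotypes, noisy GWAS
   summary statistics, and binary liability-threshold phenotypes with a
   known decomposition into polygenic (A_P), measured-e4 (A_e4), background
   genetic (A_B), shared (C) and unique (E) variance, optional A–C
   covariance, covariate effects, incomplete pairs and MZ co-twin score
   imputation.
2. **`twinprs.prscore`** — clumping-and-thresholding PRS construction: QC
   and allele harmonization, greedy LD clumping at a dosage-r² cutoff
   (default 0.01), eight p-value thresholds, allele-weighted scoring,
   APOE-region exclusion, ancestry PCA (fitted excluding duplicate MZ
   genomes), PC residualization and within-array standardization, and
   epsilon-allele counts from the rs429358/rs7412 dosages.
3. **`twinprs.probitmm`** — mixed-effects probit (or logit) regression with
   separate MZ and DZ pair-level random-intercept variances via adaptive
   Gauss–Hermite quadrature, plus ICCs, deviance (LRT) tests, Nagelkerke
   R², rank-based AUC and log-likelihood-minus-penalty information
   criteria.
4. **`twinprs.biometric`** — the extended ACE liability-threshold twin
   model: a latent polygenic factor identified by the measured standardized
   PRS (and optionally the measured e4 count), background genetic, shared
   and unique environment with optional A–C covariance. Total liability
   variance is fixed at 1 with E derived, the threshold is fixed at 0 with
   the liability mean regressed on covariates, and variance components are
   estimated by maximum likelihood **without sign bounds** so LRTs keep
   nominal type-I error. Includes model comparison, SEM-convention AIC/BIC,
   profile-likelihood confidence intervals and Monte-Carlo power.

Pair likelihoods combine a Gaussian density for the measured block with a
bivariate-normal rectangle probability for the binary pair, evaluated
through Owen's T function (`twinprs._bvn`). MZ pairs imply a cross-twin
measured correlation of 1, so their measured block is collapsed to the
pair-level mean with a univariate density.

## CLI

```sh
# simulate a cohort (direct mode: the PRS is the latent polygenic factor)
twinprs simulate --config examples/sim.yaml --out-dir out/sim

# build C+T scores from a dosage panel + summary statistics
twinprs prs --sumstats ss.tsv --genotypes out/sim/genotypes --out prs.tsv

# mixed probit regression with MZ/DZ random variances
twinprs regress --cohort out/sim/cohort.tsv --out regress.json

# extended ACE fit on complete pairs
twinprs twinfit --cohort out/sim/cohort.tsv --model ae_prs --ci profile --out twin.json

# Monte-Carlo power for dropping a component
twinprs power --config examples/sim.yaml --full-model ace --reduced-model ae \
    --n-reps 100 --out power.json

# all stages in one deterministic run
twinprs pipeline --config examples/sim.yaml --out-dir out/run
```

A minimal simulation config (YAML or JSON):

```yaml
n_mz: 500
n_dz: 700
sigma2_ap: 0.101   # variance shares must sum to 1 (with 2*cov_ac)
sigma2_ab: 0.614
sigma2_e: 0.285
prevalence: 0.27
incomplete_rate: 0.3
seed: 42
```

Model names for `twinfit`: `ace`, `ae`, `e`, `ace_prs`, `ae_prs`,
`ace_prs_e4`, `ae_prs_e4`, plus `ae_prs_null` / `ae_prs_e4_null` (the
measured variable keeps its twin-covariance block but loads zero on
liability — the nested null for power calculations).

## Notes on conventions

- Regression information criteria follow the reporting convention
  `AIC = logLik - k`, `SBC = logLik - (k/2) ln(n clusters)` with
  `k = fixed effects + free random variances`.
- Biometric AIC/BIC use `-2LL + 2k` / `-2LL + k ln(n pairs)` where `k`
  counts the derived E component as estimated (constraint-style counting).
- The clumping window (250 kb default) and APOE region
  (chr19:44,400,000–46,500,000, closed interval) are configurable; results
  depend on both.
- ICC for the probit link is `v / (1 + v)`; for the logit link
  `v / (v + pi^2/3)`.
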