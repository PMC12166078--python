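# Methods

## Model and estimation

The computational core is a covariance-structure engine in RAM form.
Every variable — observed indicator, observed exogenous regressor
(a polygenic score), latent factor — is a node; directed paths
(loadings, regressions) populate an asymmetric matrix `A`, and
(co)variances a symmetric matrix `S`. The implied covariance of the
manifest variables is `Σ(θ) = F (I−A)⁻¹ S (I−A)⁻ᵀ Fᵀ`. Fitting
minimises the normal-theory maximum-likelihood discrepancy

    F_ML(θ) = ln|Σ(θ)| + tr(S_sample Σ(θ)⁻¹) − ln|S_sample| − p

with the test statistic `T = (n−1)·F_ML` at the optimum.

Ordinal 3-category items are treated as continuous, and models are fit
to covariance matrices of covariate-residualised (sex, age, ten
ancestry PCs; Z-scored) measures, listwise-complete over the measures
in a given model. This mirrors an analysis design that reports a single
N per model and deliberately leaves ordinal-threshold (WLSMV)
estimation out of scope. Treating skewed ordinal items as continuous
attenuates their loadings relative to the latent response — visible in
the synthetic cohort and worth remembering when comparing ordinal-item
and continuous-measure results.

Numerical choices:

- **Identification** by fixing factor variances to 1 (standardised
  factors); an explicit check (non-negative df, every factor anchored)
  runs before optimisation.
- **Optimisation**: L-BFGS-B with analytic gradients (the RAM
  derivative identities), falling back to numeric gradients when a spec
  contains nonlinearly constrained cells; 5 restarts (declared starts
  plus jitter), ranked by discrepancy, ties by restart order;
  convergence tolerance 1e-10 on F_ML. Variance parameters are bounded
  below at 1e-8, so Heywood cases surface as boundary solutions and
  flip the admissibility flag rather than crashing.
- **Standard errors** from the inverse observed information of F_ML,
  `acov = 2/(n−1) · H⁻¹` with a finite-difference Hessian;
  nonparametric case-resampling bootstrap as an alternative
  (replicate non-convergence is counted, >50% aborts).
- **Fit indices**: CFI (capped to [0,1]), TLI (uncapped), RMSEA, and
  SRMR computed as the root mean square of `D(S−Σ)D` over the lower
  triangle including the diagonal, with `D = diag(S)^(−1/2)` (sample
  SDs). `df = 0` leaves RMSEA/TLI undefined (`None`), never silently 0.
  The baseline model is the independence model with sample variances.

## Structure discovery

The number of factors uses the Kaiser rule (eigenvalues of the
correlation matrix strictly greater than 1), logged for scree
inspection; block-level counts come from per-block Kaiser rules. The
split-half stratifies on sex crossed with the per-measure
observed/missing signature (strata under 4 pooled), shuffles within
stratum and assigns alternately, alternating the starting half across
strata so the overall size difference stays ≤ 1.

Exploratory solutions are extracted per block by maximum-likelihood
factor analysis (scikit-learn) on standardised complete cases and
rotated in-house: classical varimax, and direct oblimin via the
gradient-projection algorithm. Cross-block loadings are fixed to zero;
blocks communicate only through factor correlations, which are
estimated from regression-method factor scores on joint complete cases
(a pragmatic stand-in for a full exploratory-SEM estimator, which no
installed library provides; within-block correlations come from the
rotation itself). Loadings with |λ| > 0.1 (strict) become free CFA
parameters; measures with no retained loading are dropped with a
warning.

Both rotations' CFA specs are confirmed on the holdout half; the
winner has the lowest RMSEA, ties broken by higher CFI and then by
parsimony (more residual df). The parsimony tie-break matters: when the
generating model is exactly true both candidates can reach the
perfect-fit corner, and the varimax-derived spec — which smears
secondary loadings above the 0.1 retention threshold whenever factors
are substantially correlated — would otherwise win arbitrarily. The
full-sample refit reports bootstrap SEs (default 1000 replicates at the
library level; the orchestration layer defaults to 0 and makes the
count a config entry, since desk-scale runs do not need them) and flags
standardised |loadings| and |factor correlations| above 0.3 (strict).

## Screening statistics

Incremental R² is `R²_full − R²_reduced` from least-squares fits on
complete cases, with the nested-model F statistic on the residual sums
of squares. Ordinal predictors enter as integer-coded linear terms
(1/2/3, reverse-coded so higher means greater ability). A confounder
PGS joins the covariates of *both* models. Predictors whose best
incremental R² across outcomes stays below 1% are dropped from
multivariate modelling (boundary retained).

Ordinal outcomes use proportional-odds logistic regression
(statsmodels `OrderedModel`, cumulative logit, shared slopes).
Nagelkerke-R² for a model is computed against the intercept-only null,

    R²_N = [1 − exp((2/n)(LL_null − LL_model))] / [1 − exp((2/n) LL_null)],

and the incremental value is the difference between the full
(covariates + PGS) and reduced (covariates) models, both against the
same null — the convention of the polygenic-score literature; the
p-value is the 1-df likelihood-ratio test.

The effective number of independent tests comes from the eigenvalues
of the phenotype correlation matrix: Li–Ji
(`Meff = Σ [I(λᵢ≥1) + (λᵢ−⌊λᵢ⌋)]`, the default) or Nyholt
(`1 + (M−1)(1 − Var(λ)/M)`). The integer used for thresholding is the
ceiling of the raw value — rounding down would assume fewer independent
tests than the spectrum supports and be anti-conservative. Power for
the 1-df polygenic association test uses the noncentral χ² with
`NCP = n·r²/(1−r²)`; it deliberately models only target-sample noise,
not discovery-GWAS noise.

## Polygenic scoring and GWAS-by-subtraction

Scores are weighted dosage sums over the SNPs shared between a weight
table (PRS-CS-style 6-column layout; externally shrunk weights are an
input, the shrinkage itself is not reimplemented) and the genotype
panel, after harmonisation: sign flips where alleles are swapped,
removal of strand-ambiguous (A/T, C/G) and unresolvable pairs, all
counted and logged. An unknown other-allele (as in PLINK `.raw`
exports) is treated as a wildcard, with orientation decided by the
effect allele. Missing dosages are imputed to 2·MAF. Scores are
Z-standardised; a zero-variance raw score is an error, not a silent
column of zeros. A naive LD-agnostic fallback converts summary
statistics to weights scaled to a target score variance, for synthetic
runs only.

GWAS-by-subtraction takes the 2×2 genetic covariance `S` (confounder
first; normally an LD-score-regression estimate, supplied as input) and
its Cholesky factor `L`. The subtracted per-SNP effect is
`β_trait − (l₂₁/l₁₁)·β_conf` with delta-method SE
`sqrt(se_t² + (l₂₁/l₁₁)²·se_c²)`. The latent-path solve (which divides
by `l₂₂`) errors when the focal trait is fully explained by the
confounder; the subtraction itself tolerates that limit, where every
subtracted effect is 0 by construction. Effective sample size for a
standardised trait is the mean of `1/(2p(1−p)·se²)` over SNPs with MAF
in a 10–40% window (configurable).

## Synthetic cohort generator

The generator defines the study conditions. Defaults: N = 5873; the
three-factor structure with standardised loadings 0.55/0.74/0.54
(musicality: sing/hum/clap at 5y), 0.61/0.64/0.20 (cognition: nonword
repetition/verbal IQ at 9y, appropriate initiation at 10y),
0.55/0.59/0.40 (speech: intelligibility/syntax/rapport at 10y) and
factor correlations 0.31/0.42/0.56; preschool items ordinalised at the
descriptive category frequencies of the source cohort (e.g. clap:
403/1003/4562 of 5968); polygenic paths a = 0.09 on musicality and
b = 0.06 on the outcome factors where a score is attached, matching
incremental R² in the 0.004–0.011 range actually observed for such
scores.

Each measure is `λ·F + covariate effects + ε` with residual variance
`1−λ²` (unit total variance before ordinalisation); factors are
multivariate normal, and when PGS paths are set each factor is
`a·PGS + disturbance` with disturbance covariances chosen so the total
factor correlations still match the configuration. Covariate effects
default to zero — the analysis residualises them out, and nonzero
values exist only to exercise that machinery. The age covariate is
drawn around the preschool assessment wave (mean 4.78 y, SD 0.07).
Missingness is masked completely at random per measure; real cohort
attrition is monotone and outcome-related, so MCAR is a stand-in and
nothing here validates robustness to informative dropout. Genotypes
are in linkage equilibrium (dosages Binomial(2, MAF), unambiguous
allele pairs); weights are rescaled so the raw score variance equals
the target incremental R². Summary-statistic pairs draw per-SNP effects
bivariate-normal with the requested across-SNP covariance and SEs of
`1/sqrt(2p(1−p)N)`; per-SNP sampling noise is not added, so the
empirical effect covariance matches the input by construction.

Because the generator and the fitted models share their functional
form, passing tests demonstrate estimator correctness, calibration and
pipeline integrity — not robustness to the misspecification,
informative missingness, LD structure or measurement error of real
cohort data.

## Problem sizes and determinism

Simulation experiments run at the analysis scale (N = 5873, 9
measures) where estimation takes well under a second; Monte-Carlo
checks average over 5–50 replicates chosen so the replication error of
the experiment sits well below the tolerance being checked (for the
simulate-and-refit recovery, 5 replicates put the mean's error near
0.007 against a ±0.04 window). Every random draw descends from an
explicit integer seed; the pipeline derives per-stage seeds from one
master seed via `SeedSequence`, and equal configs reproduce equal
artefact hashes.

## Known limitations

- Ordinal items as continuous: attenuation for skewed items; no
  threshold-model estimation.
- No full-information ML; listwise deletion per model.
- The exploratory stage approximates exploratory-SEM by per-block EFA
  plus factor-score correlations rather than joint estimation.
- Delta-method product SEs use the independence approximation
  `SE(a·b) = sqrt(a²SE_b² + b²SE_a²)`; the bootstrap option drops that
  approximation.
- LD, population structure, relatedness and imputation uncertainty are
  out of scope throughout.
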