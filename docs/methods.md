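# Methods

## Estimators

**Weighted genetic risk score.** The instrument is
`GRS_i = Σ_j d_ij w_j`, with `d_ij` the count (0–2) of the urate-increasing
allele and `w_j` the per-allele serum-urate effect in µmol/L. The four
default weights are 27.555 (rs1481012), 16.945 (rs2231137), 24.654
(rs16890979) and 7.456 (rs3799352) after orientation. Two of the source
betas are negative (they were estimated for the urate-*lowering* allele);
the loader flips those SNPs to the complementary allele and takes the
absolute weight, so the score is monotone in genetic urate burden and its
attainable range is [0, 153.220]. A signed-weight reading — coding risk
alleles 0–2 but multiplying by signed betas — would make two risk alleles
*lower* the score, which is why orientation happens at load; the raw
signed file is still accepted and re-oriented. The effect/other alleles
shipped with the default weights come from the source genetic-association
study of this cohort and are user-overridable through any weights TSV.
An unweighted allele-count score (range 0–8) is available for sensitivity
analyses; the weighted score is the default instrument because it weights
each SNP by its information about the exposure.

**Missing dosages** are handled complete-case by default (a subject with
any missing dosage gets a missing score and drops out of score-dependent
analyses); mean-dosage imputation is available behind a flag. Complete-case
is the conservative choice when the missingness mechanism is unknown.

**OLS arm.** Classical linear regression with an always-included intercept,
homoskedastic standard errors `sqrt(σ̂² [(XᵀX)⁻¹]_jj)` with
`σ̂² = RSS/(n−k)`, and two-sided t p-values at `n−k` degrees of freedom.
An HC1 robust-SE switch exists but is off by default, matching the
classical reporting convention of the analysis this package implements.
No multiple-testing correction is applied anywhere. Fits are delegated to
statsmodels behind the `AdjustedOLS` surface; rank deficiency is detected
first via pivoted QR and reported as a hard error naming the collinear
columns.

**Two-stage least squares.** Stage 1 projects the exposure on
[1, instruments, covariates]; stage 2 regresses the outcome on
[1, fitted exposure, covariates]. The error variance uses *structural*
residuals `y − W_actual β̂` (actual exposure, not stage-2 fitted values)
with the stage-2 Gram matrix — using second-stage residuals is the classic
2SLS mistake and misstates the variance. Inference is t with `n−k` degrees
of freedom by default (`df_mode="asymptotic"` switches to normal). With a
single instrument and no covariates the estimate reduces exactly to the
Wald ratio cov(z,y)/cov(z,x); the test suite checks both this identity and
full numerical agreement (β, SE, p) with statsmodels' independent IV2SLS
implementation.

**First-stage diagnostics.** The headline F and R² come from the
*univariate* exposure~instrument regression, which obeys
`F = (R²/(1−R²))(n−2)` exactly — the convention under which the study
strata's printed (F, R², n) triples are mutually consistent. The
covariate-adjusted partial F (squared t of the instrument) is computed
alongside. `F < 10` (strictly) sets the weak-instrument flag. An
instrument numerically identical to the exposure is rejected as a
degenerate diagnostic, except inside the 2SLS fitter where it legitimately
collapses the estimator to OLS.

**Durbin–Hausman test.** Default is the contrast form
`H = (β_2SLS − β_OLS)²/(se²_2SLS − se²_OLS)` on χ²(1); both fits must share
subjects and adjustment set. OLS is efficient under exogeneity, so the
variance difference should be positive; when a finite sample delivers a
non-positive difference the augmented (control-function) form is used
instead and the fallback recorded: regress exposure on instrument +
covariates, add the residual v̂ to the outcome regression, and refer the
squared t of v̂ to χ²(1). The two forms agree closely on well-behaved data
(checked by simulation), but under an exact null the contrast form is
conservative — the variance difference hovers around zero — so size
(type-I error) calibration is checked with the augmented form, which is
exactly sized. Significance at α = 0.05 sets the decision to
`use_tsls`. Note one published crude-stratum p of 0.053 sits exactly at
the boundary; the implementation reports raw p and applies the strict
p < 0.05 rule.

## Analysis pipeline

Subjects on urate-lowering drugs are excluded at load (counted in the join
report), as are subjects with missing — or non-positive, hence unusable —
exposure or outcome. Subgroups are the sex strata and the serum-urate
strata (hyperuricemia strictly > 417 µmol/L; SU = 417 goes to the normal
group), and their crossings: 9 strata in all, each fitted crude
(intercept + SU) and adjusted. The default adjustment set is age, sex,
BMI, BUN, FBG; sex is dropped automatically inside single-sex strata. The
per-confounder independence checks adjust each confounder for the
remaining covariates; the exact adjustment set is recorded with every run.
Strata smaller than `min_n` (default 30) are emitted with an explicit
`insufficient_n` marker rather than dropped. A per-SNP pass repeats first
stage + 2SLS + DWH with each single dosage as instrument, carrying the
weak-instrument flag; monomorphic SNPs are marked degenerate. Subgroup
analyses reuse the fixed pooled weights (standard MR practice; nothing is
refit per stratum). All outputs are written with fixed float formatting
and no timestamps, so identical inputs + config + seed reproduce
byte-identical files.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* genotypes: independent binomial(2, MAF) draws (Hardy–Weinberg, linkage
  equilibrium). MAFs are not published for this cohort; the defaults
  0.3/0.3/0.05/0.2 are placeholders chosen to keep the risk-score variance
  budget attainable, and are configurable.
* covariates: sex ~ Bernoulli(0.723 male); age, BMI, FBG, BUN Gaussian at
  the cohort's marginal moments, truncated to positive by resampling (no
  point mass at zero). Covariates are mutually independent — real
  correlations (e.g. BMI–FBG) are unknown from the published marginals.
* structural equations, with U ~ N(0,1) a latent (unmeasured) confounder:

  ```
  SU   = 347.24 + c·(GRS − E GRS) + a·U + ε_su
  TBIL = 19.25  + β·(SU − 347.24) + b·U + 3.0·(male − p_male) + ε_tbil
  ```

  `c` is solved so the score explains exactly `grs_r2` (default 0.031) of
  the SU variance at total SD 101.07; residual variances close each budget,
  and an infeasible budget (components exceeding the target variance) is a
  hard error stating the shortfall. The true effect β defaults to −0.021
  µmol/L TBIL per µmol/L SU. The confounder loadings default to `a = 40`
  µmol/L SU per SD of U with `b` solved from the omitted-variable bias
  formula `bias = a·b/Var(SU)` so naive OLS lands near +0.003 — a
  calibration convenience reproducing the qualitative OLS/2SLS contrast,
  not a published quantity. The direct male TBIL shift (+3 µmol/L)
  emulates the observed sex difference.

SU and TBIL themselves are *not* truncated: truncating the outcome would
attenuate the structural slope away from β and break parameter recovery,
which is the generator's defining contract. At the study moments about 1 %
of simulated TBIL values fall at or below zero; in-memory analyses see the
exact linear-Gaussian model, while cohorts that round-trip through files
have those rows dropped (and counted) by the loader, a ~1 % selection the
file-based path accepts. SU sits ~5 SD above zero, so this is immaterial
for the exposure.

What passing tests on these cohorts do **not** show about real data: no
linkage disequilibrium or population stratification, no genotype error, no
covariate correlations, Gaussian (not skewed) biomarker distributions, and
a single scalar confounder. The generator validates the estimators'
statistical behaviour, not the biology.

## Problem sizes and numerical choices

Simulation-based checks use: 200 replicates per stratum for first-stage F
calibration; 500 replicates at n = 3,753 for parameter recovery and DWH
power; 1,000 replicates at n = 800 for DWH size (type-I error); 1,000
random small datasets for the Wald-ratio identity (tolerance 1e-10
relative); 200 replicates at n = 2,000 for contrast-vs-augmented
agreement. Replicate seeds are spawned from a single user seed via
`numpy.random.SeedSequence`, so every figure is reproducible from one
integer. Ties and degenerate inputs: constant instruments, monomorphic
SNPs, rank-deficient designs and perfect instruments all raise explicit
errors (or emit marked rows in the pipeline) rather than propagating NaNs.

## Known limitations

* Single endogenous regressor only; no over-identification tests (the
  composite score is one instrument), no LIML/Fuller weak-instrument
  corrections, and no summary-statistic MR estimators (IVW, MR-Egger,
  weighted median).
* Pleiotropy is addressed only through the measured-confounder
  independence checks; a variant affecting TBIL through a non-urate
  pathway would bias the estimate undetected.
* The VCF reader handles biallelic GT-only records matched by rsID; no
  liftover, dbSNP lookup, LD pruning or reference-panel imputation.
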