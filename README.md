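# uratemr

Mendelian-randomization analysis of the effect of serum urate (SU) on total
bilirubin (TBIL), with a synthetic-cohort generator for validating every
stage of the analysis.

## The problem

Observational studies disagree on whether serum urate is associated with
bilirubin, and any observed association is vulnerable to confounding
(lifestyle, body composition, medication, baseline health) and reverse
causation. Mendelian randomization sidesteps this by using genetic variants
— randomly assorted at conception, hence independent of later confounders —
as *instrumental variables* for the exposure. Here the instrument is a
weighted genetic risk score (GRS) built from four urate-transporter SNPs
(*ABCG2* rs1481012 and rs2231137, *SLC2A9* rs16890979, *SLC17A1* rs3799352):

```
GRS_i = Σ_j  dosage_ij × w_j
```

where `dosage_ij ∈ {0,1,2}` counts subject *i*'s copies of SNP *j*'s
urate-increasing allele and `w_j` is that allele's per-allele SU effect
(µmol/L). The causal effect β of SU on TBIL is estimated by two-stage least
squares (2SLS):

1. first stage: `SU ~ GRS + covariates`, giving fitted exposure `SU-hat`;
2. second stage: `TBIL ~ SU-hat + covariates`; the coefficient on `SU-hat`
   is β, with standard errors computed from structural residuals
   (`TBIL − Xβ` using the *actual* SU).

Instrument validity is checked by the first-stage F statistic (F > 10 for a
non-weak instrument; `F = (R²/(1−R²))(n−2)` in the univariate first stage)
and by regressing the GRS against each measured confounder. The
Durbin–Hausman test compares the OLS and 2SLS estimates: a significant
difference indicates the exposure is endogenous and the 2SLS estimate is
the one to trust,

```
H = (β_2SLS − β_OLS)² / (se²_2SLS − se²_OLS)   ~  χ²(1).
```

The package is organised as scikit-learn-style estimators —
`GeneticRiskScore` (transformer), `AdjustedOLS` and `TwoStageLeastSquares`
(regressors with `fit`/`predict` and `coef_`/`se_`/`pvalues_` attributes) —
with thin functional wrappers (`weighted_grs`, `ols_fit`, `tsls_fit`,
`first_stage`, `dwh_contrast`, `dwh_augmented`) and a pipeline
(`run_analysis`, `per_snp_analysis`, `instrument_diagnostics`) that emits
tidy per-subgroup result tables. Because the original cohort is not public,
`uratemr.synthetic` generates cohorts with the study's marginal structure
(n = 3,753, SU 347.24 ± 101.07 µmol/L, TBIL 19.25 ± 8.21 µmol/L, GRS
explaining 3.1 % of SU variance) plus a latent confounder that biases OLS —
so parameter recovery, test calibration and power are all checkable.

## Worked example

```python
from uratemr import SimParams, simulate_cohort, weighted_grs, \
    ols_fit, tsls_fit, first_stage, dwh_contrast
from uratemr.pipeline import design_covariates

params = SimParams()                       # study-cohort conditions
cohort = simulate_cohort(params, seed=1)
score = weighted_grs(cohort, list(params.weights))
C, names = design_covariates(cohort, ("age", "sex", "bmi", "bun", "fbg"))

fs = first_stage(cohort["su"], score)
ols = ols_fit(cohort["tbil"], cohort["su"], covariates=C,
              term="su", covariate_names=names)
tsls = tsls_fit(cohort["tbil"], cohort["su"], score,
                covariates=C, covariate_names=names)
dwh = dwh_contrast(ols, tsls, fallback_data=(cohort["tbil"], cohort["su"],
                                             score, C))
print(f"first-stage F = {fs.f_stat:.1f}, R2 = {fs.r2:.3f}")
print(f"OLS  beta = {ols.beta:+.4f} (se {ols.se:.4f}, p {ols.p:.3f})")
print(f"2SLS beta = {tsls.beta:+.4f} (se {tsls.se:.4f}, p {tsls.p:.4f})")
print(f"Durbin-Hausman p = {dwh.p:.4f} -> {dwh.decision}")
```

Output:

```
first-stage F = 118.2, R2 = 0.031
OLS  beta = +0.0018 (se 0.0013, p 0.180)
2SLS beta = -0.0260 (se 0.0080, p 0.0012)
Durbin-Hausman p = 0.0005 -> use_tsls
```

The instrument is strong (F ≈ 118 ≫ 10). Naive OLS reports a slightly
*positive* SU–TBIL slope — the confounder at work — while 2SLS recovers a
negative causal effect near the generator's truth (−0.021 µmol/L TBIL per
µmol/L SU), and the Durbin–Hausman test rejects exogeneity, so the 2SLS
estimate is the one to report.

The same analysis runs from the shell on TSV (or VCF) inputs:

```sh
uratemr simulate --n 3753 --seed 1 --out data/
uratemr run --genotypes data/genotypes.tsv --pheno data/phenotypes.tsv \
            --out results/
```

producing `results.tsv` (per-subgroup OLS/2SLS/DWH rows, including sex and
hyperuricemia strata split strictly above 417 µmol/L),
`instrument_diagnostics.tsv`, `per_snp.tsv` (single-SNP instruments with
weak-instrument flags), `run_log.txt` and `config_resolved.yaml`.

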