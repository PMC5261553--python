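# Methods

## Design

Intergenerational MR estimates the causal effect of an intrauterine
exposure — maternal pregnancy BMI — on an offspring outcome, using the
mother's BMI-associated variants as instruments.  The estimand throughout is
`beta_int`, the SD change in offspring outcome per SD of maternal BMI.  The
offspring's own weighted allele score is included in the IV model to block
the direct transmission path; the package treats the resulting collider
problem (below) as a first-class object of study rather than a footnote.

## Generative model

`synthetic_trios.simulate_cohort` draws, per family and per SNP, four
parental haplotype alleles ~ Bernoulli(p_j) (Hardy–Weinberg, unlinked loci,
random mating) and one fair-coin transmission per parent.  Weighted scores
Z = Σ_j w_j·dosage_j are centred and scaled by their theoretical moments
(mean Σ 2p_j w_j, variance Σ w_j²·2p_j(1−p_j)), giving Z* with unit
variance and parent–offspring score correlation exactly ½.  Phenotypes:

    X_m = √rho2_m·Z*_m + c_x·C + e_x                    Var(X_m) = 1
    X_f = √rho2_m·Z*_f + c_x·C + e_f                    Var(X_f) = 1
    Y_o = beta_int·X_m + lambda_o·Z*_o + beta_pat·X_f
          + c_y·C + delta·P_m + e_y                     Var(Y_o) = 1

C ~ N(0,1) is shared within family; P_m is the centred maternal allele
count (delta injects constant per-allele directional pleiotropy).  The
residual outcome variance is solved exactly from the model's second
moments; a parameter set whose structural terms exceed unit variance raises
a "variance budget" error rather than silently rescaling.  All phenotypes
are generated directly on the SD scale so estimates are directly comparable
to `beta_int`.

### Default study conditions (chosen once)

| parameter | default | rationale |
|---|---|---|
| panel | 32 unlinked SNPs, w_j ~ U(0.02, 0.10) SD/allele, p_j ~ U(0.1, 0.9) | size and effect-size range of the published BMI hit panels |
| rho2_m | 0.022 | instrument strength reported for the maternal BMI score |
| lambda_o | 0.15 (≈ √0.022) | offspring score explains ~2.2 % of own BMI, mirroring the maternal instrument |
| c_x, c_y | 0.3 | moderate shared familial confounding; biases naive OLS by c_x·c_y ≈ 0.09 SD, the order of the observed multivariable–MR gap |
| beta_pat | 0 | paternal phenotype path off unless a scenario opens it |

What the generator deliberately omits: linkage disequilibrium, imputation
uncertainty and genotyping error, assortative mating, X-chromosome loci,
ancestry structure.  Passing tests therefore demonstrate estimator
correctness under the design's own assumptions, not robustness to those
real-data complications; random mating is an explicit extension point.

## Estimators and numerical choices

* **OLS / TSLS.** Classical homoskedastic SEs by default (plain 95 %
  normal-theory CIs); `robust=True` switches to HC sandwich SEs.  TSLS SEs
  use stage-2 residuals recomputed with the observed exposure.  Complete
  cases per model (listwise deletion), so n legitimately varies across
  models.  Rank-deficient designs raise with the collinear column names
  (pivoted-QR detection).  First-stage diagnostics are the partial R² and
  partial F of the instruments given the included covariates,
  F = R²(n−k−c−1)/(k(1−R²)); a perfect instrument yields F = ∞ rather than
  a division error.
* **Bootstrap z-test.** Families are the independent unit, so resampling is
  family-level; B = 1,000 by default, seed mandatory.  When the instrument
  reproduces the exposure the OLS and IV estimators coincide in every
  replicate and the variance of their difference is exactly zero; the test
  then returns (z, p) = (0, 1) instead of 0/0.  A zero bootstrap variance
  with a nonzero point difference still raises.
* **Wald ratios.** First-order delta SE (se_zy/|β_zx|); adequate in the
  strong-instrument regime (first-stage F ≫ 10) this design operates in.
* **MR-Egger.** Associations are oriented to β_zx ≥ 0 before fitting;
  weights 1/se_zy²; SEs and p-values follow the weighted-lm convention
  (t with k−2 df), matching the standard summary-MR implementations.
  Per-SNP outcome associations are computed with offspring-score
  adjustment, mirroring the offspring-adjusted IV models.
* **Pooled two-stage ratio.** Stage-1 and stage-2 coefficients are pooled
  by fixed-effects IVW separately; their ratio carries the first-order
  Taylor SE √(se₂²/b₁² + b₂²·se₁²/b₁⁴).  The within-cohort covariance of
  the two stage coefficients is omitted — the result label carries a
  `taylor_se_omits_stage_covariance` flag, and a simulation test checks the
  pooled ratio against individual-level TSLS on concatenated data.
* **Internal z-scores.** Sample SD (divisor n−1), the convention in cohort
  analyses; maternal strata are age-in-years, offspring strata sex ×
  age-in-months.  Singleton or constant strata are hard errors naming the
  stratum.
* **Score rescaling with missing SNPs** uses per-person availability (the
  rescaling formula's "SNPs available" read per person); the simulator
  emits complete data, so this path is exercised by fixtures.
* **Transmission inference from real trios** is attempted only where
  unambiguous (not mother, father and child all heterozygous); ambiguous
  records are excluded from haplotype scores with a logged count.  No
  statistical phasing is implemented.
* **Power.** `power_mr` uses the asymptotic normal approximation for the IV
  estimator on standardised variables, SE ≈ 1/√(n·rho2):
  power = Φ(√(n·rho2)|β| − z_{1−α/2}) + Φ(−√(n·rho2)|β| − z_{1−α/2}).
  This is the package's own documented choice of formula.

## The collider study

Conditioning on the offspring score Z*_o induces, by linear projection on
the exact score covariances (corr(Z*_m, Z*_o) = corr(Z*_f, Z*_o) = ½), a
coefficient of −⅓ for Z*_f on Z*_m given Z*_o.  A paternal phenotype effect
`beta_pat` therefore biases the offspring-adjusted IV estimate by exactly
−beta_pat/3 — toward the null for positive effects and monotone in
`beta_pat` — while adding the paternal score as a covariate blocks the path
and restores recovery, and the non-transmitted-haplotype instrument is
immune (it never requires the offspring-score adjustment).
`run_sim_study` verifies all three behaviours empirically and reports, per
scenario × estimator, the mean estimate, empirical SD, mean model SE, bias,
95 % CI coverage and the Monte-Carlo SE of the mean; acceptance bands are
expressed in Monte-Carlo SEs rather than fixed tolerances.  In the
simulation study the "non_transmitted" estimator is TSLS with the
non-transmitted haplotype score as instrument, so its output is on the
`beta_int` scale; the separate `non_transmitted_regression` operation
returns the joint transmitted/non-transmitted coefficients themselves.

## Problem sizes

Replicate counts and cohort sizes were fixed a priori: parameter-recovery
runs use 1,000 replicates of n = 5,000 trios (Monte-Carlo SE of the
coverage proportion ≈ 0.7 %, comfortably inside the [93 %, 97 %] coverage
band's half-width); the collider grid uses beta_pat ∈ {0.1, 0.2, 0.3} with
300 replicates at n = 3,000; Egger-intercept calibration uses 1,500
replicate null cohorts of n = 2,000 trios.  The acceptance script uses 500
recovery and 1,000 calibration replicates, which keeps its end-to-end run
under a minute while leaving Monte-Carlo noise well below the effects being
demonstrated.

## Known limitations

* The per-SNP instruments are individually weak (per-SNP F ≈ 1–2 at these
  panel sizes); only the aggregate score is a strong instrument.  MR-Egger
  slopes are mildly regression-diluted at moderate n as a consequence; the
  calibration of the *intercept test* under the null is unaffected and is
  what the tests pin down.
* The Taylor SE of the pooled ratio ignores the stage-1/stage-2 covariance
  (flagged in output); with strong instruments the omission is second
  order.
* `power_mr` is an asymptotic approximation that ignores the offspring-
  score adjustment's reduction of effective instrument strength (the
  partial R² given Z*_o is ¾ of the marginal R²); power statements for
  offspring-adjusted models should use the partial R².
* Determinism is guaranteed per (inputs, config, seed) on a fixed platform;
  bit-identity across BLAS builds is not promised.
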