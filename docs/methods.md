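# Methods

This note documents the statistical models implemented in `serogx`, the
generative model behind the synthetic cohorts used to validate them, the
numerical choices that matter, and the limits of what the test suite can
show about real data.

## The analysis model

### Assay cleaning and residualization

Raw assay values are colorimetric ratios standardized to 1.0 per microtiter
plate, so they are strictly positive with residual batch structure.
Cleaning proceeds in a fixed order: (1) outlier-plate exclusion, (2) zero
removal, (3) log2 transform, (4) mixed-model residualization.  The order
matters — a genuinely failed plate would otherwise contaminate the
residualizer's variance components.

*Outlier plates.* For each plate and analyte, the plate's log2 values are
compared to the pooled remainder with a two-sample Kolmogorov–Smirnov test;
a plate is flagged if any analyte's p-value falls below the Bonferroni
level α/(n_plates × n_analytes).  KS was chosen because the screening
target is any "distribution difference", not a location shift; the
Bonferroni correction holds the family-wise false-flag rate at α, so about
one cohort in twenty will flag a clean plate — the cost of a detector with
guaranteed error control rather than a tuned heuristic.  Plates with fewer
than three observations are skipped, never flagged.

*Residualization.* Each analyte is fitted independently with
`log2(y) = β0 + β1·storage_years + u_plate + e`, `u ~ N(0, σ²_u)`,
`e ~ N(0, σ²_e)`, by REML.  With a single random intercept, V = I + λZZ′
has a closed-form blockwise inverse (λ = σ²_u/σ²_e), so the REML criterion
is profiled to a 1-D function of λ and minimized by bounded scalar search
on log λ over [e⁻¹⁶, e¹⁰] (xatol 1e-10).  BLUPs take the classical
shrinkage form u_j = λn_j/(1+λn_j) · (mean within-plate GLS residual), and
the returned residual is y − Xβ̂ − û; by the GLS normal equations these
residuals sum exactly to zero.  With fewer than three plates the model
degrades to fixed-effect plate dummies (a logged fallback), since a
variance component estimated from two levels is meaningless.  The test
suite checks the optimizer against a dense-matrix brute-force grid search
of the same criterion (agreement < 1e-6 in −2·log-likelihood) and against
statsmodels' MixedLM.

### Seropositivity thresholding

A Gaussian KDE (Silverman bandwidth by default, overridable in data units)
is evaluated on a 512-point grid padded three bandwidths beyond the data
range.  The distribution is declared bimodal iff the two tallest local
maxima each reach 10% of the global density maximum (the prominence
fraction, configurable) and the minimum between them lies below 90% of the
lower peak.  The threshold is the grid argmin strictly between the peaks;
exact ties resolve to the midpoint of the tied region, and values exactly
at the threshold are seronegative (a stated convention, since densities
give no guidance at a point).  This is deliberately the valley-of-KDE rule
rather than an EM mixture fit or a dip test: the procedure being emulated
is threshold-at-the-valley, and the tests show it tracks the analytic
valley of known two-Gaussian mixtures within ±0.3 and misclassifies within
3 percentage points of the Bayes rate.  Analytes can be pinned
binary/continuous in configuration (`STUDY_PINNING` reproduces the fixed
anti-TOXO/HSV1/CMV vs anti-HHV6/GLD/CRP assignment); auto-detection is the
default.

### Group comparisons and one-sided testing

Each case/parent group is compared to controls only (no pooled multi-group
model), with age at blood draw and sex entering linearly and additively.
Continuous features use OLS with Wald t tests; binarized features use
logistic regression with Wald z tests.  All p-values are upper-tail
one-sided — the prior hypothesis is elevation in cases and their relatives
— so a wrong-direction effect can at best reach p = 0.5 and is displayed as
"n/a".  Wald (not likelihood-ratio) statistics are used because the
reported quantity is the β ± SE pair.  Binary cells with an empty
seropositive or seronegative arm are reported as non-estimable rather than
fitted; suspected separation is flagged.  The 36-cell multiple-comparison
ledger uses Bonferroni: 0.05/36 ≈ 0.0014.

### Linked within-sex permutation enrichment

The evidence in the comparison table is cumulative rather than cellwise, so
two summary statistics are tested: the count of nominally significant
antibody cells (CRP excluded; 30 cells) and the count with positive β.  The
null re-links status to the serology block uniformly at random *within sex*
— the table splits vertically into (antibody features + age) and (status);
the status sub-table is re-ordered within each sex stratum.  Age stays
attached to the features (it is a property of the blood draw), sex stays
attached to both sides by stratification, and the full covariate-adjusted
comparison stage is re-fitted per permutation.  Empirical p = k/N with ties
counted toward k; a (k+1)/(N+1) option exists behind a flag.  Replicates
with any failed cell fit are dropped with the denominator adjusted (warned
above 1%).  Permuting the status block rather than the feature block is a
recorded arbitrary choice — the two are distributionally identical.

### Genotype QC and the interaction scan

The QC cascade runs in a fixed, order-sensitive sequence: SNPs > 5%
missing; then subjects > 2% missing; then SNPs > 2% missing; then HWE
p < 10⁻⁶ (1-df chi-square on pooled genotype counts by default, an exact
enumeration test as an option — the chi-square is adequate at MAF ≥ 0.05
and n ≈ 10³); then MAF < 0.05.  Each step's removals are reported, and a
step that empties the SNP set raises an error naming itself.

The scan fits, per SNP, `phenotype ~ g + s + g·s + age + sex` by
Newton/IRLS with convergence tolerance 1e-8 on the maximum coefficient
change and a 50-iteration cap, additively coded minor-allele dosage,
complete-case per SNP (missing dosages are zero-weighted; no imputation).
Parents are excluded — the scan is case–control.  The per-SNP fits are
vectorized: a batched IRLS solves all SNP models in a chunk simultaneously
(shared covariate columns, per-SNP genotype and product columns), which is
what makes 10⁵-scale permutation and calibration runs affordable.
Rank-deficient designs (e.g. constant serology making g·s collinear with g)
raise a degenerate-design error in the single-SNP path and are flagged, not
fatal, in the scan.  Two significance tiers are flagged (5×10⁻⁸/6 ≈
8.3×10⁻⁹ genome-wide; 10⁻⁵ suggestive) and λ_GC (median interaction
chi-square over 0.455) is reported as the calibration diagnostic.

### SNP-set enrichment under LD

For a pre-specified SNP set the statistic is the count of members with
interaction p < α (same two-sided Wald p as the scan — a recorded choice,
since "nominally significant" does not state sidedness).  The null permutes
phenotype labels within sex strata while genotypes, serology and age stay
attached to subjects: LD between set members and any genotype–exposure
dependence survive, only the phenotype link is broken.  Duplicating the
whole set doubles the observed count and every permutation count, leaving
the empirical p bit-identical — the defining robustness property (for a
single duplicated SNP the p can move by at most the tie mass at the
observed count).  Both the raw empirical p and a ×K Bonferroni-corrected
value (K = number of serology variables screened) are reported.

## The synthetic-data generator

The generator is first-class, tested code defining the study conditions
under which the pipeline is validated.

*Cohort structure.* Default group sizes are 580 SZ, 262 SZ fathers, 266 SZ
mothers, 489 BP, 314 BP fathers, 314 BP mothers, 362 controls (2,587
subjects) on 32 plates.  `with_failed_plate()` adds 73 technical-failure
records confined to a designated plate with a +3 log2 shift, so the raw
table holds 2,660 records and returns to 2,587 once cleaning excludes the
plate — the generator's emulation of the source accounting, whose printed
totals (2,660 raw; group sizes summing 2,587) do not otherwise decompose.

*Assay model.* For analyte a of subject i the latent log2 value is
`component draw + age_slope_a·(age−45) + sex_shift_a·[male] +
storage_slope·(storage−mean) + plate effect`, and the raw ratio is 2^latent
with a 0.5% zero (failed-assay) rate.  Plate intercepts are drawn
independently per analyte (each analyte is its own assay pass) with SD 0.06
— small because the ratios are already plate-standardized upstream, and
consistent with a study in which exactly one of 32 plates was distinct
enough to flag.  Age slopes are positive for all analytes except anti-HHV6
(negative), male shifts are negative (strongest for HHV6 and CMV), and
storage drift is +0.05/year, matching the direction of the reported
covariate effects.

*Group effects on two scales.*  For the three continuous analytes the group
effect is an additive latent shift in log2 units.  For the three bimodal
analytes it shifts the seroprevalence log-odds (the mixture weight's
logit), not the latent mean: the downstream model for these analytes is a
logistic regression on serostatus, so configuring effects on the logit
scale makes generator truth and fitted coefficient directly commensurable —
an additive latent shift would induce an attenuated log-odds effect of
uncontrolled size.  Default effect values are the published point estimates
of the emulated study (e.g. CRP +1.04 in SZ, +0.42 in BP; HSV1 +0.48 in BP
mothers), so a faithful re-analysis recovers them within its standard
errors.  Component locations/scales and seroprevalences (TOXO 0.13, HSV1
0.75, CMV 0.78; continuous SDs 1.35/1.20/1.80) were set so the fitted
standard errors match the published precision, and mixture components are
separated enough that valley thresholding misclassifies ~2%.

*Ages and storage.* Age distributions are assumptions (none are published):
probands ~N(42,13), parents ~N(60,12), controls ~N(50,15), truncated at 18.
The parent–control gap is kept moderate; a larger, more literal gap makes
age nearly collinear with parent status and inflates the binary-cell
standard errors well beyond the published ones, which is evidence the
source cohort's age distributions overlapped substantially.  Draw years
span 1996–2011 against a 2012 reference, giving 1–16 storage years.

*Genotypes.* Each haplotype is a latent AR(1) Gaussian within an LD block
(adjacent-SNP correlation `ld_rho`), thresholded at Φ⁻¹(MAF); dosage is the
sum of two independent haplotypes, so HWE holds per SNP by construction.
Note the dosage-scale r² is substantially below the latent ρ² (thresholding
attenuates correlation, more so at low MAF); the tests pin the adjacent-SNP
correlation to the closed-form thresholded-bivariate-normal value.  Disease
labels come from `P(case) = logistic(baseline + Σ main·g + Σ int·g·s)` with
configurable spiked SNPs.  Stacking many strong interaction terms inflates
the latent variance and attenuates every marginal single-SNP fit
(non-collapsibility), so enrichment scenarios use a few spikes in distinct
LD blocks and let block-mates light up through LD.

*What the generator does not emulate*: Mendelian transmission between
parents and probands (groups are simulated marginally, so family structure
contributes no correlation), population stratification, genotyping batch
effects, BMI/smoking confounding of CRP, and any dependence of serology on
genotype except through the spiked disease model.  Passing tests therefore
show the machinery is correct and calibrated under these conditions — not
that real cohorts satisfy them.

## Numerical choices and problem sizes

- Logistic IRLS: tolerance 1e-8 on coefficient change, 50 iterations,
  linear predictors clipped at ±30; |β| > 25 or saturated fits flag
  suspected separation.  The batched solver marks diverging or singular
  SNP models failed and continues.
- Empirical p-values are k/N (ties counted); bit-reproducible given seed,
  with all stage seeds derived from one global seed by fixed offsets.
- Calibration suites run at deliberately reduced sizes chosen as the
  package's own validation budget: 300 null cohorts × 100 permutations for
  both permutation tests' type-I error (binomial 95% band around 0.05),
  100,000 tests for null-scan calibration (Poisson-interval check on
  p < 10⁻⁴ counts and λ_GC ∈ [0.95, 1.05]), n = 4,000 for interaction
  recovery.

## Known limitations

- Directional-consistency enrichment has limited power when the true group
  effects equal published point estimates: the expected direction count is
  ~21–22 of 30, near the permutation null's rejection boundary, because
  point estimates already contain the sampling noise that produced the
  original extreme count.  The significance-count enrichment does not share
  this problem.
- The KS plate screen flags a clean plate in about one cohort in twenty
  (its designed family-wise rate); flagged plates are excluded wholesale,
  so those runs analyze slightly fewer records.
- HWE defaults to the pooled-sample chi-square; a controls-only option is
  not currently exposed.
- Wald and likelihood-ratio interaction p-values agree asymptotically but
  diverge in the extreme tail (|log10 p| ≳ 20), as usual.
- No BMI/smoking adjustment exists anywhere in the pipeline; CRP contrasts
  on real data would carry that confounding.
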