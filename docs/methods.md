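# Methods

This note documents the statistical models behind `prskit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where a published description left
the choice open.

## Cross-ancestry combination

Summary statistics from two ancestries are matched on (chromosome, position)
and aligned to a common effect allele; when the second table's effect allele
equals the first's other allele, its log-OR is negated and its effect-allele
frequency replaced by 1−EAF. Palindromic variants (A/T, C/G) are dropped by
default because strand cannot be resolved from summary data alone; an
override flag keeps them. Positions with incompatible allele sets are dropped
with a reason code, never silently kept.

Per-variant pooling is fixed-effect inverse-variance weighting. The pooled
standard error 1/√(Σw) is never larger than any input SE (tested as an
invariant). LD matrices are blended per block as a convex combination with
weights proportional to total per-ancestry sample size (cases + controls);
convexity preserves symmetry, the unit diagonal, and positive
semidefiniteness. For the exported combined summary-statistics file, EAF is
the total-sample-size-weighted average of the ancestry EAFs and case/control
counts are summed — the published description does not state how these
columns were formed, so this convention (matching the LD-blend weighting) is
this package's own choice.

Running LDpred2 or PRS-CSx themselves is out of scope: the package produces
and consumes their input/output formats only.

## Scoring and the two-PRS combination

Raw PRS = Σⱼ wⱼ·dⱼ′ where dⱼ′ is the dosage of the weight file's effect
allele (d, or 2−d after an allele flip). Missing dosages are imputed with
2×EAF when the weight file carries an allele frequency, otherwise with the
cohort mean dosage of that variant. Scoring is linear in the weights and
invariant to variant order (both tested).

The weighted combination of a European and an Asian PRS is a
maximum-likelihood logistic regression of case status on the two PRSs, each
standardized to unit SD on the training set so the coefficients are
comparable across cohorts. The regression carries no covariates — the
combination is a score-construction step, not an inference — and the
intercept is dropped when the combination is applied, because every
downstream use (AUC, per-SD OR, percentiles) is invariant to a monotone
shift. Perfect separation and near-collinear inputs (|r| > 0.999) raise
errors rather than returning unstable coefficients.

## Trans-ancestry standardization

Principal components are computed from reference-panel dosages centered at
2f and scaled by √(2f(1−f)); loadings are top-k right singular vectors
(k = 4 by default, matching the number of PCs used for the published
adjustment), with each loading's sign fixed so its largest-magnitude entry
is positive — serialized models are then bit-reproducible.

The mean model is OLS of raw PRS on the k PC scores. The variance model is
OLS of the *squared mean-model residuals* on the same PCs: the denominator
of the standardization is a conditional SD around the conditional mean, not
a raw second moment. Because a linear variance model can predict non-positive
values, predictions are floored at 10⁻⁴ × the marginal PRS variance; the
floor only binds for degenerate inputs (e.g. constant PRS). The adjusted PRS
is location-equivariant: adding a constant to every raw PRS and refitting
returns identical adjusted values (tested).

Per-study offsets (for studies whose raw PRS carries a technical shift, such
as a different imputation reference panel) are computed on controls only —
case enrichment differs wildly across study designs, while controls
approximate the population the reference adjustment targets — and shift the
flagged study's cases and controls by the same amount so that its control
mean matches the pooled control mean of the non-flagged studies.

## Discrimination, association and calibration

**Adjusted AUC.** The PRS is residualized on the covariates (age, sex, PCs)
by least squares *fitted among controls* and applied to all samples; the AUC
is the Mann–Whitney statistic of the residualized PRS with ties counted ½.
Residualization removes confounder-driven PRS variation without letting
covariates contribute to discrimination. The SE comes from 500 (default)
bootstrap resamples stratified by case status, each repeating the entire
procedure including the residualization fit; the 95% CI is estimate ±
1.96·SE clipped to [0, 1]. Two-PRS comparisons evaluate both scores on the
same paired resamples and convert the point-estimate difference to a
two-sided p via the normal approximation against the bootstrap SE. Study
pooling is the same IVW estimator used for summary statistics.

**Per-SD OR.** Logistic regression of case status on the PRS scaled to unit
SD within the analysis sample, plus covariates; Wald CI and p. Stratified
estimates (family history yes/no; age <50, 50–59, 60–69, 70–79, >80) rescale
the PRS within each stratum; strata with fewer than 10 cases are skipped
with a warning, and samples with missing family history form their own
category that is excluded from family-history-stratified analyses. The age
trend test is inverse-variance-weighted least squares of log-OR on the
stratum *index* (the open-ended top band has no midpoint; the stated bands
are near-equal width), with a Wald p on the slope.

**Relative-risk percentile curve.** Under a log-linear risk model with a
standard-normal PRS, the risk at percentile p relative to the population
average is RR(p) = exp(β·z_p)/E[exp(β·Z)] = exp(β·z_p − β²/2), β = ln(OR per
SD). This closed form reproduces the four published 90th-percentile relative
risks (1.67, 1.44, 1.65, 1.69) from the published per-SD ORs (1.64, 1.39,
1.62, 1.67) to two decimals; whether the original figure was computed this
way or empirically is not stated, and the closed form is adopted because it
matches all four printed values.

**Calibration.** PRS is cut into twenty 5% bins at type-7 sample quantiles
with ties assigned to the lower bin (a determinism choice); the two middle
bins (40–60%) merge into the reference stratum. The expected OR of a bin is
the ratio of within-bin geometric means of individual model-based ORs,
exp(mean_bin(PRS·β) − mean_ref(PRS·β)); the observed OR is a logistic
regression of case status on the bin-vs-reference indicator plus covariates
with a 95% Wald CI. The reference stratum has observed OR ≡ 1.

## Decision-curve analysis under competing risks

Follow-up is coded 0 = censored, 1 = CRC, 2 = death (competing). The
cumulative incidence I(t) is the Aalen–Johansen estimator, written directly
in the package (a dozen lines) because exact, deterministic tie handling is
needed for reproducibility; it is cross-checked against
`lifelines.AalenJohansenFitter` in the tests.

Per-sample 10-year risks come from cause-specific exponential-hazard
regressions: log λ₁ linear in the predictors (family history alone, or
family history + PRS), fitted by maximum likelihood via the
Poisson-likelihood equivalence for censored exponential data (event
indicator ~ Poisson with exposure = follow-up time), and a constant death
hazard λ₂ = deaths/person-time. The predicted risk is the closed-form
cause-1 cumulative incidence λ₁/(λ₁+λ₂)·(1−e^{−(λ₁+λ₂)t}). The published
analysis does not specify its 10-year-risk model; the exponential family was
chosen because it matches the synthetic generator's hazard family, which
makes recovery directly testable. A logistic-at-landmark fallback is
available behind `model="logistic"`.

At threshold rt, z = 1 iff predicted risk ≥ rt; TP = I(t|z=1)·P(z=1)·N and
FP = (1−I(t|z=1))·P(z=1)·N, with I(t|z) estimated on the respective
subgroup. Sensitivity and specificity are count ratios against the treat-all
(rt→0) row — TPR = TP_rt/TP₀, FPR = FP_rt/FP₀ — so that with no censoring
and no competing deaths the whole module reduces exactly to classical
counting decision-curve analysis (tested against a direct-counting oracle).
NB = sens·p − (1−spec)(1−p)·w with w = rt/(1−rt) and p = I(t); sNB = NB/p.
The false-positive reduction per 100 is (NB_model − NB_treat-all)/w × 100,
and the net-interventions-avoided summary applies the same stated formula —
published interventions-avoided figures derived differently are not
reverse-engineered. Bootstrap CIs for sNB resample the whole cohort and
refit the risk models; the default threshold grid mirrors the published
table (0.04%–0.32%) plus the clinical anchors 0.29%, 0.39%, 0.49% (average
10-year risk at ages 45, 50, 55).

## Synthetic-data generator

The generator defines the conditions under which the pipeline is exercised:

* **Reference panel.** Ancestral allele frequencies uniform on (0.05, 0.95);
  each ancestry drifts by a Balding–Nichols Beta draw with fixation index
  (default 0.1 in the CLI, a typical continental-scale value). Within-block
  LD comes from an exchangeable Gaussian copula on haplotypes (default
  latent correlation 0.5); diploid dosages are sums of two independent
  haplotypes. LD is blockwise-exchangeable rather than haplotype-realistic —
  enough to exercise LD blending and marginal-beta leakage, not a coalescent
  simulation.
* **GWAS.** The expected marginal effect of a variant is the within-block
  empirical-LD rotation of the true effects; observed effects add
  *independent* Gaussian noise at the plug-in case-control SE
  √(1/(2f(1−f)n_eff)), n_eff = 4/(1/n_cases + 1/n_controls). Correlated
  within-block noise would be more realistic for downstream shrinkage
  methods but no in-scope consumer depends on it.
* **Cohorts.** PRS standard normal within group; family history Bernoulli
  with prevalence 9% (the validation cohort's rate) and an independent
  multiplicative risk effect of 2 (a typical first-degree-relative CRC risk
  ratio; only its marginal association is exercised); CRC times exponential
  with hazard λ₀·exp(β·PRS + γ·famhx); death an independent exponential
  (0.003/yr, plausible for the 40s–70s age range); administrative censoring
  at end of follow-up. λ₀ is solved so the baseline individual's 10-year
  cumulative incidence equals the target (default 0.3%, the average 10-year
  risk at age 45 used as the screening threshold). Defaults: β = ln(1.67),
  the largest validation group's per-SD OR. Ages are uniform and hazards
  age-constant, so passing tests say nothing about age-varying baseline
  risk; the log-linear PRS→risk link is exactly the model the relative-risk
  and calibration machinery assumes, which is what makes parameter-recovery
  tests well-posed — they validate the implementation, not the biological
  adequacy of the model.

All generators are pure functions of (parameters, seed).

## Problem sizes used in the test suite

Closed-form identities are checked exactly (to 10⁻¹² or printed precision).
Simulation-based properties run at: per-SD-OR CI coverage, 100 replicates of
n = 20,000 at 1% baseline risk; the rare-disease AUC limit Φ(β/√2), the mean
of 4 replicates of n = 50,000 at 1% baseline (a single replicate has
Monte-Carlo SE ≈ 0.013, comparable to the ±0.015 tolerance); standardization
alignment on panels of 500/ancestry (means, SDs) and 1000/ancestry
(Kolmogorov–Smirnov); cumulative-incidence agreement at n = 50,000; the
decision-curve comparison over 25 replicates of n = 20,000 at 0.3% baseline
risk. The full suite runs in well under five minutes on one CPU.

## Known limitations

* Fixed-effect IVW only; no heterogeneity (random-effects) handling across
  ancestries or studies.
* The exponential risk model ignores age; real 10-year risks are strongly
  age-dependent.
* The covariate-adjusted AUC is defined by control-fitted residualization;
  other covariate-adjusted ROC constructions exist and give slightly
  different estimates.
* Palindromic variants are dropped rather than frequency-resolved.
* No PLINK .bed/.pgen parsing, no imputation, no remote accession fetching.
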