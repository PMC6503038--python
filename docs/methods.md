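# Methods

## The brain age gap and how this package estimates it

Brain age is the age a regression model predicts for a person from
structural brain features after being trained exclusively on healthy
individuals. The **brain age gap** (BAG) of a scan is

    BAG = predicted age − chronological age   (years),

with positive values indicating an older-appearing brain. (Some texts write
the difference the other way around; we use the convention under which
disease groups with accelerated brain aging have *positive* BAG.) Because
regression to the mean makes raw BAG negatively correlated with age, BAG is
**residualized**: an OLS model `BAG ~ 1 + (age − c) + (age − c)² + sex` is
fitted on a healthy reference sample (age centered at the reference mean `c`
to decorrelate the linear and quadratic columns) and its fitted values are
subtracted from *every* scan. Fitting on healthy controls only, and applying
the coefficients to patients, prevents disease effects from being absorbed
into the bias model. Residuals on the reference sample are numerically
orthogonal to age and age² (|r| < 1e-8) and mean-balanced across sexes —
this is asserted at run time.

When scans from more than one MRI scanner are pooled, each non-reference
scanner's additive effect on residualized BAG is estimated by a linear
mixed-effects model (`BAG_resid ~ scanner + age + age² + sex`, random
intercept per subject) and subtracted from that scanner's rows. The order is
residualize-then-adjust, presenting the combined correction "for age, age²,
sex and scanner". With a single scanner the adjustment is the identity. The
coefficient is only identified by subjects scanned on several scanners or by
age-overlapping groups; the code warns when the design confounds scanner
with group. If the mixed model cannot be fitted (degenerate variance), an
OLS fallback with the same fixed effects is used, with a warning.

## The brain-age model

One extreme-gradient-boosting tree ensemble is trained **per sex** to
regress chronological age (in years, untransformed) on the morphometric
features; tree models are scale-free, so no feature standardization is
applied. Hyperparameters: learning rate 0.01, max depth 4, subsample 1.0,
squared-error objective, `base_score` initialized at the sex's mean age. The
number of boosting rounds — the only tuned quantity — is chosen by an inner
5-fold cross-validation with early stopping (patience 50 rounds, cap 4,000),
taking the round count minimizing held-out RMSE. An optional outer
cross-validation (default 10 folds, each with its own inner loop — nested)
produces out-of-fold predictions; the reported accuracy is the Pearson r
between out-of-fold predicted and true age, pooled across the two sexes, as
is conventional when a single combined figure is quoted for per-sex models.
Fold bookkeeping guarantees no row is ever scored by a model fitted on its
own fold, and retraining with the same data and seed reproduces the report
exactly.

Regional models use exactly the same procedure on one region's features
(seven coarse labels: occipital, frontal, temporal, parietal, cingulate,
insula, subcortical/cerebellar). Because depth-limited, shrunken tree
ensembles initialized at the target mean cannot extrapolate, predictions lie
within the training age range (tested with a ±5-year guard band).

## Longitudinal and association statistics

* **Annual rate of brain aging** per patient: change in adjusted BAG between
  the chronologically first and last scans divided by the elapsed years (the
  longest available interval; intermediate visits are ignored). A
  per-subject OLS slope over all visits is available as an alternative
  estimator but is not the default. Subjects with fewer than two usable
  scans are excluded, never imputed. For an affine within-subject BAG
  trajectory the estimator equals the slope exactly. Note that additive
  per-scanner shifts cancel within subject, so rates are invariant to the
  scanner adjustment.
* **Group rate test**: one-sample two-sided t-test of the per-subject rates
  against 0 (SE = sd/√n, n−1 df). A zero-variance sample with nonzero mean
  reports p below machine epsilon with a warning rather than NaN.
* **Reliability**: intraclass correlation of the subjects × sessions matrix
  from the ANOVA mean squares — one-way single-rater ICC(1,1) =
  (BMS − WMS)/(BMS + (k−1)WMS) and two-way consistency single-rater
  ICC(3,1) = (BMS − EMS)/(BMS + (k−1)EMS). Both are computed; ICC(3,1) is
  reported by default because session-level shifts (e.g. a scanner upgrade
  mid-study) should not count against consistency. Rows with missing
  sessions are dropped with a logged count; a constant matrix is an error
  (the variance ratio is undefined).
* **Annualized brain-volume change**: 100·(V_last − V_first)/(V_first·Δt) in
  %/year, with an alternative mean-of-consecutive-pairs estimator behind a
  flag.
* **Effect sizes and associations**: Cohen's D with the pooled-SD
  denominator; Pearson correlations with two-sided p-values from the t
  transform (n−2 df); case-control comparisons from an OLS model
  `BAG ~ group + age + age² + sex (+ scanner)` whose group coefficient is
  the *adjusted difference* in years. Association tables run one Pearson
  test per (variable, region) pair on pairwise-complete observations and
  control the false discovery rate by Benjamini–Hochberg **across the whole
  table** (the most conservative reading of a table-wide correction); plain
  correlations are used rather than partial ones because the covariates have
  already been removed from BAG upstream.

## The synthetic cohort generator

No subject-level data are distributable for studies of this kind, so the
package ships a generator whose latent process is fully known, making every
downstream stage testable end to end. Features are linear in a latent brain
age with additive Gaussian noise — the simplest model under which a
regressor trained on healthy scans transfers group offsets into predicted
age:

    x_f = a_f + b_f · (BA_region(f) + scanner_offset) + c_f · 1[sex = F] + ε_f,
    ε_f ~ N(0, σ_f),

with 7 regions × 12 features (thickness mm / area mm² / volume mm³ cycling).
Latent brain age per region is

    BA_r = age + u_i                                      healthy controls
    BA_r = age + u_i + offset_r + γ_i + δ·(t − t_first)   MS patients

where `u_i ~ N(0, σ_u)` is a healthy subject-level deviation, `offset_r` a
region-specific disease offset, `γ_i ~ N(0, σ_gap)` a patient deviation
**shared across regions** (independent per-region draws would shrink the
global gap SD by √7 and understate between-patient heterogeneity), and δ the
within-patient acceleration. Scanner effects are a pure additive shift, in
years, on the latent-age input of every feature of that scanner's scans, so
the true scanner coefficient on BAG is known. Brain volume declines linearly
at a per-patient rate drawn from N(−0.30, 0.53) % of baseline per year
(linear-in-baseline so that the first-to-last annualized estimator is exact);
lesion load starts at N(4000, 1500) mm³ with correlation 0.46 to γ_i and
grows at N(504, 28) mm³/year. One pseudo-random substream per subject, keyed
by a stable hash of the subject id, makes tables byte-identical under a
fixed (config, seed) and leaves existing subjects untouched when a cohort is
enlarged.

### Key defaults (GeneratorConfig)

| parameter | default | meaning |
|---|---|---|
| `n_train_hc / n_test_hc / n_ms` | 800 / 200 / 200 | cohort sizes |
| `train_age_range` | 12–95 y | training cohort ages (uniform) |
| `test_age_range` | 21–49 y | case-control and patient baseline ages |
| `female_fraction` | 0.71 | sex mix of every cohort |
| `n_visits`, `followup_years` (SD) | 3, 4.4 (0.4) y | longitudinal design |
| `gap_offset_global` | 4.4 y | mean disease BAG offset |
| `gap_offset_region` | 6.2 y subcortical/cerebellar, 4.1 y elsewhere | scales proportionally with the global offset so a zero offset is a true null |
| `gap_sd` (σ_gap) | 6.0 y | between-patient gap SD |
| `acceleration` (δ) | 0.41 y/y | within-patient brain-age acceleration |
| `subject_random_sd` (σ_u) | 3.5 y | healthy brain-age deviation |
| `scanner_offsets` | 3T: 0, 1.5T: +3.0 y | additive latent-age shift per scanner |
| `atrophy_rate` (SD) | −0.30 (0.53) %/y | annual brain-volume change |
| `wmll_annual_change` (SD) | 504 (28) mm³/y | lesion-load growth |
| `wmll_gap_correlation` | 0.46 | lesion load vs latent gap |
| feature noise | σ_f/|b_f| ~ U(10, 25) y | per-feature noise in latent-age years |

### Calibration of the noise scales

The per-feature noise and σ_u were fixed once, from closed forms and a ridge
oracle, before any recovery test was run. Two considerations set them:

1. **Scale-down argument.** Real morphometric pipelines provide ~1,100
   features; the generator uses 84, each standing in for roughly a dozen real
   features, so per-feature noise expressed in years of latent age is drawn
   from U(10, 25) — about 1/√13 of what a single real feature would carry —
   preserving the information content of the ensemble (optimal estimation
   error ≈ 1.7 y globally, ≈ 4.6 y for a 12-feature region).
2. **Dispersion target.** With σ_gap = 6.0 y, a Cohen's D of ≈ 0.69 at a
   4.4-year group offset requires a healthy residual-BAG SD of ≈ 4.8 y;
   σ_u = 3.5 y plus the boosted model's estimation noise (≈ 3 y) lands
   there.

A consequence worth stating plainly: the synthetic training cohort is
*cleaner per feature* than real data, so the out-of-fold accuracy of models
trained on it (r ≈ 0.97–0.98) exceeds what full-scale morphometric studies
report (r ≈ 0.9). The generator is calibrated to reproduce case-control and
longitudinal effect recovery, not raw prediction accuracy; those two cannot
be matched simultaneously under this feature model with σ_gap = 6.

### What the generator does not emulate

No images, lesion masks or surface geometry; no feature–feature correlation
beyond the shared latent age (real thickness/area/volume features are
strongly cross-correlated); no site differences beyond an additive shift (no
variance or nonlinear scanner effects, which is why no ComBat-style
harmonization is included); no attrition, motion artifacts or segmentation
failures; clinical covariates are Gaussian with a configurable correlation
to the latent gap, not realistic EDSS distributions. Passing recovery tests
therefore demonstrates that the estimators are correct and unbiased under an
additive, linear-Gaussian world — not that the pipeline is robust to the
messiness of real multi-site MRI.

## Numerical choices and degenerate inputs

* Residualization solves via `numpy.linalg.lstsq`; a rank check raises a
  collinearity error (e.g. constant reference age) before solving. A
  single-sex reference drops the sex term with a warning. At least four
  reference rows are required.
* The orthogonality check is skipped when residuals are numerically zero
  (perfectly explained bias), where a correlation would be noise.
* Ages are centered before squaring everywhere (residualization, scanner
  LME, group OLS), with the centering constant stored alongside the
  coefficients.
* Rounds chosen by `argmin` of the inner-CV RMSE curve; ties resolve to the
  smaller count. Per-sex seeds derive deterministically from the training
  seed.
* `fdr_adjust` validates p ∈ [0, 1] and reports the index of any offender;
  outputs are capped at 1 and elementwise ≥ the inputs.
* BAG tables enforce `bag_raw = predicted − age` exactly, and subjects with
  one usable scan are excluded (with a logged count) from every rate
  analysis.

## Problem sizes used by the test suite and the acceptance script

Recovery runs use the study-scale design: models trained once on 800
healthy scans, then 200 simulated longitudinal cohorts (68 patients × 3
visits) for the rate, 100 case-control cohorts (200 + 200) for the adjusted
difference, Cohen's D and the regional offset, a 500 × 3 test-retest design
for the ICC, and 500 reduced-size replicates (30 + 30 case-control; 20
patients × 2 visits) for the null-calibration check. Structural unit tests
run on a 3-features-per-region generator with a fast learning-rate override;
the scientific defaults (learning rate 0.01, full feature set) are exercised
by the recovery tests. These sizes are the package's chosen trade-off
between Monte-Carlo precision and turnaround.

## Known limitations

* The boosted model's age-dependent bias is only approximately removed by
  the quadratic residualization; a small systematic drift (≈ −0.03 to −0.08
  years/year raw) attenuates estimated rates, so recovered accelerations sit
  slightly below the injected truth. This is a property of the method, not
  of the implementation.
* The scanner coefficient is a single additive constant; when no subject is
  scanned on both scanners it is confounded with group differences (the code
  warns), though within-subject rates are unaffected.
* Tree ensembles mildly shrink group offsets (slope of prediction on latent
  brain age ≈ 0.92–0.99 depending on the feature count), so regional
  differences recovered from 12 features are attenuated by a few percent.
* ICC forms disagree when session means shift; both are reported, and the
  choice matters when comparing against published reliability ranges.
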