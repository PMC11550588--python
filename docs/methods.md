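# Methods

`serodta` implements a three-stage evidence pipeline for ranking serum
immunoassay biomarkers of non-small cell lung cancer (NSCLC): a bivariate
diagnostic-test-accuracy (DTA) meta-analysis with Laboratory Medicine Best
Practices (LMBP) evidence grading, a matched case-control ROC validation
stage, and an integrated re-meta-analysis with subgroup, threshold-effect
and publication-bias diagnostics.  This note records the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Study-level data

Each study arm contributes a 2×2 table (TP/FP/FN/TN) against a pathology
reference standard, plus covariates: control composition (healthy / benign
lung disease / mixed), proportion of late-stage (III–IV) cases, assay
platform (CLIA / ELISA / RIA / other) and design.  Tables containing a zero
cell receive the conventional 0.5 continuity correction applied to **all
four cells of the affected table only**, flagged for audit.  The correction
rule is a documented package convention; zero-cell handling is rarely
reported in published DTA analyses and other choices (dataset-wide
correction, exact likelihoods) would differ in the third decimal at the
sample sizes involved.

Per-study sensitivity and specificity carry Wald intervals on the logit
scale with SE(logit sens) = √(1/TP + 1/FN) and SE(logit spec) =
√(1/TN + 1/FP); likelihood ratios and the diagnostic odds ratio use the
standard log-scale variances.  The logit-Wald choice (rather than exact
binomial intervals) keeps per-study and pooled intervals on the same scale.
All internal computation is full precision; half-up rounding exists only at
the presentation layer, because reproducing published table arithmetic
requires explicit, late rounding.

## Bivariate random-effects model

The pooling model is the normal–normal approximation to the bivariate DTA
model: study i contributes y_i = (logit se_i, logit sp_i) with known
within-study variances (independent components), and between studies

    y_i ~ N(μ, T + C_i),   T = [[τ₁², ρτ₁τ₂], [ρτ₁τ₂, τ₂²]].

A negative between-study correlation ρ is the signature of a threshold
effect: studies using stricter positivity cutoffs trade sensitivity for
specificity.  Estimation is restricted maximum likelihood (REML) over
(τ₁², τ₂², ρ), with the fixed effects profiled out by GLS.  The search is
unconstrained — variances on the log scale, correlation by Fisher z — and
derivative-free (Nelder–Mead) from five deterministic starting points;
variance components that collapse below 1e-8 are floored to exactly zero.
This normal–normal formulation was chosen over the exact binomial GLMM for
determinism and desk-scale speed; at the simulated arm sizes (tens to
hundreds of subjects per arm) the difference between the two likelihoods is
second-order.  A fit requires at least 4 studies, mirroring the usual
inclusion rule for DTA meta-analyses of a single test.

Pooled sensitivity and specificity are the back-transformed fixed effects
with logit-Wald intervals.  Intervals for PLR, NLR and DOR propagate the
fixed-effect covariance by parametric Monte Carlo (100,000 multivariate
normal draws, percentile intervals).  The Monte Carlo seed defaults to
20241019 and is recorded in every report bundle, so reports are bytewise
reproducible.

### Summary ROC curve and AUC

The SROC is traced as the model-implied regression of logit-sensitivity on
logit-specificity: logit se(fpr) = μ₁ + b·(logit(1−fpr) − μ₂) with
b = ρτ₁τ₂/τ₂²; when τ₂² = 0 the curve is the constant-sensitivity line.
The AUC integrates sensitivity over the **full** fpr range [0, 1] by the
trapezoid rule on a uniform grid (default 1,001 points for reports, 10,001
where analytic exactness is checked); a partial-AUC variant restricted to an
observed fpr window is available as an option.  Note a consequence of this
curve definition: when the estimated between-study correlation is near
zero, the curve is nearly flat and the AUC approaches the pooled
sensitivity, which can sit well below the "ROC-point intuition" value
(se + sp)/2.  AUC intervals propagate fixed-effect uncertainty by Monte
Carlo with T held at its estimate.

### Heterogeneity and the threshold effect

The bivariate I² is the determinant-based (generalized-variance)
construction: I² = |T|^½ / (|T|^½ + |W|^½), where W is the typical
within-study covariance built per component from Higgins' typical s².
It is 0 when T = 0 and strictly increasing in the between-study covariance.
A univariate DerSimonian–Laird Higgins I² per component is also computed;
step 3 triggers subgroup analysis when either component exceeds 50%.

The "threshold-effect percentage" is defined here as ρ²·100 when the
estimated correlation has threshold orientation (ρ(sens, spec) < 0) and 0
otherwise: the share of between-study variance aligned with the
sens/spec trade-off axis.  No published formula exists for the quantity
this statistic is usually labelled with, and different meta-analysis
packages report different constructions, so these percentages are
comparable within `serodta` runs but not across software.

### Outlier diagnostics

Empirical-Bayes predicted random effects b̂_i = T V_i⁻¹ (y_i − μ̂) are
standardized component-wise by the diagnostic SD √diag(T V_i⁻¹ T) — the
sampling SD of the predictor under the model — giving level-2 residuals
that are approximately standard normal for exchangeable studies.  A study
is flagged when either component strictly exceeds |2|; the strict
inequality is a deliberate boundary convention.  Because two roughly
independent z-scores are screened per study, the expected false-flag rate
under the null is ≈ 2·2·(1−Φ(2)) ≈ 9% per study — the flag is a screening
device feeding a sensitivity analysis (refit without flagged studies), not
a hypothesis test.  When T is estimated as zero there are no study-level
effects to predict and nothing is flagged.

### Group comparison and meta-regression

Biomarkers (and covariate subgroups within a biomarker) are compared by a
joint bivariate model with the binary indicator entering both logit
equations — equivalently group-specific means with a shared T — fitted by
maximum likelihood.  The global 2-df likelihood-ratio test compares this
against a pooled-mean null; per-component Wald tests and Monte-Carlo
intervals for the relative sensitivity/specificity (ratios of
back-transformed means) localize the effect.  ML rather than REML is used
wherever fixed-effect structures are compared, since REML likelihoods are
not comparable across mean structures.  Comparisons between biomarkers
require 4 studies per group; within-biomarker subgroup analyses relax this
to 2 per level because T is shared across all studies in the joint model.
Subgroup dichotomies: late-stage majority at >50% late-stage cases (exactly
50% counts as early-majority), CLIA vs non-CLIA platform, healthy vs benign
controls.  No multiplicity adjustment is applied across pairwise
comparisons by default (an optional Bonferroni/Holm flag exists), matching
how such comparisons are conventionally reported.

### Publication bias

Deeks' funnel-plot asymmetry test regresses ln(DOR) on 1/√ESS with weights
ESS, where ESS = 4n₁n₀/(n₁+n₀) is the effective sample size; the slope's
two-sided p-value uses a t reference distribution on K−2 degrees of
freedom (the reference-distribution choice is a package decision; z would
differ negligibly at K ≥ 10), with bias declared at α = 0.1.

## LMBP evidence grading

The "Apprizing" step scores the seven QUADAS-2 domains (four risk-of-bias,
three applicability) at 1 / 0.5 / 0 points for low / unclear / high risk;
quality is good above 5, fair from 3.5 to 5, poor at or below 3 (0.5-point
granularity makes the (3, 3.5) gap unreachable).  Effect size comes from
the study's likelihood-ratio pair: substantial iff LR+ > 10 **and**
LR− < 0.1, moderate iff exactly one criterion holds, minimal otherwise —
all inequalities strict, and point estimates (not CI bounds) are used.
The "Analyzing" step tallies qualifying studies into High / Moderate /
Suggestive / Insufficient evidence strength, evaluated top-down.  The
published tier wording is not exhaustive (e.g. two substantial plus one
moderate study, all good), so by default higher tiers count toward
lower-tier tallies ("moderate-or-better", "fair-or-better"); the literal
exact-category reading is available behind a switch and the audit trail
records which rule fired.  High or Moderate strength maps to "recommend";
Suggestive or Insufficient to "no recommendation"; "recommend against" is
reserved for an adverse-effects flag that is never fired automatically.

Upstream of grading, a clinical-applicability filter admits a biomarker
only when it has at least 4 studies and **more than** half of them show
AUC > 0.70 or (LR+ > 2 and LR− < 0.5).  When inputs are bare 2×2 tables,
per-study AUCs are unavailable and only the likelihood-ratio clause can
qualify a study; a marker with published-scale accuracy around
sens 0.51 / spec 0.90 (NLR ≈ 0.54) then sits exactly at the filter
boundary and may be excluded in some synthetic replicates — a behaviour to
keep in mind when reading demo outputs.

## Patient-level validation

The validation stage takes a 1:1 sex- and age-matched (±2 years)
case-control cohort with continuous biomarker values (CEA ng/mL,
Cyfra 21-1 μg/L, HE4 pmol/L, SAA mg/L).  Paired case/control location
shifts use the Wilcoxon signed-rank test by default with the paired t-test
reported alongside.  The nonparametric AUC is the Mann–Whitney statistic
(ties 0.5) with the Hanley–McNeil closed-form SE (Q₁ = A/(2−A),
Q₂ = 2A²/(1+A)); AUCs are compared with the independent-curves z-test
z = (A₁−A₂)/√(SE₁²+SE₂²).  Applying that test to markers measured on the
same subjects ignores their positive correlation and is therefore
conservative; the package reproduces this widely used practice rather than
substituting a correlated-curves method, and documents it here.

Biomarker panels are combined by maximum-likelihood logistic regression on
log-transformed values (serum marker distributions are right-skewed and are
conventionally analysed on the log scale; a raw-scale option exists); the
combined score is the fitted linear predictor, whose AUC is invariant to
the monotone link.  Under perfect separation the ML fit diverges and a
ridge-penalized refit (penalty 1e-4) is used and flagged.

Kit cutoffs (CEA 5.00 ng/mL, Cyfra 21-1 3.3 μg/L, HE4 70 pmol/L, SAA
10.0 mg/L) dichotomize the cohort into an experimental 2×2 row per marker
for step-3 integration.  Kit inserts define the negative side ("below
cutoff"), so a value exactly at the cutoff is positive.  Age is
dichotomized at 65 years for covariate stratification.

## Synthetic data generator

No raw study-level counts or patient-level measurements are publicly
deposited for this problem, so the generator is a first-class module that
produces data with exactly the statistical structure the analysis assumes:

* **Studies**: (logit se_i, logit sp_i) drawn from the bivariate normal
  with configurable (μ, τ₁², τ₂², ρ); arm sizes uniform over configurable
  ranges (default 40–200, the typical span of serum-marker accuracy
  studies); TP and TN binomial.  Study-level covariates (late-stage
  majority, platform, control type) can shift either logit, applied
  centered (±shift/2) so the marginal pooled accuracy stays at the
  configured truth.
* **Cohorts**: log-normal marker levels; the case/control separation is
  set from a target AUC through the binormal identity AUC = Φ(δ/(σ√2)).
  Planted covariate effects (larger shifts for LUSC/LLCC than LUAD, an
  over-65 age effect, optional late-stage effects) are centered within the
  case population.  Pairs share sex and differ by at most 2 years of age.
* **QUADAS-2 fixtures**: independent categorical draws per domain, with a
  default profile of elevated bias risk in patient selection and index
  test — the footprint of case-control designs — and clean applicability.

All generators are pure functions of (config, seed); one global seed fans
out into named substreams so adding a biomarker never perturbs another's
draws.  The default scenario mirrors a four-marker NSCLC panel: a CEA-like
marker (31 studies, sens 0.51/spec 0.90, stage-dependent specificity), a
Cyfra 21-1-like marker (44 studies, 0.62/0.90, stage-dependent), an
HE4-like marker (24 studies, 0.73/0.83, stage-invariant) and an SAA-like
marker (6 studies, 0.73/0.85, strong threshold correlation), with
τ² = 0.3 per component and threshold-oriented ρ; the 70-pair cohort has
35 healthy and 35 benign controls and target AUCs 0.77 / 0.83 / 0.84 /
0.88.

What the generator does **not** emulate: correlated multi-marker
measurements within a study arm, non-log-normal marker distributions,
informative missingness, reader/assay drift, or the actual published
per-study counts (which exist only in figures).  Passing tests therefore
demonstrate that the pipeline recovers truth under its own model family at
realistic sizes — not that any particular published estimate is correct.

## Simulation sizes used by the test suite

Chosen as the package's standing verification conditions: parameter
recovery uses 100 replicates of K = 30 studies at 200 subjects/arm with
truth (0.73, 0.83, τ² = 0.3, ρ = −0.3); Deeks calibration uses 500
replicates at K = 20; comparison-test calibration uses 500 replicates of
25 studies per group (the scale of the larger marker groups); the
validation-AUC bootstrap cross-check uses a 70 vs 70 cohort with 2,000
resamples.

## Known limitations

* The normal–normal within-study approximation understates uncertainty for
  very small arms (n ≲ 20) and relies on the continuity correction at the
  extremes; an exact binomial GLMM would be preferable there.
* The 2-df likelihood-ratio global test is asymptotic in the number of
  studies; with fewer than ~10 studies per group its type-I error drifts
  above nominal.
* The ρ²-based threshold-effect percentage and the determinant-based I²
  are self-consistent definitions, not reproductions of any one software
  package's output.
* The independent-curves AUC comparison in the validation stage is
  conservative for same-subject marker comparisons (documented choice).
* QUADAS-2 judgments are inputs; the package does not automate appraisal.
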