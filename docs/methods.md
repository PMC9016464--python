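# Methods

## Scope and data model

The package evaluates blood-based composite scores against liver-biopsy
histology. A `PatientRecord` stores demographics, routine labs,
neo-epitope biomarkers and histology in canonical units (albumin g/dL,
platelets 10⁹/L, glucose mmol/L, insulin mU/L, AST/ALT U/L); the CSV
reader performs declared unit conversions (g/L → g/dL ÷ 10, mg/dL
glucose → mmol/L ÷ 18.016) so the score formulae never see source
units. Three binary target conditions are defined on histology:
advanced fibrosis (stage ≥ F3), significant fibrosis (≥ F2), and
fibrotic NASH (NASH with activity score ≥ 4 and ≥ F2 fibrosis).

Missing-data policy: a record missing any input to a given score gets a
missing value for that score, and is excluded from that score's
analyses only — each analysis reports its own n. Records are never
imputed. When no explicit impaired-fasting-glucose flag is available,
IFG is operationalized as fasting glucose ≥ 5.6 mmol/L (the 100 mg/dL
criterion); the NFS indicator is IFG-or-diabetes.

## Score formulae and coefficients

FIB-4, NFS, APRI and BARD are fixed by definition. HFS, ADAPT, FIBC3
and MACK-3 are config-driven: their coefficients live in
`src/fibroscreen/data/score_coefficients.yaml` with a provenance string
per score, transcribed from the developer publications, so the
transcription is auditable and swappable without touching code.
Categorical bands (HFS) use closed lower bounds. The APRI AST upper
limit of normal defaults to 40 U/L and is configurable — the score's
definition leaves it to the laboratory.

Two caveats are recorded in the config itself. First, the MACK-3
developer coefficients could not be transcribed from an authoritative
source; the bundled values are a reconstructed surrogate with the
correct inputs (HOMA-IR, AST, CK-18 M30), logistic form and sign
structure, calibrated to the published operating range (median ≈ 0.10
in an obese biopsy cohort, decision cutoffs 0.134/0.549 both
attainable). Analyses of MACK-3's decision behavior are exact; its
numeric values are surrogate. Second, the interplay between the HFS
HOMA-IR bands and its diabetes term is ambiguous in secondary sources;
the bands are implemented additively.

## Diagnostic-accuracy machinery

Cutoff conventions follow the published decision rules: the lower
(rule-out) cutoff used as a binary screen is inclusive (score ≥ cutoff
⇒ positive), the upper (rule-in) cutoff exclusive (score > cutoff ⇒
positive), the gray zone closed on both sides; a single-cutoff rule is
positive at or above its cutoff. Age-adjusted lower cutoffs (FIB-4 2.0,
NFS 0.12) replace the standard lower cutoff at age ≥ 65. Combined
dual-cutoff performance counts indeterminate condition-positives as
true positives and condition-negatives as true negatives, reflecting
the assumption that gray-zone patients proceed to definitive biopsy.

Proportion CIs are exact Clopper–Pearson at 95% — the conservative,
reproducible choice where the reporting convention is unstated.
Likelihood ratios and NND have two modes: `raw` (analytic default) and
`integer_percent`, which first rounds Se/Sp to whole percents (half
away from zero) before forming LR⁺ = Se/(1−Sp), LR⁻ = (1−Se)/Sp and
NND = 1/(Se+Sp−1). The latter exists solely to reproduce printed
summary tables, whose LR/NND columns are derived from the rounded
percent cells (e.g. 79/87 → LR⁺ 6.08, NND 1.5; 32/98 → LR⁺ 16.00).

AUROC is the tie-corrected Mann–Whitney statistic (ties ½), with curve
points from scikit-learn; its CI and paired comparisons use DeLong's
structural-components estimator implemented here (variance of the
per-positive and per-negative placement components; two-sided normal
p). Perfect separation in both arms yields zero variance and is flagged
degenerate rather than reported as a p-value.

The Obuchowski measure is defined operationally: over all subject pairs
with different stages, a pair scores 1 if the score ranks them
concordantly with stage, ½ on a score tie, 0 otherwise; the pair weight
is 0.25 × |Δstage| and the measure is the weighted mean pair score.
With two stages and constant weights this reduces exactly to AUROC. The
CI is a leave-one-out jackknife — the normalization and CI method are
design choices here, since only the penalty is conventionally fixed.

Paired rate comparisons use the exact McNemar test (p = 1 when no pairs
are discordant); unpaired comparisons use Pearson's chi-squared without
continuity correction. Predictive values of paired tests are compared
with a weighted generalized score statistic: each subject contributes
its disease status to the test-positive arm of every test calling it
positive, the common PPV is estimated under H0 by group-size-weighted
pooling, and the variance is a cluster-robust sandwich over per-subject
influence contributions (analogously for NPV on negative calls). The
implementation is validated against a subject-bootstrap oracle in the
test suite.

The prevalence projection is the Bayes identity: at prevalence π,
PPV = Se·π / (Se·π + (1−Sp)(1−π)), NPV = Sp(1−π) / (Sp(1−π) + (1−Se)π),
accuracy = Se·π + Sp(1−π). At (Se, Sp, π) = (0.85, 0.95, 0.15) this
gives PPV 0.750, NPV 0.973, accuracy 0.935 — the planning rationale for
the 85%/95% anchors.

## Cutoff derivation

BMI bands default to nonobese [0, 30), obese [30, 40), morbidly obese
[40, ∞) kg/m². Within each band the data are split 70:30 into
derivation and validation sets, stratified on the target condition so
case prevalence is preserved to within one subject; the split is a pure
function of the seed. (Whether the original split should be stratified
is an open design point; stratification was chosen because it removes a
nuisance source of variation in small bands.) Bands without cases are
excluded with a warning. Subjects aged ≥ 65 are included by default —
elderly-specific cutoffs are deliberately out of scope.

Candidate cutoffs are midpoints between adjacent distinct observed
scores plus ±∞, so derivation depends only on ranks and is invariant
under strictly increasing transformations of the score. "Approximately
85% sensitivity / 95% specificity" is operationalized as constrained
optimization: the rule-out cutoff is the feasible candidate (derivation
Se ≥ 0.85) maximizing specificity, the rule-in cutoff the feasible
candidate (Sp ≥ 0.95) maximizing sensitivity, ties broken toward the
lower cutoff; the best single cutoff maximizes Youden's index. A floor
only attainable at ±∞ is flagged unattainable. The published band
cutoffs themselves (−2.022/0.326, −1.083/1.076, 0.544/2.054) are
data-dependent quantities of restricted cohorts and are not re-derived;
they ship as constants for application and sequential testing.

## Sequential testing

The two-stage pathway applies a dual-cutoff first test (FIB-4 with
age-adjusted lower cutoff by default); low/high calls are final, and
only gray-zone subjects receive the binary second test (ADAPT 6.3287,
FIBC3 0.4, HFS 0.12, or NFS with the BMI-band rule-out cutoff as
threshold). Gray-zone subjects lacking the second score are flagged
unclassifiable and excluded from metrics with an explicit count.
False-positive reduction is reported against the first test's lower
cutoff used alone, the screening policy the pathway replaces:
reduction = 1 − FP_seq/FP_single. Structurally, sequential sensitivity
cannot exceed — and specificity cannot fall below, when the second test
has any specificity in the gray zone — that comparator; the synthetic
suites verify this pattern.

## Synthetic cohorts

The generator draws fibrosis stage from a prevalence vector, then
analytes from stage-conditional families: log-normal for right-skewed
analytes (AST, ALT, insulin, PRO-C3, CK-18) with stage-increasing
location, truncated normal for platelets (stage-decreasing), albumin
and glucose; diabetes is logistic in BMI and stage; NASH probability
rises with stage and the activity score is drawn conditional on NASH
(NASH implies NAS ≥ 3). AST and ALT share a log-normal injury factor so
the AST/ALT ratio carries stage signal. Analytes are otherwise
conditionally independent given stage, BMI and that factor — the
simplest structure preserving what the scores exploit. Default effect
sizes were set once so that FIB-4 attains an AUROC of roughly 0.85–0.9
for ≥ F3 on the obese-clinic preset, the regime reported for this class
of cohorts, and are fully configurable.

Three presets emulate published cohort archetypes through their
marginal anchors only: `overweight_obese` (BMI median ≈ 40, stage
prevalences 204/125/21/17/11 over F0–F4, diabetes ≈ 43%),
`hepatology_lean` (BMI median ≈ 28, advanced-fibrosis prevalence
≈ 12%), `elevated_risk` (older, cirrhosis-enriched). Real cohorts carry
inter-analyte correlation, assay noise and selection effects the
generator does not model, so green recovery tests demonstrate pipeline
correctness, not expected field performance.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: oracle
equivalence uses exhaustive pair enumeration up to n = 200 (AUROC),
n = 50 (Obuchowski) and n = 100 (cutoff search); DeLong and
predictive-value tests are checked against 10⁴-replicate resampling
oracles within Monte-Carlo error; cutoff recovery uses 2000 subjects
per BMI band across repeated seeds, with per-run validation Se/Sp
required to fall in the 95% binomial band around the 0.85/0.95 anchors
(variance combining derivation and validation case counts) in ≥ 85% of
runs and pooled means within 0.03. Degenerate inputs (single-class
labels, single-stage cohorts, zero discordant pairs, zero denominators)
raise typed errors or return explicit undefined markers rather than
NaN. All randomness flows through `numpy.random.default_rng` seeds.

## Known limitations

* MACK-3 coefficient values are a labelled surrogate (above).
* Only the higher-is-more-diseased orientation is implemented.
* The Obuchowski jackknife CI and the cluster-robust form of the
  predictive-value comparison are principled choices, not transcriptions
  of a uniquely specified method.
* Published AUROCs of the original cohorts cannot be reproduced without
  the restricted patient-level data; the package reproduces the
  printed-count worked examples and the statistical machinery instead.
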