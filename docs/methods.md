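# Methods

This note documents the modelling choices behind the package: what each
stage computes, which parameters matter, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## The criteria and their operationalization

A patient qualifies for consideration (the *core* feature) with a slow,
predominant amnestic neurodegenerative syndrome: an amnestic MCI or amnestic
dementia diagnosis, with a known symptom duration under two years
disqualifying. An unknown duration does not disqualify, since insidious
onset is the norm in the populations this targets.

Standard supportive features:

- **Older age** — age at first visit ≥ `age_cutoff` (default 75 years,
  configurable; the boundary is inclusive and intentionally not rigid).
- **Mild clinical syndrome** — an amnestic-MCI diagnosis, or CDR-SB ≤ 4 at
  the *first* visit. A dementia diagnosis with no recorded CDR-SB leaves the
  feature unavailable rather than unmet.
- **Disproportionate hippocampal atrophy** — see below; evaluated at the
  *last* MRI.
- **Impaired semantic memory** — carried as a tri-state flag but excluded
  from likelihood counts unless `include_semantic_feature` is set, because
  no validated quantitative operationalization exists yet.

Advanced supportive features:

- **Limbic hypometabolism** — FDG-PET inferior-to-medial temporal (IMT)
  ratio at or above a ROC-derived cut. The IMT denominator is the
  volume-weighted mean SUVR of amygdala and hippocampus; weights are
  template region sizes supplied as data or config, defaulting to a
  hippocampus:amygdala ratio of 4:1 (their approximate anatomical size
  ratio). Subject-specific weights can be supplied through the imaging
  panel. The ratio is invariant to common rescaling of SUVRs and of
  weights.
- **Absence of a neocortical degenerative pattern** — FDG-PET Alzheimer
  meta-ROI SUVR *strictly above* its abnormality cut (the printed cuts put
  the boundary on the abnormal side: ≤ 1.47 Mayo pipeline, ≤ 1.21 ADNI
  pipeline is hypometabolic).
- **Low likelihood of significant neocortical tau** — a prioritized
  cascade: (i) negative amyloid-PET establishes the feature (amyloid is a
  surrogate for absent neocortical tau); (ii) with positive amyloid-PET, a
  negative tau-PET establishes it and a positive tau-PET refutes it; a
  positive amyloid-PET with *no* tau-PET leaves the feature unmet — fluids
  are fallbacks only when PET is absent, and positive fluids likewise mean
  "further workup", not LANS support; (iii) without PET, every available
  CSF measure must be Alzheimer-negative (Aβ42 > 1026 pg/ml, P-tau <
  22 pg/ml, P-tau/Aβ42 < 0.023 — a conservative conjunction, since no
  combination rule is established); (iv) without PET or CSF, plasma
  pTau181 strictly below its assay-specific cut. A tau-PET without an
  amyloid-PET decides directly, since it measures neocortical tau itself.

Degrees of certainty are evaluated highest → high → moderate → low,
returning the first satisfied rule; this resolves combinations the verbal
rules leave implicit (e.g. one standard plus three advanced features is
*low*, because both higher rules require at least two standard features).
"All standard features" for *highest* means all operationalized ones (three
when the semantic feature is excluded). Unavailable features never count
toward either tally, so missing data can only hold a patient at a lower
likelihood.

## Threshold dialects

Cut-points are cohort-pipeline-specific ("dialects"): the MAYO dialect uses
the in-house pons-normalized FDG pipeline with PiB amyloid (FDG ≤ 1.47,
PiB ≥ 1.48, flortaucipir ≥ 1.29, plasma pTau181 negative < 2.56 pg/ml); the
ADNI dialect the Berkeley pipeline with florbetapir/florbetaben (FDG ≤ 1.21,
≥ 1.11 / ≥ 1.0818, tau ≥ 1.29, plasma < 17.7 pg/ml). CSF Elecsys thresholds
are shared. The two ROC-derived cuts (IMT, disproportion Z) have no
constants; they stay unset until derived from data or supplied.

The printed CSF ratio threshold is dimensionally ambiguous between an
Aβ42/P-tau and a P-tau/Aβ42 reading; with the companion thresholds
(22/1026 ≈ 0.021) only P-tau/Aβ42 ≥ 0.023 is coherent, and that is what is
implemented.

## Disproportionate atrophy

ICV-adjusted hippocampal volume (residual from a sex-specific OLS of raw
volume on intracranial volume fitted on controls, hemispheres summed before
adjustment) is regressed on CDR-SB in a linear mixed model with a
per-subject random intercept, fitted by maximum likelihood on all
longitudinal visits. Random slopes are available behind a flag but default
off: most subjects contribute few visits, and a random-slope variance is
then weakly identified.

Patients are scored at the last visit carrying a volume as
`observed − (β₀ + β₁·CDR-SB)` — the *fixed-effects* prediction only, so a
model fitted in one cohort transfers to another without touching its
labels. Residuals are divided by the model residual SD ("scaled
residuals") and then Z-scored across the scored cohort (sample SD, ddof 1).
Z-scoring is per cohort by default, with a pooling flag. The abnormality
cut on Z is chosen by ROC analysis against autopsy TDP-43 status, with
more-negative residuals as the positive direction.

## ROC contract

AUC is all-pairs concordance with ties counting one half (equivalently the
normalized Mann-Whitney U, computed via midranks). Threshold candidates are
the midpoints between adjacent sorted unique scores, making the result
invariant to monotone jitter below data resolution; the reported threshold
maximizes Youden's J, with ties broken toward higher sensitivity and then
toward the numerically lower threshold. With weak class separation the
Youden optimum is flat and the selected cut can sit well away from any
generating threshold — visible in the synthetic pipeline, where derived
cuts are more liberal than the generator's anchors. If every score is
identical no midpoint exists; the common value is returned with everything
called positive.

## TDP-43 classifier

Logistic regression (maximum likelihood, via IRLS) of TDP-43 presence
(LATE-NC alone or comorbid = 1, pure ADNC = 0) on six features: age at
first visit, baseline CDR-SB, adjusted hippocampal volume at the last MRI,
IMT ratio and FDG meta-ROI (continuous), and tau positivity (binary, the
cascade feature not met; unavailable becomes missing). Complete-case
analysis mirrors the reduced denominators of real biomarker availability.
Class calls use probability ≥ 0.5 (configurable); the headline metric is
balanced accuracy, the unweighted mean of sensitivity and specificity.
Perfect separation is reported as a warning, not an error.

## Contingency and trajectory analyses

Likelihood-by-pathology tables collapse highest and high into one bin.
The omnibus test is the ordinary chi-square; pairwise two-proportion
z-tests (per category, per group pair) run only when the omnibus p < 0.05
and are uncorrected by default (a Holm flag is provided), matching the
convention of reporting raw pairwise p-values.

CDR-SB trajectories are modelled as `cdr_sb ~ time * group` with random
intercepts and (by default) random slopes per subject, maximum likelihood.
The `time:group` interaction coefficients are the contrasts of interest:
the difference in annual CDR-SB slope relative to the reference group.

## Synthetic cohort generator

The generator is the package's stand-in for a clinicopathological cohort
and encodes the study conditions directly: group sizes 75/81/9
(ADNC / comorbid / pure LATE-NC), per-group feature positivity and
availability rates taken from the published frequency table, age spreads
from the published interquartile ranges, and CDR-SB slope ordering (pure
LATE-NC slowest, ADNC fastest).

Each patient carries two latent severities, limbic L and neocortical N
(standard normal, independent). Each feature's continuous index is
`u = ρ·driver + √(1−ρ²)·ε`, standard normal within group, with loadings
L: age 0.3, mild 0.4, atrophy 0.7, limbic hypometabolism 0.7; N (negative):
preserved neocortex −0.7, low tau −0.7. A feature with configured rate p is
positive when `u > Φ⁻¹(1−p)`, and its biomarker value is anchored so it
crosses the corresponding abnormality threshold at exactly that quantile —
rates therefore match their configured values in expectation *exactly*,
while features sharing a latent are positively correlated. An independence
switch zeroes all loadings for analytic checks.

Quantities no table prints are fixed, field-realistic defaults: the
generating IMT threshold 1.20 with spread 0.12 (centring the three groups
near 1.07/1.19/1.28); amyloid PiB spread 0.30 around 1.48 (positives
reaching ≈ 2.4, consistent with high-centiloid disease); adjusted-volume
model intercept −0.2 cm³, CDR-SB slope −0.05 cm³/point, random-intercept
SD 0.5, residual SD 0.2, atrophy latent shift 0.7 cm³ per SD; CDR-SB
slopes 1.2 / 0.9 / 0.4 points/year (SD 0.3) with visit-level noise SD 0.4
on an annual schedule of 2-7 visits. Baseline CDR-SB derives from the
mild-syndrome index anchored at 4, so baseline severity is approximately —
not exactly — matched across groups (the pure LATE-NC group runs mildest,
as in the source data). Both FDG features share one scan-availability draw;
amyloid availability governs the PET arm of the tau cascade, with tau-PET,
CSF and plasma available at fixed secondary rates (0.3 / 0.25 / 0.4).

What the generator does *not* emulate: education, APOE4, non-amnestic
co-pathologies, measurement drift between cohorts, informative missingness
(masking is random given the group), visit dropout correlated with
severity, and any voxel-level structure. Passing tests therefore show that
the pipeline's statistical machinery behaves correctly under the published
marginal structure with plausible latent coupling — not that it would
reproduce patient-level results on real data.

## Problem sizes and numerical choices

The test suite fits the volume mixed model at 85 subjects / ~435
observations (the reference fit size) and checks 95% CI coverage over 100
replicates; generator calibration is checked at ~10,000 patients against
binomial sampling bands (3.5 SE); pipeline-level metrics (classifier
balanced accuracy, high-bin enrichment) are averaged over 25 default-size
replicates. The acceptance script uses 10 replicates. Mixed models are fit
by ML (not REML) so fixed-effects comparisons across models are coherent;
boundary variance estimates (zero random-effect variance on noiseless data)
are accepted silently. CSV I/O writes floats with shortest-round-trip
formatting and reads them with round-trip precision, so cohort round-trips
are bit-exact; missing values are empty cells, and negative sentinel values
fail validation instead of being compared against thresholds.

## Known limitations

- The pure LATE-NC stratum is tiny (9 patients at default size), so any
  statistic conditioned on it is noisy; the generator reproduces this
  honestly rather than inflating the group.
- Youden-derived cuts are unstable on weakly separated data (see above);
  derived cuts should be frozen and transferred, not re-derived per cohort,
  which is how the pipeline applies them.
- The tau cascade treats a positive-amyloid/no-tau-PET patient as not
  meeting the low-tau feature; clinically this is "indeterminate, work up
  further", and the tri-state vocabulary cannot express that distinction.
- Semantic memory is a pass-through flag; enabling it changes the standard
  feature count to 4 and raises the bar for the highest likelihood
  accordingly.
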