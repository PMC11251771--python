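# lans-criteria

Computational implementation of the clinical criteria for
**limbic-predominant amnestic neurodegenerative syndrome (LANS)** — a
clinico-radiological syndrome of slow, predominant episodic-memory decline
localizing to the limbic system, most often driven by limbic-predominant
age-related TDP-43 encephalopathy neuropathological change (LATE-NC) rather
than by Alzheimer's disease neuropathological change (ADNC).

The package is aimed at clinical researchers in dementia and
neurodegeneration who want to apply, stress-test or extend rule-based
diagnostic likelihood criteria on tabular clinicopathological cohort data.

## What it implements

**Feature operationalization.** Per patient, each supportive feature is
evaluated as met / not met / unavailable:

- *standard* — age at first visit ≥ 75 years; mild clinical syndrome
  (amnestic MCI diagnosis, or CDR-SB ≤ 4 at the first visit);
  hippocampal atrophy out of proportion to syndrome severity; impaired
  semantic memory (supported as a flag but excluded from likelihood counts
  by default);
- *advanced* — limbic hypometabolism (FDG-PET inferior-to-medial temporal
  ratio, IMT = SUVR_IT / weighted-mean(SUVR_amygdala, SUVR_hippocampus),
  above a ROC-derived cut); absence of a neocortical degenerative pattern
  (FDG-PET Alzheimer meta-ROI above its abnormality cut); and low
  likelihood of significant neocortical tau, via a prioritized cascade —
  amyloid-PET, then tau-PET, with CSF and plasma pTau181 as fallbacks only
  when PET is unavailable.

**Degrees of certainty.** With S of 3 standard and A of 3 advanced features
met (core amnestic syndrome required): *highest* = all features; *high* =
(S ≥ 3 and A ≥ 1) or (S ≥ 2 and A ≥ 2); *moderate* = S ≥ 3 or (S ≥ 2 and
A ≥ 1); *low* otherwise. Unavailable features never count: missing data
caps the likelihood, it never excludes the syndrome.

**Disproportionate atrophy.** A linear mixed model (random intercept per
subject, maximum likelihood) of ICV-adjusted hippocampal volume on CDR-SB;
patients are scored at their last MRI as Z-scored scaled residuals from the
fixed-effects prediction, and the abnormality cut is derived by ROC analysis
(Youden's J) against autopsy TDP-43 status.

**Validation machinery.** Likelihood-by-pathology contingency analysis
(chi-square with pairwise post hoc tests, highest/high collapsed), a
logistic TDP-43 classifier on the operationalized features (complete cases;
balanced accuracy as the headline metric; out-of-sample application to an
external cohort), and time x group mixed models of longitudinal CDR-SB.

**Synthetic cohorts.** A calibrated generator reproduces the published
group sizes (75 ADNC / 81 comorbid / 9 LATE-NC), age distributions,
per-group feature-positivity and availability rates, and group-dependent
CDR-SB slopes, with features coupled through latent limbic/neocortical
severities — so the whole pipeline is testable without any patient data.

## Worked example

```python
from lans import (
    AmyloidTracer, ClinicalDx, Cohort, ImagingPanel, PatientRecord, Sex,
    TriState, Visit, evaluate_patient, load_threshold_config,
)

cfg = load_threshold_config(None, "MAYO").replace(
    imt_abnormal_min=1.2, hippo_z_abnormal_max=-1.0,
)
patient = PatientRecord(
    patient_id="case", cohort=Cohort.MAYO, age_first_visit=79.0, sex=Sex.F,
    clinical_dx=ClinicalDx.AMNESTIC_MCI, symptom_duration=4.0,
    visits=[Visit(0.0, cdr_sb=1.0)],
)
# MRI shows disproportionate hippocampal atrophy; no advanced workup yet
profile, likelihood = evaluate_patient(patient, cfg, atrophy_flag=TriState.MET)
print(likelihood.category.name, likelihood.n_standard_met, likelihood.n_advanced_met)

# FDG-PET: limbic hypometabolism with preserved neocortex; amyloid-PET negative
patient.imaging = ImagingPanel(
    inferior_temporal_suvr=1.45, amygdala_suvr=0.95, hippocampus_suvr=1.0,
    amygdala_volume=1.0, hippocampus_volume=4.0,
    fdg_meta_roi_suvr=1.60, amyloid_pet_suvr=1.10, amyloid_tracer=AmyloidTracer.PIB,
)
profile, likelihood = evaluate_patient(patient, cfg, atrophy_flag=TriState.MET)
print(likelihood.category.name, likelihood.n_standard_met, likelihood.n_advanced_met)
```

prints

```
MODERATE 3 0
HIGHEST 3 3
```

— on standard features alone (old age, mild syndrome, disproportionate
atrophy) the patient reaches a moderate likelihood; the advanced workup
(limbic hypometabolism, preserved meta-ROI, negative amyloid) raises the
diagnosis to the highest likelihood.

The same flow is scriptable from a shell:

```bash
lans --seed 5 --out-dir cohort simulate
lans --out-dir results classify \
    --patients cohort/patients.csv --visits cohort/visits.csv \
    --biomarkers cohort/biomarkers.csv
lans --out-dir results fit-classifier \
    --patients cohort/patients.csv --visits cohort/visits.csv \
    --biomarkers cohort/biomarkers.csv
```

which writes a per-patient likelihood table and classifier metrics such as

```
{'balanced_accuracy_pct': 74.7, 'sensitivity_pct': 57.1, 'specificity_pct': 92.3}
```

## Layout

- `src/lans/records.py`, `config.py` — domain types, threshold dialects
- `src/lans/imaging.py` — IMT ratio, thresholding, ROC, normative volumes
- `src/lans/atrophy.py` — disproportionate-atrophy mixed model and scoring
- `src/lans/criteria.py` — feature evaluation and likelihood assignment
- `src/lans/simulate.py` — calibrated synthetic cohort generator
- `src/lans/validation.py`, `pipeline.py` — classifier, contingency and
  trajectory analyses, orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
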