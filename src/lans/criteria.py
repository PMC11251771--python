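"""Box-style rule engine for the LANS clinical criteria.

A patient must first satisfy the core feature: a slow, predominant amnestic
neurodegenerative syndrome (insidious onset, gradual progression over two or
more years). Standard supportive features are older age at evaluation
(>= 75 by default), a mild clinical syndrome (MCI diagnosis or CDR-SB <= 4 at
the first visit), hippocampal atrophy out of proportion to syndrome severity,
and impaired semantic memory (not operationalized here and excluded from
likelihood counts unless explicitly enabled). Advanced supportive features
are limbic hypometabolism (high FDG-PET IMT ratio), absence of a neocortical
degenerative pattern (preserved FDG meta-ROI), and a low likelihood of
significant neocortical tau established through a prioritized biomarker
cascade (amyloid-PET, then tau-PET, with CSF and plasma as fallbacks only
when PET is unavailable).

Degrees of certainty: with S met standard features (out of S_max
operationalized) and A met advanced features (out of 3) —

* NOT_LANS  — core feature not met;
* HIGHEST   — S = S_max and A = 3 (all features met);
* HIGH      — S >= 3 and A >= 1, or S >= 2 and A >= 2;
* MODERATE  — S >= 3, or S >= 2 and A >= 1;
* LOW       — otherwise.

Unavailable features never count as met: missing data can only hold a
patient at a lower likelihood, it never excludes the syndrome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .config import ThresholdConfig
from .imaging import compute_imt_ratio
from .records import (
    ClinicalDx,
    FluidPanel,
    ImagingPanel,
    PatientRecord,
    TriState,
)

__all__ = [
    "LansCategory",
    "TauScenario",
    "FeatureProfile",
    "LansLikelihood",
    "evaluate_core",
    "evaluate_standard",
    "evaluate_tau_cascade",
    "evaluate_advanced",
    "assign_likelihood",
    "evaluate_patient",
    "classify_cohort",
    "imt_ratio_from_panel",
]


class LansCategory(enum.IntEnum):
    """Ordered likelihood categories (order supports monotonicity checks)."""

    NOT_LANS = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3
    HIGHEST = 4


class TauScenario(enum.Enum):
    AMYLOID_PET = "AMYLOID_PET"
    TAU_PET = "TAU_PET"
    CSF = "CSF"
    PLASMA = "PLASMA"
    NONE = "NONE"


@dataclass
class FeatureProfile:
    core_met: bool
    age_ge_cutoff: TriState = TriState.UNAVAILABLE
    mild_syndrome: TriState = TriState.UNAVAILABLE
    disproportionate_atrophy: TriState = TriState.UNAVAILABLE
    semantic_impairment: TriState = TriState.UNAVAILABLE
    limbic_hypometabolism: TriState = TriState.UNAVAILABLE
    no_neocortical_pattern: TriState = TriState.UNAVAILABLE
    low_neocortical_tau: TriState = TriState.UNAVAILABLE
    tau_scenario_used: TauScenario = TauScenario.NONE

    def standard_features(self, include_semantic: bool) -> list[TriState]:
        feats = [self.age_ge_cutoff, self.mild_syndrome, self.disproportionate_atrophy]
        if include_semantic:
            feats.append(self.semantic_impairment)
        return feats

    def advanced_features(self) -> list[TriState]:
        return [
            self.limbic_hypometabolism,
            self.no_neocortical_pattern,
            self.low_neocortical_tau,
        ]


@dataclass
class LansLikelihood:
    category: LansCategory
    n_standard_met: int
    n_advanced_met: int


def evaluate_core(record: PatientRecord) -> bool:
    """Slow, predominant amnestic syndrome with >= 2 years of progression.

    An amnestic diagnosis qualifies; a known symptom duration under two years
    disqualifies (an unknown duration does not, since insidious onset is the
    norm in the clinic populations this targets).
    """
    if record.clinical_dx not in (ClinicalDx.AMNESTIC_MCI, ClinicalDx.AMNESTIC_DEMENTIA):
        return False
    if record.symptom_duration is not None and record.symptom_duration < 2.0:
        return False
    return True


def evaluate_standard(
    record: PatientRecord, cfg: ThresholdConfig, atrophy_flag: TriState
) -> FeatureProfile:
    """Standard supportive features; the atrophy flag arrives pre-computed
    from the disproportion pipeline."""
    age = TriState.MET if record.age_first_visit >= cfg.age_cutoff else TriState.NOT_MET

    if record.clinical_dx is ClinicalDx.AMNESTIC_MCI:
        mild = TriState.MET
    else:
        cdr = record.baseline_cdr_sb
        if cdr is None:
            mild = TriState.UNAVAILABLE
        else:
            mild = TriState.MET if cdr <= cfg.cdr_sb_mild_max else TriState.NOT_MET

    semantic = (
        record.semantic_memory_impaired
        if record.semantic_memory_impaired is not None
        else TriState.UNAVAILABLE
    )
    return FeatureProfile(
        core_met=evaluate_core(record),
        age_ge_cutoff=age,
        mild_syndrome=mild,
        disproportionate_atrophy=atrophy_flag,
        semantic_impairment=semantic,
    )


def _amyloid_positive(imaging: ImagingPanel, cfg: ThresholdConfig) -> bool | None:
    if imaging is None or imaging.amyloid_pet_suvr is None:
        return None
    cut = cfg.amyloid_abnormal_min.get(imaging.amyloid_tracer)
    if cut is None:
        raise ValueError(
            f"no amyloid cut-point configured for tracer {imaging.amyloid_tracer}"
        )
    return imaging.amyloid_pet_suvr >= cut


def _tau_pet_positive(imaging: ImagingPanel, cfg: ThresholdConfig) -> bool | None:
    if imaging is None or imaging.tau_pet_suvr is None:
        return None
    return imaging.tau_pet_suvr >= cfg.tau_pet_abnormal_min


def evaluate_tau_cascade(
    imaging: ImagingPanel | None,
    fluids: FluidPanel | None,
    cfg: ThresholdConfig,
) -> tuple[TriState, TauScenario]:
    """Low likelihood of significant neocortical tau, by prioritized scenario.

    (i) a negative amyloid-PET is a surrogate for absent neocortical tau;
    (ii) with positive amyloid-PET, a negative tau-PET establishes the
    feature and a positive one refutes it — and if no tau-PET was done the
    feature cannot be established (fluids are fallbacks only when PET is
    absent, so amyloid-positive patients do not fall through to them);
    (iii) without PET, all available CSF measures must be Alzheimer-negative;
    (iv) without PET or CSF, plasma pTau181 below its cut establishes it.
    A tau-PET without amyloid-PET decides directly, since it measures
    neocortical tau itself.
    """
    amyloid = _amyloid_positive(imaging, cfg)
    tau = _tau_pet_positive(imaging, cfg)

    if amyloid is not None:
        if not amyloid:
            return TriState.MET, TauScenario.AMYLOID_PET
        if tau is not None:
            return (TriState.NOT_MET if tau else TriState.MET), TauScenario.TAU_PET
        return TriState.NOT_MET, TauScenario.AMYLOID_PET
    if tau is not None:
        return (TriState.NOT_MET if tau else TriState.MET), TauScenario.TAU_PET

    if fluids is not None and fluids.any_csf:
        positive = False
        if fluids.csf_abeta42 is not None:
            positive |= fluids.csf_abeta42 <= cfg.csf_abeta42_abnormal_max
        if fluids.csf_ptau181 is not None:
            positive |= fluids.csf_ptau181 >= cfg.csf_ptau_abnormal_min
        if fluids.csf_ptau_abeta_ratio is not None:
            positive |= fluids.csf_ptau_abeta_ratio >= cfg.csf_ratio_abnormal_min
        return (TriState.NOT_MET if positive else TriState.MET), TauScenario.CSF

    if fluids is not None and fluids.plasma_ptau181 is not None:
        met = fluids.plasma_ptau181 < cfg.plasma_ptau_abnormal_min
        return (TriState.MET if met else TriState.NOT_MET), TauScenario.PLASMA

    return TriState.UNAVAILABLE, TauScenario.NONE


def imt_ratio_from_panel(imaging: ImagingPanel | None, cfg: ThresholdConfig) -> float | None:
    """IMT ratio from a panel, weighting medial regions by their template
    volumes (panel volumes when present, config defaults otherwise)."""
    if imaging is None:
        return None
    if (
        imaging.inferior_temporal_suvr is None
        or imaging.amygdala_suvr is None
        or imaging.hippocampus_suvr is None
    ):
        return None
    amy_vol = imaging.amygdala_volume or cfg.amygdala_template_volume
    hip_vol = imaging.hippocampus_volume or cfg.hippocampus_template_volume
    return compute_imt_ratio(
        imaging.inferior_temporal_suvr,
        [(imaging.amygdala_suvr, amy_vol), (imaging.hippocampus_suvr, hip_vol)],
    )


def evaluate_advanced(
    imaging: ImagingPanel | None,
    cfg: ThresholdConfig,
    tau: TriState,
    tau_scenario: TauScenario = TauScenario.NONE,
) -> FeatureProfile:
    """Advanced supportive features (limbic hypometabolism, absent
    neocortical pattern) combined with a pre-evaluated tau feature."""
    imt = imt_ratio_from_panel(imaging, cfg)
    if imt is None or cfg.imt_abnormal_min is None:
        limbic = TriState.UNAVAILABLE
    else:
        limbic = TriState.MET if imt >= cfg.imt_abnormal_min else TriState.NOT_MET

    if imaging is None or imaging.fdg_meta_roi_suvr is None:
        no_neo = TriState.UNAVAILABLE
    else:
        # preserved neocortical metabolism = strictly above the abnormality cut
        no_neo = (
            TriState.MET
            if imaging.fdg_meta_roi_suvr > cfg.fdg_meta_roi_abnormal_max
            else TriState.NOT_MET
        )
    return FeatureProfile(
        core_met=True,
        limbic_hypometabolism=limbic,
        no_neocortical_pattern=no_neo,
        low_neocortical_tau=tau,
        tau_scenario_used=tau_scenario,
    )


def assign_likelihood(profile: FeatureProfile, cfg: ThresholdConfig) -> LansLikelihood:
    """Map a feature profile to its degree-of-certainty category.

    Rules are evaluated HIGHEST -> HIGH -> MODERATE -> LOW, returning the
    first satisfied; "all standard features" for HIGHEST means all
    operationalized ones (3, or 4 when the semantic feature is enabled).
    """
    standard = profile.standard_features(cfg.include_semantic_feature)
    advanced = profile.advanced_features()
    s = sum(f is TriState.MET for f in standard)
    a = sum(f is TriState.MET for f in advanced)
    s_max = len(standard)

    if not profile.core_met:
        cat = LansCategory.NOT_LANS
    elif s == s_max and a == 3:
        cat = LansCategory.HIGHEST
    elif (s >= 3 and a >= 1) or (s >= 2 and a >= 2):
        cat = LansCategory.HIGH
    elif s >= 3 or (s >= 2 and a >= 1):
        cat = LansCategory.MODERATE
    else:
        cat = LansCategory.LOW
    return LansLikelihood(category=cat, n_standard_met=s, n_advanced_met=a)


def evaluate_patient(
    record: PatientRecord,
    cfg: ThresholdConfig,
    atrophy_flag: TriState = TriState.UNAVAILABLE,
) -> tuple[FeatureProfile, LansLikelihood]:
    """Full per-patient evaluation: standard features, tau cascade, advanced
    features, likelihood."""
    profile = evaluate_standard(record, cfg, atrophy_flag)
    tau, scenario = evaluate_tau_cascade(record.imaging, record.fluids, cfg)
    adv = evaluate_advanced(record.imaging, cfg, tau, scenario)
    profile.limbic_hypometabolism = adv.limbic_hypometabolism
    profile.no_neocortical_pattern = adv.no_neocortical_pattern
    profile.low_neocortical_tau = adv.low_neocortical_tau
    profile.tau_scenario_used = adv.tau_scenario_used
    return profile, assign_likelihood(profile, cfg)


def classify_cohort(
    records: list[PatientRecord],
    cfg: ThresholdConfig,
    atrophy_z: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Evaluate every patient and return one row each.

    ``atrophy_z`` maps patient_id to the disproportion Z-score; the flag is
    MET when Z <= ``cfg.hippo_z_abnormal_max``. Patients absent from the map
    (or with no installed Z cut) get an UNAVAILABLE atrophy feature and are
    still classified — missingness caps, never excludes.
    """
    if not records:
        raise ValueError("empty cohort")
    atrophy_z = atrophy_z or {}
    rows = []
    for rec in records:
        z = atrophy_z.get(rec.patient_id)
        if z is None or cfg.hippo_z_abnormal_max is None:
            flag = TriState.UNAVAILABLE
        else:
            flag = TriState.MET if z <= cfg.hippo_z_abnormal_max else TriState.NOT_MET
        profile, likelihood = evaluate_patient(rec, cfg, flag)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "pathology_group": rec.pathology_group.value,
                "core_met": profile.core_met,
                "age_ge_cutoff": profile.age_ge_cutoff.value,
                "mild_syndrome": profile.mild_syndrome.value,
                "disproportionate_atrophy": profile.disproportionate_atrophy.value,
                "semantic_impairment": profile.semantic_impairment.value,
                "limbic_hypometabolism": profile.limbic_hypometabolism.value,
                "no_neocortical_pattern": profile.no_neocortical_pattern.value,
                "low_neocortical_tau": profile.low_neocortical_tau.value,
                "tau_scenario": profile.tau_scenario_used.value,
                "n_standard": likelihood.n_standard_met,
                "n_advanced": likelihood.n_advanced_met,
                "likelihood": likelihood.category.name,
            }
        )
    return pd.DataFrame(rows)
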