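"""Rule-engine behavior: core/standard/advanced features, tau cascade,
likelihood assignment against an independently coded rule table."""

import itertools

import pytest

from lans.config import load_threshold_config
from lans.criteria import (
    FeatureProfile,
    LansCategory,
    TauScenario,
    assign_likelihood,
    classify_cohort,
    evaluate_advanced,
    evaluate_core,
    evaluate_standard,
    evaluate_tau_cascade,
)
from lans.records import (
    AmyloidTracer,
    ClinicalDx,
    Cohort,
    FluidPanel,
    ImagingPanel,
    PathologyGroup,
    PatientRecord,
    Sex,
    TriState,
    Visit,
)

MET, NOT, UNA = TriState.MET, TriState.NOT_MET, TriState.UNAVAILABLE


@pytest.fixture(scope="module")
def cfg():
    # install the two ROC-derived cuts so advanced features are decidable
    return load_threshold_config(None, "MAYO").replace(
        imt_abnormal_min=1.2, hippo_z_abnormal_max=-1.0
    )


def _record(
    dx=ClinicalDx.AMNESTIC_MCI,
    age=80.0,
    duration=None,
    cdr0=None,
    imaging=None,
    fluids=None,
    group=PathologyGroup.UNKNOWN,
    semantic=None,
):
    visits = [Visit(0.0, cdr_sb=cdr0)] if cdr0 is not None else []
    return PatientRecord(
        patient_id="p",
        cohort=Cohort.MAYO,
        age_first_visit=age,
        sex=Sex.F,
        clinical_dx=dx,
        symptom_duration=duration,
        visits=visits,
        imaging=imaging,
        fluids=fluids,
        pathology_group=group,
        semantic_memory_impaired=semantic,
    )


# ------------------------------------------------------------------ core


@pytest.mark.parametrize(
    "dx, duration, expected",
    [
        (ClinicalDx.AMNESTIC_MCI, None, True),
        (ClinicalDx.AMNESTIC_DEMENTIA, 3.0, True),
        (ClinicalDx.OTHER, None, False),
        (ClinicalDx.AMNESTIC_DEMENTIA, 1.0, False),  # <2 years of progression
        (ClinicalDx.AMNESTIC_MCI, 2.0, True),
    ],
)
def test_core_feature(dx, duration, expected):
    assert evaluate_core(_record(dx=dx, duration=duration)) is expected


# -------------------------------------------------------------- standard


def test_standard_features_typical_late_profile(cfg):
    profile = evaluate_standard(_record(age=86.2), cfg, atrophy_flag=MET)
    met = [profile.age_ge_cutoff, profile.mild_syndrome, profile.disproportionate_atrophy]
    assert met == [MET, MET, MET]


def test_age_boundary_is_strict(cfg):
    assert evaluate_standard(_record(age=74.9), cfg, UNA).age_ge_cutoff is NOT
    assert evaluate_standard(_record(age=75.0), cfg, UNA).age_ge_cutoff is MET


def test_mild_syndrome_dementia_at_cdr_boundary(cfg):
    rec = _record(dx=ClinicalDx.AMNESTIC_DEMENTIA, cdr0=4.0)
    assert evaluate_standard(rec, cfg, UNA).mild_syndrome is MET
    rec = _record(dx=ClinicalDx.AMNESTIC_DEMENTIA, cdr0=4.5)
    assert evaluate_standard(rec, cfg, UNA).mild_syndrome is NOT


def test_mild_syndrome_unavailable_for_dementia_without_cdr(cfg):
    rec = _record(dx=ClinicalDx.AMNESTIC_DEMENTIA)
    assert evaluate_standard(rec, cfg, UNA).mild_syndrome is UNA


# ----------------------------------------------------------- tau cascade


def _panel(amyloid=None, tau=None, tracer=AmyloidTracer.PIB):
    return ImagingPanel(
        amyloid_pet_suvr=amyloid,
        amyloid_tracer=tracer if amyloid is not None else None,
        tau_pet_suvr=tau,
    )


@pytest.mark.parametrize(
    "imaging, fluids, expected_state, expected_scenario",
    [
        # (i) negative amyloid-PET is a surrogate for absent neocortical tau
        (_panel(amyloid=1.10), None, MET, TauScenario.AMYLOID_PET),
        # (ii) amyloid positive, tau-PET 1.26 < 1.29 negative
        (_panel(amyloid=2.0, tau=1.26), None, MET, TauScenario.TAU_PET),
        (_panel(amyloid=2.0, tau=1.80), None, NOT, TauScenario.TAU_PET),
        # amyloid positive, no tau-PET: cannot establish low tau; no fluid fallback
        (
            _panel(amyloid=2.0),
            FluidPanel(plasma_ptau181=1.0),
            NOT,
            TauScenario.AMYLOID_PET,
        ),
        # tau-PET alone decides directly
        (_panel(tau=1.10), None, MET, TauScenario.TAU_PET),
        # (iii) CSF all-negative
        (
            None,
            FluidPanel(csf_abeta42=1500.0, csf_ptau181=15.0, csf_ptau_abeta_ratio=0.01),
            MET,
            TauScenario.CSF,
        ),
        # any positive CSF measure refutes
        (
            None,
            FluidPanel(csf_abeta42=1500.0, csf_ptau181=30.0),
            NOT,
            TauScenario.CSF,
        ),
        (None, FluidPanel(csf_abeta42=1000.0), NOT, TauScenario.CSF),
        # (iv) plasma fallback, strict < 2.56 in the Mayo dialect
        (None, FluidPanel(plasma_ptau181=2.0), MET, TauScenario.PLASMA),
        (None, FluidPanel(plasma_ptau181=2.56), NOT, TauScenario.PLASMA),
        # (v) nothing available
        (None, None, UNA, TauScenario.NONE),
    ],
)
def test_tau_cascade_prioritization(cfg, imaging, fluids, expected_state, expected_scenario):
    state, scenario = evaluate_tau_cascade(imaging, fluids, cfg)
    assert state is expected_state
    assert scenario is expected_scenario


def test_tau_cascade_amyloid_boundary_positive(cfg):
    # PiB SUVR exactly at 1.48 is amyloid-positive
    state, scenario = evaluate_tau_cascade(_panel(amyloid=1.48), None, cfg)
    assert state is NOT and scenario is TauScenario.AMYLOID_PET


# -------------------------------------------------------------- advanced


def test_advanced_meta_roi_direction(cfg):
    # preserved neocortical metabolism (1.60 > 1.47) supports LANS
    p = evaluate_advanced(ImagingPanel(fdg_meta_roi_suvr=1.60), cfg, UNA)
    assert p.no_neocortical_pattern is MET
    # hypometabolic meta-ROI refutes
    p = evaluate_advanced(ImagingPanel(fdg_meta_roi_suvr=1.40), cfg, UNA)
    assert p.no_neocortical_pattern is NOT


def test_advanced_missing_imt_is_unavailable(cfg):
    p = evaluate_advanced(ImagingPanel(fdg_meta_roi_suvr=1.60), cfg, UNA)
    assert p.limbic_hypometabolism is UNA


def test_advanced_imt_threshold(cfg):
    panel = ImagingPanel(
        inferior_temporal_suvr=1.3,
        amygdala_suvr=1.0,
        hippocampus_suvr=1.0,
        amygdala_volume=1.0,
        hippocampus_volume=4.0,
    )
    assert evaluate_advanced(panel, cfg, UNA).limbic_hypometabolism is MET  # 1.3 >= 1.2


# ------------------------------------------------- likelihood assignment


def _rule_oracle(core, s, a, s_max):
    """Independently coded degree-of-certainty table."""
    if not core:
        return LansCategory.NOT_LANS
    if s == s_max and a == 3:
        return LansCategory.HIGHEST
    if (s >= 3 and a >= 1) or (s >= 2 and a >= 2):
        return LansCategory.HIGH
    if s >= 3 or (s >= 2 and a >= 1):
        return LansCategory.MODERATE
    return LansCategory.LOW


def _profile_from_counts(core, s, a, include_semantic):
    n_standard = 4 if include_semantic else 3
    flags = [MET] * s + [NOT] * (n_standard - s)
    adv = [MET] * a + [NOT] * (3 - a)
    return FeatureProfile(
        core_met=core,
        age_ge_cutoff=flags[0],
        mild_syndrome=flags[1],
        disproportionate_atrophy=flags[2],
        semantic_impairment=flags[3] if include_semantic else UNA,
        limbic_hypometabolism=adv[0],
        no_neocortical_pattern=adv[1],
        low_neocortical_tau=adv[2],
    )


@pytest.mark.parametrize("include_semantic", [False, True])
def test_likelihood_matches_rule_oracle_exhaustively(cfg, include_semantic):
    c = cfg.replace(include_semantic_feature=include_semantic)
    s_max = 4 if include_semantic else 3
    for core in (False, True):
        for s in range(s_max + 1):
            for a in range(4):
                got = assign_likelihood(_profile_from_counts(core, s, a, include_semantic), c)
                assert got.category is _rule_oracle(core, s, a, s_max), (core, s, a)
                assert (got.n_standard_met, got.n_advanced_met) == (s, a)


@pytest.mark.parametrize("include_semantic", [False, True])
def test_likelihood_monotone_in_every_feature(cfg, include_semantic):
    """Flipping any feature to MET never lowers the category; UNAVAILABLE
    counts exactly like NOT_MET."""
    c = cfg.replace(include_semantic_feature=include_semantic)
    names = [
        "age_ge_cutoff",
        "mild_syndrome",
        "disproportionate_atrophy",
        "semantic_impairment",
        "limbic_hypometabolism",
        "no_neocortical_pattern",
        "low_neocortical_tau",
    ]
    states = (MET, NOT, UNA)
    for combo in itertools.product(states, repeat=len(names)):
        base = FeatureProfile(core_met=True, **dict(zip(names, combo)))
        cat = assign_likelihood(base, c).category
        for i, st in enumerate(combo):
            if st is MET:
                continue
            flipped = dict(zip(names, combo))
            flipped[names[i]] = MET
            cat_f = assign_likelihood(FeatureProfile(core_met=True, **flipped), c).category
            assert cat_f >= cat
        # unavailability is never counted
        as_not = dict(zip(names, [NOT if s is UNA else s for s in combo]))
        assert assign_likelihood(FeatureProfile(core_met=True, **as_not), c).category is cat


def test_highest_needs_every_operationalized_feature(cfg):
    for s in range(4):
        for a in range(4):
            got = assign_likelihood(_profile_from_counts(True, s, a, False), cfg)
            if got.category is LansCategory.HIGHEST:
                assert (s, a) == (3, 3)


def test_fig5_style_worked_case(cfg):
    """Core met + 3 standard features without advanced data is MODERATE;
    adding limbic hypometabolism, preserved meta-ROI and negative amyloid-PET
    raises it to HIGHEST."""
    moderate = assign_likelihood(_profile_from_counts(True, 3, 0, False), cfg)
    assert moderate.category is LansCategory.MODERATE
    highest = assign_likelihood(_profile_from_counts(True, 3, 3, False), cfg)
    assert highest.category is LansCategory.HIGHEST


def test_two_standard_two_advanced_is_high(cfg):
    assert assign_likelihood(_profile_from_counts(True, 2, 2, False), cfg).category is LansCategory.HIGH


def test_core_only_is_low(cfg):
    assert assign_likelihood(_profile_from_counts(True, 0, 0, False), cfg).category is LansCategory.LOW


# --------------------------------------------------------- cohort table


def test_classify_cohort_spanning_categories(cfg):
    full_panel = ImagingPanel(
        inferior_temporal_suvr=1.5,
        amygdala_suvr=1.0,
        hippocampus_suvr=1.0,
        amygdala_volume=1.0,
        hippocampus_volume=4.0,
        fdg_meta_roi_suvr=1.60,
        amyloid_pet_suvr=1.10,
        amyloid_tracer=AmyloidTracer.PIB,
    )
    records = [
        # young, not mild, nothing else: LOW
        _record(dx=ClinicalDx.AMNESTIC_DEMENTIA, age=68.0, cdr0=6.0),
        # old + mild + atrophy, no advanced data: MODERATE
        _record(age=80.0, cdr0=1.0),
        # everything met: HIGHEST
        _record(age=86.0, cdr0=0.5, imaging=full_panel),
    ]
    for i, r in enumerate(records):
        r.patient_id = f"p{i}"
    z = {"p1": -2.0, "p2": -2.0}
    table = classify_cohort(records, cfg, z)
    assert list(table["likelihood"]) == ["LOW", "MODERATE", "HIGHEST"]


def test_missing_biomarkers_cap_at_moderate(cfg):
    records = [_record(age=80.0, cdr0=1.0)]
    table = classify_cohort(records, cfg, {})
    assert table.loc[0, "likelihood"] in ("LOW", "MODERATE")
    assert table.loc[0, "n_advanced"] == 0


def test_adding_advanced_feature_never_lowers_category(cfg):
    rec = _record(age=80.0, cdr0=1.0)
    before = classify_cohort([rec], cfg, {}).loc[0, "likelihood"]
    rec.imaging = ImagingPanel(amyloid_pet_suvr=1.10, amyloid_tracer=AmyloidTracer.PIB)
    after = classify_cohort([rec], cfg, {}).loc[0, "likelihood"]
    assert LansCategory[after] >= LansCategory[before]


def test_classify_cohort_rejects_empty(cfg):
    with pytest.raises(ValueError, match="empty"):
        classify_cohort([], cfg, {})
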