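"""High-level orchestration: derive data-driven cut-points, evaluate the
criteria cohort-wide, and run the validation battery.

The intended flow mirrors the validation study design: the hippocampal
disproportion model and both ROC cut-points (disproportion Z, IMT ratio) are
derived in one cohort and then applied — fixed-effects predictions and frozen
thresholds — to the cohort under evaluation, avoiding circularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atrophy import DisproportionateAtrophyModel, derive_atrophy_cutoff
from .config import ThresholdConfig
from .criteria import classify_cohort, imt_ratio_from_panel
from .imaging import Direction, RocResult, roc_optimal_threshold
from .records import PathologyGroup, PatientRecord
from .validation import (
    ConfusionMetrics,
    LateClassifier,
    build_classifier_features,
    likelihood_distribution,
    predict_out_of_sample,
)

__all__ = ["DerivedCutpoints", "derive_cutpoints", "evaluate_cohort", "run_validation"]

_LATE_GROUPS = (PathologyGroup.LATE, PathologyGroup.ADNC_LATE)


def _late_present(rec: PatientRecord) -> bool:
    return rec.pathology_group in _LATE_GROUPS


@dataclass
class DerivedCutpoints:
    config: ThresholdConfig
    atrophy_model: DisproportionateAtrophyModel
    atrophy_roc: RocResult
    imt_roc: RocResult


def derive_cutpoints(records: list[PatientRecord], cfg: ThresholdConfig) -> DerivedCutpoints:
    """Fit the disproportion model and ROC-derive the two open cut-points.

    Patients with TDP-43 at autopsy (alone or comorbid) are the positive
    class for both ROC analyses; disproportion uses the last-MRI Z-score
    (more negative = positive direction), the IMT analysis the last FDG scan.
    """
    model = DisproportionateAtrophyModel().fit(records)
    scores = model.transform(
        [r for r in records if r.last_visit_with_volume() is not None]
    )
    by_id = {r.patient_id: r for r in records}
    labels = [_late_present(by_id[s.patient_id]) for s in scores]
    atrophy_roc = derive_atrophy_cutoff(scores, labels)

    imt_vals, imt_labels = [], []
    for rec in records:
        imt = imt_ratio_from_panel(rec.imaging, cfg)
        if imt is not None:
            imt_vals.append(imt)
            imt_labels.append(_late_present(rec))
    imt_roc = roc_optimal_threshold(imt_vals, imt_labels, Direction.HIGHER_IS_POSITIVE)

    cfg = cfg.replace(
        hippo_z_abnormal_max=atrophy_roc.optimal_threshold,
        imt_abnormal_min=imt_roc.optimal_threshold,
    )
    return DerivedCutpoints(
        config=cfg, atrophy_model=model, atrophy_roc=atrophy_roc, imt_roc=imt_roc
    )


def evaluate_cohort(
    records: list[PatientRecord],
    cfg: ThresholdConfig,
    atrophy_model: DisproportionateAtrophyModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score disproportion, evaluate every patient, return (features with
    Z-scores, likelihood table)."""
    scorable = [r for r in records if r.last_visit_with_volume() is not None]
    scores = atrophy_model.transform(scorable)
    z_map = {s.patient_id: s.z_score for s in scores}
    table = classify_cohort(records, cfg, z_map)
    features = table.copy()
    features["atrophy_z"] = features["patient_id"].map(z_map)
    features["imt_ratio"] = [
        imt_ratio_from_panel(r.imaging, cfg) for r in records
    ]
    return features, table


def run_validation(
    train_records: list[PatientRecord],
    test_records: list[PatientRecord] | None,
    cfg: ThresholdConfig,
    atrophy_model: DisproportionateAtrophyModel,
) -> dict:
    """Distribution analysis plus in-sample and optional out-of-sample
    classification metrics, as a JSON-ready mapping."""
    _, likelihoods = evaluate_cohort(train_records, cfg, atrophy_model)
    dist = likelihood_distribution(likelihoods)

    X, y = build_classifier_features(train_records, cfg, atrophy_model)
    clf = LateClassifier().fit(X, y)
    in_sample: ConfusionMetrics = predict_out_of_sample(clf, X, y)
    out = {
        "chi2": dist.chi2,
        "chi2_p_value": dist.p_value,
        "in_sample": in_sample.as_percent(),
        "n_complete_cases": clf.n_complete_cases_,
        "coefficients": dict(clf.coef_),
        "intercept": clf.intercept_,
    }
    if test_records is not None:
        Xt, yt = build_classifier_features(test_records, cfg, atrophy_model)
        oos = predict_out_of_sample(clf, Xt, yt)
        out["out_of_sample"] = oos.as_percent()
    return out
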