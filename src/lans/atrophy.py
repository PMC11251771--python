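"""Disproportionate hippocampal atrophy scoring.

The standard feature "hippocampal atrophy out of proportion to syndrome
severity" is operationalized by regressing ICV-adjusted hippocampal volume on
CDR-SB in a linear mixed model with a per-subject random intercept (fit by
maximum likelihood on all longitudinal visits), then expressing each
patient's volume at the last MRI as a residual from the *fixed-effects*
prediction. Using fixed effects only means a model fitted in one cohort can
score patients of another. Residuals are divided by the model residual SD and
Z-scored across the scored cohort; a sufficiently negative Z marks
disproportionate atrophy, with the cut-point chosen by ROC analysis against
autopsy TDP-43 status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

from .imaging import Direction, RocResult, roc_optimal_threshold
from .records import PatientRecord

__all__ = [
    "MixedModelFit",
    "DisproportionScore",
    "DisproportionateAtrophyModel",
    "fit_volume_cdr_model",
    "score_disproportion",
    "derive_atrophy_cutoff",
]


@dataclass
class MixedModelFit:
    """Summary of a fitted linear mixed model."""

    fixed_intercept: float
    fixed_slopes: dict[str, tuple[float, float]]  # name -> (coef, se)
    random_intercept_sd: float
    residual_sd: float
    n_subjects: int
    n_observations: int
    converged: bool
    random_slope_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.residual_sd >= 0:
            raise ValueError("residual_sd must be >= 0")
        if self.n_observations < self.n_subjects:
            raise ValueError("n_observations must be >= n_subjects")


@dataclass
class DisproportionScore:
    patient_id: str
    raw_residual: float
    scaled_residual: float
    z_score: float
    source_visit_time: float


def _long_table(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for v in rec.visits:
            if v.cdr_sb is not None and v.hippocampal_volume_adj is not None:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "cdr_sb": v.cdr_sb,
                        "volume": v.hippocampal_volume_adj,
                    }
                )
    return pd.DataFrame(rows)


class DisproportionateAtrophyModel(BaseEstimator):
    """Mixed model of adjusted hippocampal volume on CDR-SB with per-patient
    random intercepts, plus residual Z-scoring of new patients.

    Parameters
    ----------
    min_subjects : minimum number of subjects contributing paired
        CDR-SB/volume observations required to fit.
    pooled_z : if False (default), ``transform`` Z-scores scaled residuals
        within the cohort being scored; if True, the caller is expected to
        pool cohorts before scoring.
    """

    def __init__(self, min_subjects: int = 20, pooled_z: bool = False):
        self.min_subjects = min_subjects
        self.pooled_z = pooled_z

    def fit(self, records: list[PatientRecord], y=None):
        df = _long_table(records)
        n_subj = df["patient_id"].nunique() if len(df) else 0
        if n_subj < self.min_subjects:
            raise ValueError(
                f"need >= {self.min_subjects} subjects with paired CDR-SB and "
                f"hippocampal volume, got {n_subj}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance fits warn
            model = smf.mixedlm("volume ~ cdr_sb", df, groups=df["patient_id"])
            result = model.fit(reml=False)
        resid_var = float(result.scale)
        ri_var = float(np.asarray(result.cov_re)[0, 0])
        self.result_ = result
        self.fit_ = MixedModelFit(
            fixed_intercept=float(result.params["Intercept"]),
            fixed_slopes={
                "cdr_sb": (float(result.params["cdr_sb"]), float(result.bse["cdr_sb"]))
            },
            random_intercept_sd=float(np.sqrt(max(ri_var, 0.0))),
            residual_sd=float(np.sqrt(max(resid_var, 0.0))),
            n_subjects=int(n_subj),
            n_observations=int(len(df)),
            converged=bool(getattr(result, "converged", True)),
        )
        return self

    def predict_population(self, cdr_sb: float) -> float:
        """Fixed-effects-only prediction of adjusted hippocampal volume."""
        f = self.fit_
        return f.fixed_intercept + f.fixed_slopes["cdr_sb"][0] * cdr_sb

    def transform(self, records: list[PatientRecord]) -> list[DisproportionScore]:
        """Score each patient at the last visit carrying an MRI volume.

        Patients lacking a visit with both CDR-SB and volume are omitted with
        a warning rather than zero-filled.
        """
        if not hasattr(self, "fit_"):
            raise ValueError("model is not fitted")
        raws, times, ids = [], [], []
        for rec in records:
            visit = rec.last_visit_with_volume()
            if visit is None or visit.cdr_sb is None:
                warnings.warn(
                    f"patient {rec.patient_id} lacks paired CDR-SB and "
                    "hippocampal volume; omitted from disproportion scoring",
                    stacklevel=2,
                )
                continue
            raws.append(visit.hippocampal_volume_adj - self.predict_population(visit.cdr_sb))
            times.append(visit.time_from_baseline)
            ids.append(rec.patient_id)
        if not raws:
            return []
        raw = np.asarray(raws, dtype=float)
        scaled = raw / self.fit_.residual_sd if self.fit_.residual_sd > 0 else raw.copy()
        if len(scaled) > 1 and scaled.std(ddof=1) > 0:
            z = (scaled - scaled.mean()) / scaled.std(ddof=1)
        else:
            z = scaled - scaled.mean()
        return [
            DisproportionScore(
                patient_id=i,
                raw_residual=float(r),
                scaled_residual=float(s),
                z_score=float(zz),
                source_visit_time=float(t),
            )
            for i, r, s, zz, t in zip(ids, raw, scaled, z, times)
        ]


# spec-facing functional wrappers ------------------------------------------


def fit_volume_cdr_model(records: list[PatientRecord]) -> DisproportionateAtrophyModel:
    """Fit the volume-on-CDR-SB mixed model; returns the fitted model object
    (its ``fit_`` attribute carries the :class:`MixedModelFit` summary)."""
    return DisproportionateAtrophyModel().fit(records)


def score_disproportion(
    model: DisproportionateAtrophyModel, records: list[PatientRecord]
) -> list[DisproportionScore]:
    return model.transform(records)


def derive_atrophy_cutoff(
    scores: list[DisproportionScore], late_labels: list[bool]
) -> RocResult:
    """ROC-optimal Z cut-point separating TDP-43-positive from negative
    patients; more-negative residuals (disproportionate atrophy) are the
    positive direction."""
    return roc_optimal_threshold(
        [s.z_score for s in scores], late_labels, Direction.LOWER_IS_POSITIVE
    )
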