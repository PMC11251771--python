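"""Cohort-level validation analyses.

* a logistic regression classifying autopsy TDP-43 status (LATE-NC present,
  alone or comorbid, versus pure ADNC) from the operationalized criteria
  features — age at examination, CDR-SB, adjusted hippocampal volume, IMT
  ratio, FDG meta-ROI (continuous) and tau positivity (binary) — fitted on
  complete cases and applied out-of-sample to an external cohort;
* confusion-matrix metrics with balanced accuracy as the headline number;
* chi-square contingency analysis of likelihood categories by pathology
  group (highest and high collapsed into one bin) with pairwise
  two-proportion post hoc tests gated on the omnibus test;
* linear mixed models of longitudinal CDR-SB with a time-by-group
  interaction quantifying differences in clinical progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .atrophy import DisproportionateAtrophyModel, MixedModelFit
from .config import ThresholdConfig
from .criteria import TriState, evaluate_tau_cascade, imt_ratio_from_panel
from .records import PathologyGroup, PatientRecord

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "LateClassifier",
    "fit_late_classifier",
    "predict_out_of_sample",
    "build_classifier_features",
    "likelihood_distribution",
    "DistributionResult",
    "fit_trajectory_model",
]

PREDICTORS = [
    "age",
    "cdr_sb",
    "hippocampal_volume_adj",
    "imt_ratio",
    "fdg_meta_roi",
    "tau_positive",
]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float

    def as_percent(self) -> dict[str, float]:
        """Headline proportions as percentages rounded to one decimal."""
        return {
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "balanced_accuracy_pct": round(100 * self.balanced_accuracy, 1),
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must have at least one case")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
    )


class LateClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression for TDP-43 status from criteria features.

    Maximum-likelihood fit on complete cases (rows with any missing predictor
    are dropped, mirroring the reduced denominators of biomarker
    availability). Label 1 = LATE-NC present. Perfect separation is reported
    as a warning, not an error. Class calls use a probability threshold of
    0.5 by default.
    """

    def __init__(self, threshold: float = 0.5, min_cases_per_class: int = 10):
        self.threshold = threshold
        self.min_cases_per_class = min_cases_per_class

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)[PREDICTORS].astype(float)
        y = np.asarray(y, dtype=float)
        complete = ~X.isna().any(axis=1)
        Xc, yc = X[complete.to_numpy()], y[complete.to_numpy()]
        n1, n0 = int(yc.sum()), int((1 - yc).sum())
        if min(n0, n1) < self.min_cases_per_class:
            raise ValueError(
                f"need >= {self.min_cases_per_class} complete cases per class, "
                f"got {n0} negative / {n1} positive"
            )
        design = sm.add_constant(Xc, has_constant="add")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = sm.GLM(yc, design, family=sm.families.Binomial()).fit()
        for w in caught:
            if "separation" in str(w.message).lower():
                warnings.warn(str(w.message), stacklevel=2)
        self.result_ = result
        self.intercept_ = float(result.params["const"])
        self.coef_ = {p: float(result.params[p]) for p in PREDICTORS}
        self.coef_se_ = {p: float(result.bse[p]) for p in PREDICTORS}
        self.n_complete_cases_ = int(complete.sum())
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)[PREDICTORS].astype(float)
        eta = self.intercept_ + X.to_numpy() @ np.array([self.coef_[p] for p in PREDICTORS])
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def fit_late_classifier(features: pd.DataFrame, labels) -> LateClassifier:
    """Fit the TDP-43 logistic classifier (label 1 = LATE-NC present)."""
    return LateClassifier().fit(features, labels)


def predict_out_of_sample(
    clf: LateClassifier, features: pd.DataFrame, labels
) -> ConfusionMetrics:
    """Apply a fitted classifier to another cohort's complete cases."""
    X = pd.DataFrame(features)
    missing = [p for p in PREDICTORS if p not in X.columns]
    if missing:
        raise ValueError(f"feature table lacks predictor columns {missing}")
    X = X[PREDICTORS].astype(float)
    y = np.asarray(labels, dtype=int)
    complete = ~X.isna().any(axis=1)
    Xc, yc = X[complete.to_numpy()], y[complete.to_numpy()]
    pred = clf.predict(Xc)
    tp = int(((pred == 1) & (yc == 1)).sum())
    fp = int(((pred == 1) & (yc == 0)).sum())
    tn = int(((pred == 0) & (yc == 0)).sum())
    fn = int(((pred == 0) & (yc == 1)).sum())
    return confusion_metrics(tp, fp, tn, fn)


def build_classifier_features(
    records: list[PatientRecord],
    cfg: ThresholdConfig,
    atrophy_model: DisproportionateAtrophyModel | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Predictor table and TDP-43 labels for the logistic classifier.

    Continuous predictors: age at first visit, baseline CDR-SB, adjusted
    hippocampal volume at the last MRI, IMT ratio, FDG meta-ROI SUVR. Binary:
    tau positivity, i.e. the low-neocortical-tau cascade feature NOT met
    (unavailable -> missing). Patients outside the ADNC/LATE autopsy groups
    are excluded.
    """
    rows, labels = [], []
    for rec in records:
        if rec.pathology_group not in (
            PathologyGroup.ADNC,
            PathologyGroup.LATE,
            PathologyGroup.ADNC_LATE,
        ):
            continue
        last_mri = rec.last_visit_with_volume()
        tau, _ = evaluate_tau_cascade(rec.imaging, rec.fluids, cfg)
        imt = imt_ratio_from_panel(rec.imaging, cfg)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age_first_visit,
                "cdr_sb": rec.baseline_cdr_sb,
                "hippocampal_volume_adj": (
                    last_mri.hippocampal_volume_adj if last_mri else None
                ),
                "imt_ratio": imt,
                "fdg_meta_roi": (
                    rec.imaging.fdg_meta_roi_suvr if rec.imaging else None
                ),
                "tau_positive": (
                    None
                    if tau is TriState.UNAVAILABLE
                    else float(tau is TriState.NOT_MET)
                ),
            }
        )
        labels.append(rec.pathology_group is not PathologyGroup.ADNC)
    return pd.DataFrame(rows), np.asarray(labels, dtype=int)


@dataclass
class DistributionResult:
    contingency: pd.DataFrame
    row_percent: pd.DataFrame
    col_percent: pd.DataFrame
    chi2: float
    p_value: float
    dof: int
    posthoc: pd.DataFrame | None = None


def likelihood_distribution(
    likelihoods: pd.DataFrame,
    collapse_high: bool = True,
    posthoc_alpha: float = 0.05,
    holm: bool = False,
) -> DistributionResult:
    """Contingency analysis of likelihood categories by pathology group.

    Expects the table produced by ``classify_cohort`` (columns ``likelihood``
    and ``pathology_group``). Highest/high are merged into one bin by
    default. Pairwise two-proportion post hoc comparisons (per category,
    between each pair of groups) run only when the omnibus chi-square is
    significant; raw p-values are reported unless ``holm`` is set.
    """
    df = likelihoods[["pathology_group", "likelihood"]].copy()
    if collapse_high:
        df["likelihood"] = df["likelihood"].replace({"HIGHEST": "HIGH_HIGHEST", "HIGH": "HIGH_HIGHEST"})
    order = [c for c in ("LOW", "MODERATE", "HIGH", "HIGHEST", "HIGH_HIGHEST") if c in set(df["likelihood"])]
    table = pd.crosstab(df["pathology_group"], df["likelihood"])[order]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two groups and two likelihood bins")
    chi2, p, dof, _ = stats.chi2_contingency(table)
    row_pct = table.div(table.sum(axis=1), axis=0) * 100
    col_pct = table.div(table.sum(axis=0), axis=1) * 100

    posthoc = None
    if p < posthoc_alpha:
        rows = []
        for cat in table.columns:
            for g1, g2 in combinations(table.index, 2):
                k = np.array([table.loc[g1, cat], table.loc[g2, cat]])
                n = np.array([table.loc[g1].sum(), table.loc[g2].sum()])
                stat, pv = _two_proportion_test(k, n)
                rows.append(
                    {"category": cat, "group_1": g1, "group_2": g2, "stat": stat, "p_value": pv}
                )
        posthoc = pd.DataFrame(rows)
        if holm and len(posthoc):
            from statsmodels.stats.multitest import multipletests

            posthoc["p_adjusted"] = multipletests(posthoc["p_value"], method="holm")[1]
    return DistributionResult(
        contingency=table,
        row_percent=row_pct,
        col_percent=col_pct,
        chi2=float(chi2),
        p_value=float(p),
        dof=int(dof),
        posthoc=posthoc,
    )


def _two_proportion_test(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled two-proportion z-test; exact-safe for tiny counts via
    chi-square equivalence (z^2 = chi2 with 1 dof, no continuity correction)."""
    from statsmodels.stats.proportion import proportions_ztest

    if np.any(n == 0):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, pv = proportions_ztest(k, n)
    return float(stat), float(pv)


def fit_trajectory_model(
    records: list[PatientRecord],
    grouping: dict[str, str],
    reference: str | None = None,
    random_slopes: bool = True,
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Mixed model of CDR-SB on time x group with per-subject random effects.

    ``grouping`` maps patient_id to a group label (e.g. likelihood bin);
    patients absent from the map are ignored. Returns the fit summary and a
    tidy table of fixed effects; rows named ``time:group[...]`` are the
    interaction contrasts — the difference in annual CDR-SB slope relative to
    the reference group.
    """
    rows = []
    for rec in records:
        g = grouping.get(rec.patient_id)
        if g is None:
            continue
        for v in rec.visits:
            if v.cdr_sb is not None:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "time": v.time_from_baseline,
                        "cdr_sb": v.cdr_sb,
                        "group": g,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("need longitudinal CDR-SB in at least two groups")
    levels = sorted(df["group"].unique())
    if reference is None:
        reference = levels[0]
    df["group"] = pd.Categorical(df["group"], categories=[reference] + [l for l in levels if l != reference])

    re_formula = "~time" if random_slopes else "~1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "cdr_sb ~ time * C(group)", df, groups=df["patient_id"], re_formula=re_formula
        )
        result = model.fit(reml=False)

    cov_re = np.asarray(result.cov_re)
    fixed = pd.DataFrame(
        {
            "coef": result.params[result.fe_params.index],
            "se": result.bse[result.fe_params.index],
            "p_value": result.pvalues[result.fe_params.index],
        }
    )
    slopes = {
        name: (float(result.fe_params[name]), float(result.bse[name]))
        for name in result.fe_params.index
        if name != "Intercept"
    }
    summary = MixedModelFit(
        fixed_intercept=float(result.fe_params["Intercept"]),
        fixed_slopes=slopes,
        random_intercept_sd=float(np.sqrt(max(cov_re[0, 0], 0.0))),
        random_slope_sd=(
            float(np.sqrt(max(cov_re[1, 1], 0.0))) if random_slopes else None
        ),
        residual_sd=float(np.sqrt(result.scale)),
        n_subjects=int(df["patient_id"].nunique()),
        n_observations=int(len(df)),
        converged=bool(getattr(result, "converged", True)),
    )
    return summary, fixed
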