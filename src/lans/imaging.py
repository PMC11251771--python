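"""Derived imaging quantities and threshold/ROC machinery.

Three primitives live here because several pipeline stages share them:

* the FDG-PET inferior-to-medial temporal (IMT) ratio — inferior temporal
  SUVR over the volume-weighted mean SUVR of amygdala and hippocampus; high
  values indicate medial-temporal-predominant hypometabolism as seen with
  TDP-43-related limbic degeneration;
* sex-specific normative regression of raw hippocampal volume on intracranial
  volume, whose residuals are the ICV-adjusted volumes used everywhere else;
* ROC analysis with a fully specified optimal-threshold contract (Youden's J
  over midpoints between adjacent unique scores, ties broken toward higher
  sensitivity and then toward the lower threshold), so derived cut-points are
  reproducible to the bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .records import Sex

__all__ = [
    "Direction",
    "RocResult",
    "compute_imt_ratio",
    "apply_threshold",
    "roc_optimal_threshold",
    "NormativeVolumeRegressor",
    "fit_normative_volume",
    "adjust_hippocampal_volume",
]


class Direction(enum.Enum):
    HIGHER_IS_POSITIVE = "HIGHER_IS_POSITIVE"
    LOWER_IS_POSITIVE = "LOWER_IS_POSITIVE"


def compute_imt_ratio(
    inferior_temporal_suvr: float,
    medial_regions: Sequence[tuple[float, float]],
) -> float:
    """Inferior-to-medial temporal FDG-PET ratio.

    Parameters
    ----------
    inferior_temporal_suvr
        Pons-normalized FDG SUVR of the inferior temporal lobe.
    medial_regions
        ``(suvr, volume)`` pairs for the medial temporal regions (amygdala,
        hippocampus). The denominator is their volume-weighted mean SUVR, so
        the ratio is invariant to a common rescaling of the volumes.
    """
    if not medial_regions:
        raise ValueError("at least one medial region is required")
    if inferior_temporal_suvr <= 0:
        raise ValueError("inferior_temporal_suvr must be > 0")
    suvrs = np.asarray([s for s, _ in medial_regions], dtype=float)
    vols = np.asarray([v for _, v in medial_regions], dtype=float)
    if np.any(suvrs <= 0) or np.any(vols <= 0):
        raise ValueError("medial SUVRs and volumes must all be > 0")
    return float(inferior_temporal_suvr / (np.sum(vols * suvrs) / np.sum(vols)))


def apply_threshold(
    value: float,
    cutoff: float,
    direction: Direction,
    inclusive: bool = True,
) -> bool:
    """Dichotomize a biomarker value against a cut-point.

    ``inclusive`` puts the boundary on the abnormal side (the usual printed
    convention, e.g. abnormal FDG meta-ROI at "<= 1.47"); strict comparisons
    (e.g. plasma pTau181 negative at "< 2.56") use ``inclusive=False``.
    """
    if direction is Direction.HIGHER_IS_POSITIVE:
        return value >= cutoff if inclusive else value > cutoff
    return value <= cutoff if inclusive else value < cutoff


@dataclass
class RocResult:
    auc: float
    optimal_threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    direction: Direction

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc must lie in [0, 1], got {self.auc}")


def roc_optimal_threshold(
    scores: Iterable[float],
    labels: Iterable[bool],
    direction: Direction = Direction.HIGHER_IS_POSITIVE,
) -> RocResult:
    """ROC AUC and Youden-optimal operating threshold.

    AUC is the all-pairs concordance probability with ties counting one half
    (computed via midranks, which is exactly the normalized Mann-Whitney U
    statistic). Threshold candidates are the midpoints between adjacent
    sorted unique scores; the returned threshold maximizes Youden's
    J = sensitivity + specificity - 1, breaking ties toward higher
    sensitivity and then toward the numerically lower threshold.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")

    oriented = s if direction is Direction.HIGHER_IS_POSITIVE else -s
    ranks = stats.rankdata(oriented)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(s)
    if uniq.size == 1:
        # degenerate: no separating midpoint exists; call everything positive
        thr = float(uniq[0])
        sens, spec = 1.0, 0.0
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
        best = None
        for thr_c in candidates:
            if direction is Direction.HIGHER_IS_POSITIVE:
                call = s > thr_c
            else:
                call = s < thr_c
            sens_c = float(call[y].mean())
            spec_c = float((~call)[~y].mean())
            key = (sens_c + spec_c - 1.0, sens_c, -thr_c)
            if best is None or key > best[0]:
                best = (key, float(thr_c), sens_c, spec_c)
        _, thr, sens, spec = best
    return RocResult(
        auc=float(auc),
        optimal_threshold=thr,
        sensitivity_at_threshold=sens,
        specificity_at_threshold=spec,
        direction=direction,
    )


class NormativeVolumeRegressor(BaseEstimator):
    """Sex-specific OLS of raw hippocampal volume on intracranial volume.

    Fit on a control sample; ``transform`` then returns the ICV-adjusted
    residual volume (observed minus sex- and ICV-expected), negative meaning
    smaller than expected. Follows the scikit-learn estimator protocol;
    fitted per-sex coefficients live in ``coef_`` and residual scales in
    ``residual_scale_``.
    """

    def __init__(self, min_per_stratum: int = 3):
        self.min_per_stratum = min_per_stratum

    @staticmethod
    def _frame(controls) -> pd.DataFrame:
        if isinstance(controls, pd.DataFrame):
            df = controls[["raw_volume", "icv", "sex"]].copy()
        else:
            df = pd.DataFrame(controls, columns=["raw_volume", "icv", "sex"])
        df["sex"] = df["sex"].map(lambda s: s if isinstance(s, Sex) else Sex(s))
        return df

    def fit(self, controls, y=None):
        df = self._frame(controls)
        coef: dict[Sex, tuple[float, float]] = {}
        scale: dict[Sex, float] = {}
        for sex in Sex:
            sub = df[df["sex"] == sex]
            if len(sub) < self.min_per_stratum:
                raise ValueError(
                    f"need at least {self.min_per_stratum} controls for sex "
                    f"{sex.value}, got {len(sub)}"
                )
            X = np.column_stack([np.ones(len(sub)), sub["icv"].to_numpy(float)])
            beta, *_ = np.linalg.lstsq(X, sub["raw_volume"].to_numpy(float), rcond=None)
            resid = sub["raw_volume"].to_numpy(float) - X @ beta
            coef[sex] = (float(beta[0]), float(beta[1]))
            scale[sex] = float(resid.std(ddof=2)) if len(sub) > 2 else 0.0
        self.coef_ = coef
        self.residual_scale_ = scale
        return self

    def predict(self, icv, sex) -> float:
        """Expected raw volume for a subject of the given sex and ICV."""
        sex = sex if isinstance(sex, Sex) else Sex(sex)
        if not hasattr(self, "coef_"):
            raise ValueError("regressor is not fitted")
        if sex not in self.coef_:
            raise ValueError(f"no fitted stratum for sex {sex.value}")
        a, b = self.coef_[sex]
        return a + b * float(icv)

    def transform(self, subjects) -> np.ndarray:
        """ICV-adjusted residual volumes for rows of (raw_volume, icv, sex)."""
        df = self._frame(subjects)
        return np.asarray(
            [
                row.raw_volume - self.predict(row.icv, row.sex)
                for row in df.itertuples()
            ],
            dtype=float,
        )


# spec-facing functional wrappers ------------------------------------------

NormativeVolumeFit = NormativeVolumeRegressor


def fit_normative_volume(controls) -> NormativeVolumeRegressor:
    """Fit the per-sex normative volume model on ``(raw_volume, icv, sex)`` rows."""
    return NormativeVolumeRegressor().fit(controls)


def adjust_hippocampal_volume(
    raw_volume: float, icv: float, sex, fit: NormativeVolumeRegressor
) -> float:
    """Residual of the subject's raw volume from the sex-specific ICV regression."""
    return float(raw_volume - fit.predict(icv, sex))
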