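"""Domain types for the LANS criteria pipeline.

A :class:`PatientRecord` bundles everything the criteria engine needs for one
subject: demographics, the clinical diagnosis, longitudinal visits carrying
CDR-SB and ICV-adjusted hippocampal volume, an optional imaging panel
(regional FDG-PET SUVRs, molecular PET), an optional fluid panel (CSF and
plasma markers), and the autopsy group label used only by the validation
analyses.

Missing measurements are represented as ``None`` and propagate downstream as
"unavailable" feature states; they are never encoded as zeros or sentinels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Cohort(enum.Enum):
    MAYO = "MAYO"
    ADNI = "ADNI"
    SYNTHETIC = "SYNTHETIC"


class Sex(enum.Enum):
    F = "F"
    M = "M"


class ClinicalDx(enum.Enum):
    AMNESTIC_MCI = "AMNESTIC_MCI"
    AMNESTIC_DEMENTIA = "AMNESTIC_DEMENTIA"
    OTHER = "OTHER"


class PathologyGroup(enum.Enum):
    ADNC = "ADNC"
    LATE = "LATE"
    ADNC_LATE = "ADNC_LATE"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class AmyloidTracer(enum.Enum):
    PIB = "PIB"
    FLORBETAPIR = "FLORBETAPIR"
    FLORBETABEN = "FLORBETABEN"


class TriState(enum.Enum):
    """Evaluation state of a diagnostic feature.

    ``UNAVAILABLE`` features never count toward a likelihood; missing data can
    only prevent a patient from reaching higher likelihood categories.
    """

    MET = "MET"
    NOT_MET = "NOT_MET"
    UNAVAILABLE = "UNAVAILABLE"


def _require_positive(name: str, value: float | None) -> None:
    if value is not None and not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass
class Visit:
    """One longitudinal visit.

    time_from_baseline is in years; cdr_sb is the Clinical Dementia Rating
    Sum of Boxes (0-18); hippocampal_volume_adj is the ICV-adjusted residual
    volume, hemispheres combined, when an MRI accompanied the visit.
    """

    time_from_baseline: float
    cdr_sb: float | None = None
    hippocampal_volume_adj: float | None = None

    def __post_init__(self) -> None:
        if self.time_from_baseline < 0:
            raise ValueError(
                f"time_from_baseline must be >= 0, got {self.time_from_baseline}"
            )
        if self.cdr_sb is not None and not (0 <= self.cdr_sb <= 18):
            raise ValueError(f"cdr_sb must lie in [0, 18], got {self.cdr_sb}")


@dataclass
class ImagingPanel:
    """Regional and global PET/MRI measurements for one patient.

    FDG SUVRs are pons-normalized; the tau-PET meta-ROI SUVR is normalized to
    the cerebellar crus. ``amygdala_volume`` / ``hippocampus_volume`` are the
    template region sizes that weight the medial-temporal denominator of the
    inferior-to-medial temporal (IMT) ratio.
    """

    inferior_temporal_suvr: float | None = None
    amygdala_suvr: float | None = None
    hippocampus_suvr: float | None = None
    amygdala_volume: float | None = None
    hippocampus_volume: float | None = None
    fdg_meta_roi_suvr: float | None = None
    amyloid_pet_suvr: float | None = None
    amyloid_tracer: AmyloidTracer | None = None
    tau_pet_suvr: float | None = None
    raw_hippocampal_volume: float | None = None
    icv: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "inferior_temporal_suvr",
            "amygdala_suvr",
            "hippocampus_suvr",
            "amygdala_volume",
            "hippocampus_volume",
            "fdg_meta_roi_suvr",
            "amyloid_pet_suvr",
            "tau_pet_suvr",
            "raw_hippocampal_volume",
            "icv",
        ):
            _require_positive(name, getattr(self, name))
        if self.amyloid_pet_suvr is not None and self.amyloid_tracer is None:
            raise ValueError("amyloid_pet_suvr given without amyloid_tracer")


@dataclass
class FluidPanel:
    """CSF and plasma Alzheimer-pathology markers (pg/ml, ratio unitless)."""

    csf_abeta42: float | None = None
    csf_ptau181: float | None = None
    csf_ptau_abeta_ratio: float | None = None
    plasma_ptau181: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "csf_abeta42",
            "csf_ptau181",
            "csf_ptau_abeta_ratio",
            "plasma_ptau181",
        ):
            _require_positive(name, getattr(self, name))

    @property
    def any_csf(self) -> bool:
        return any(
            v is not None
            for v in (self.csf_abeta42, self.csf_ptau181, self.csf_ptau_abeta_ratio)
        )


@dataclass
class PatientRecord:
    patient_id: str
    cohort: Cohort
    age_first_visit: float
    sex: Sex
    clinical_dx: ClinicalDx
    symptom_duration: float | None = None
    visits: list[Visit] = field(default_factory=list)
    imaging: ImagingPanel | None = None
    fluids: FluidPanel | None = None
    pathology_group: PathologyGroup = PathologyGroup.UNKNOWN
    semantic_memory_impaired: TriState | None = None
    # populated only by the synthetic generator; carries latent truth states
    synthetic_truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.age_first_visit > 0:
            raise ValueError(f"age_first_visit must be > 0, got {self.age_first_visit}")
        self.visits = sorted(self.visits, key=lambda v: v.time_from_baseline)

    @property
    def baseline_visit(self) -> Visit | None:
        return self.visits[0] if self.visits else None

    @property
    def baseline_cdr_sb(self) -> float | None:
        """CDR-SB at the first visit (the score used for the mild-syndrome feature)."""
        return self.visits[0].cdr_sb if self.visits else None

    def last_visit_with_volume(self) -> Visit | None:
        """Last visit carrying an adjusted hippocampal volume (last MRI)."""
        for v in reversed(self.visits):
            if v.hippocampal_volume_adj is not None:
                return v
        return None
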