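"""Tabular cohort I/O.

The cohort lives in three CSV files joined on ``patient_id``:

* ``patients.csv`` — one row per patient: demographics, diagnosis, pathology
  group, optional semantic-memory flag;
* ``visits.csv`` — long format, one row per visit: time from baseline in
  years, CDR-SB, ICV-adjusted hippocampal volume when an MRI was done;
* ``biomarkers.csv`` — one row per patient: imaging and fluid panels
  ("last scan" semantics — downstream stages treat these as the most recent
  measurement of each modality).

Missing values are empty cells, full stop: they become ``None`` on the
records and "unavailable" feature states downstream. Negative sentinel
values are rejected by the record invariants rather than silently compared
against thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
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

__all__ = ["read_cohort", "write_cohort", "write_report"]

PATIENT_COLUMNS = [
    "patient_id",
    "cohort",
    "age_first_visit",
    "sex",
    "clinical_dx",
    "symptom_duration",
    "pathology_group",
    "semantic_memory_impaired",
]
VISIT_COLUMNS = ["patient_id", "time_from_baseline", "cdr_sb", "hippocampal_volume_adj"]
IMAGING_COLUMNS = [
    "inferior_temporal_suvr",
    "amygdala_suvr",
    "hippocampus_suvr",
    "amygdala_volume",
    "hippocampus_volume",
    "fdg_meta_roi_suvr",
    "amyloid_pet_suvr",
    "amyloid_tracer",
    "tau_pet_suvr",
    "raw_hippocampal_volume",
    "icv",
]
FLUID_COLUMNS = ["csf_abeta42", "csf_ptau181", "csf_ptau_abeta_ratio", "plasma_ptau181"]
BIOMARKER_COLUMNS = ["patient_id", *IMAGING_COLUMNS, *FLUID_COLUMNS]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_enum(enum_cls, value):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise ValueError(f"unknown {enum_cls.__name__} value {value!r}") from exc


def read_cohort(
    patients_csv: str | Path,
    visits_csv: str | Path,
    biomarkers_csv: str | Path | None = None,
) -> list[PatientRecord]:
    """Assemble one :class:`PatientRecord` per patient from the three tables.

    Visits are attached sorted by time. Patients without biomarker rows get
    empty panels. Duplicate (patient_id, time) visit rows are rejected with
    their row numbers; unknown enum values and non-numeric numerics raise.
    """
    kw = dict(dtype={"patient_id": str}, float_precision="round_trip")
    patients = pd.read_csv(patients_csv, **kw)
    visits = pd.read_csv(visits_csv, **kw)
    biomarkers = (
        pd.read_csv(biomarkers_csv, **kw)
        if biomarkers_csv is not None and Path(biomarkers_csv).exists()
        else pd.DataFrame(columns=BIOMARKER_COLUMNS)
    )

    dup = visits.duplicated(subset=["patient_id", "time_from_baseline"], keep=False)
    if dup.any():
        rows = [i + 2 for i in visits.index[dup]]  # 1-based incl. header
        raise ValueError(f"duplicate (patient_id, time_from_baseline) visit rows at lines {rows}")

    bio_by_id = {row["patient_id"]: row for _, row in biomarkers.iterrows()}
    visits_by_id: dict[str, list[Visit]] = {}
    for _, row in visits.iterrows():
        visits_by_id.setdefault(row["patient_id"], []).append(
            Visit(
                time_from_baseline=float(row["time_from_baseline"]),
                cdr_sb=_opt_float(row.get("cdr_sb")),
                hippocampal_volume_adj=_opt_float(row.get("hippocampal_volume_adj")),
            )
        )

    records = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        bio = bio_by_id.get(pid)
        imaging = fluids = None
        if bio is not None:
            imaging_kwargs = {c: _opt_float(bio.get(c)) for c in IMAGING_COLUMNS if c != "amyloid_tracer"}
            imaging_kwargs["amyloid_tracer"] = _opt_enum(AmyloidTracer, bio.get("amyloid_tracer"))
            if any(v is not None for v in imaging_kwargs.values()):
                imaging = ImagingPanel(**imaging_kwargs)
            fluid_kwargs = {c: _opt_float(bio.get(c)) for c in FLUID_COLUMNS}
            if any(v is not None for v in fluid_kwargs.values()):
                fluids = FluidPanel(**fluid_kwargs)
        semantic = row.get("semantic_memory_impaired")
        records.append(
            PatientRecord(
                patient_id=pid,
                cohort=Cohort(row["cohort"]),
                age_first_visit=float(row["age_first_visit"]),
                sex=Sex(row["sex"]),
                clinical_dx=ClinicalDx(row["clinical_dx"]),
                symptom_duration=_opt_float(row.get("symptom_duration")),
                visits=visits_by_id.get(pid, []),
                imaging=imaging,
                fluids=fluids,
                pathology_group=(
                    _opt_enum(PathologyGroup, row.get("pathology_group"))
                    or PathologyGroup.UNKNOWN
                ),
                semantic_memory_impaired=_opt_enum(TriState, semantic),
            )
        )
    return records


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the three cohort tables; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    p_rows, v_rows, b_rows = [], [], []
    for rec in records:
        p_rows.append(
            {
                "patient_id": rec.patient_id,
                "cohort": rec.cohort.value,
                "age_first_visit": rec.age_first_visit,
                "sex": rec.sex.value,
                "clinical_dx": rec.clinical_dx.value,
                "symptom_duration": rec.symptom_duration,
                "pathology_group": rec.pathology_group.value,
                "semantic_memory_impaired": (
                    rec.semantic_memory_impaired.value if rec.semantic_memory_impaired else None
                ),
            }
        )
        for v in rec.visits:
            v_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "time_from_baseline": v.time_from_baseline,
                    "cdr_sb": v.cdr_sb,
                    "hippocampal_volume_adj": v.hippocampal_volume_adj,
                }
            )
        b = {"patient_id": rec.patient_id}
        img = rec.imaging
        for c in IMAGING_COLUMNS:
            if c == "amyloid_tracer":
                b[c] = img.amyloid_tracer.value if img and img.amyloid_tracer else None
            else:
                b[c] = getattr(img, c) if img else None
        for c in FLUID_COLUMNS:
            b[c] = getattr(rec.fluids, c) if rec.fluids else None
        b_rows.append(b)

    paths = {
        "patients": out / "patients.csv",
        "visits": out / "visits.csv",
        "biomarkers": out / "biomarkers.csv",
    }
    # repr gives the shortest exact float representation, so write/read
    # round-trips bit-for-bit; numeric columns must be float dtype (not
    # object with Nones) for the formatter to apply
    kw = dict(index=False, float_format=lambda x: repr(float(x)))
    non_numeric = {
        "patient_id", "cohort", "sex", "clinical_dx", "pathology_group",
        "semantic_memory_impaired", "amyloid_tracer",
    }

    def _write(rows, columns, path):
        df = pd.DataFrame(rows, columns=columns)
        for c in columns:
            if c not in non_numeric:
                df[c] = pd.to_numeric(df[c])
        df.to_csv(path, **kw)

    _write(p_rows, PATIENT_COLUMNS, paths["patients"])
    _write(v_rows, VISIT_COLUMNS, paths["visits"])
    _write(b_rows, BIOMARKER_COLUMNS, paths["biomarkers"])
    return paths


def write_report(
    features: pd.DataFrame,
    likelihoods: pd.DataFrame,
    metrics: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the feature and likelihood tables plus a JSON metrics file.

    Deterministic: column order is taken from the tables, metric keys are
    sorted, so re-running on identical inputs is byte-identical.
    """
    if features.empty or likelihoods.empty:
        raise ValueError("feature and likelihood tables must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "likelihoods": out / "likelihoods.csv",
        "metrics": out / "metrics.json",
    }
    features.to_csv(paths["features"], index=False)
    likelihoods.to_csv(paths["likelihoods"], index=False)
    paths["metrics"].write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    return paths
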