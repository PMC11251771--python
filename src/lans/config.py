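"""Abnormality-threshold configuration.

Biomarker cut-points differ between cohorts because acquisition pipelines,
tracers and assays differ; each set of cut-points is a "dialect". The MAYO
dialect uses pons-normalized FDG-PET processed in-house with a PiB amyloid
tracer and a Simoa plasma assay; the ADNI dialect uses the Berkeley pipeline
with florbetapir/florbetaben tracers and a different plasma assay scale.
CSF Elecsys thresholds are shared.

Two cut-points are not fixed constants but derived from data: the FDG-PET
inferior-to-medial-temporal (IMT) ratio threshold and the hippocampal
disproportion Z threshold, both obtained by ROC analysis against autopsy
labels. They stay ``None`` until derived or supplied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .records import AmyloidTracer

__all__ = ["Dialect", "ThresholdConfig", "load_threshold_config"]


class Dialect:
    MAYO = "MAYO"
    ADNI = "ADNI"
    _ALL = ("MAYO", "ADNI")


# CSF Elecsys thresholds (shared across dialects). Positivity (Alzheimer-like):
# Abeta42 <= 1026 pg/ml, P-tau >= 22 pg/ml, P-tau/Abeta42 ratio >= 0.023.
_CSF_DEFAULTS = {
    "csf_abeta42_abnormal_max": 1026.0,
    "csf_ptau_abnormal_min": 22.0,
    "csf_ratio_abnormal_min": 0.023,
}

_DIALECT_DEFAULTS: dict[str, dict] = {
    Dialect.MAYO: {
        "fdg_meta_roi_abnormal_max": 1.47,
        "amyloid_abnormal_min": {AmyloidTracer.PIB: 1.48},
        "tau_pet_abnormal_min": 1.29,
        "plasma_ptau_abnormal_min": 2.56,
        **_CSF_DEFAULTS,
    },
    Dialect.ADNI: {
        "fdg_meta_roi_abnormal_max": 1.21,
        "amyloid_abnormal_min": {
            AmyloidTracer.FLORBETAPIR: 1.11,
            AmyloidTracer.FLORBETABEN: 1.0818,
        },
        "tau_pet_abnormal_min": 1.29,
        "plasma_ptau_abnormal_min": 17.7,
        **_CSF_DEFAULTS,
    },
}


@dataclass
class ThresholdConfig:
    """Complete set of cut-points needed to evaluate the criteria.

    Directions follow the printed threshold tables: FDG meta-ROI is abnormal
    (hypometabolic) at or below its cut; amyloid/tau PET are positive at or
    above; plasma pTau181 counts as Alzheimer-negative strictly below its cut.
    """

    dialect: str = Dialect.MAYO
    age_cutoff: float = 75.0
    cdr_sb_mild_max: float = 4.0
    fdg_meta_roi_abnormal_max: float = 1.47
    amyloid_abnormal_min: dict[AmyloidTracer, float] = field(
        default_factory=lambda: dict(_DIALECT_DEFAULTS[Dialect.MAYO]["amyloid_abnormal_min"])
    )
    tau_pet_abnormal_min: float = 1.29
    csf_abeta42_abnormal_max: float = 1026.0
    csf_ptau_abnormal_min: float = 22.0
    csf_ratio_abnormal_min: float = 0.023
    plasma_ptau_abnormal_min: float = 2.56
    # ROC-derived cut-points; None until installed
    imt_abnormal_min: float | None = None
    hippo_z_abnormal_max: float | None = None
    # template region sizes weighting the IMT medial denominator (hippocampus:amygdala ~ 4:1)
    hippocampus_template_volume: float = 4.0
    amygdala_template_volume: float = 1.0
    include_semantic_feature: bool = False

    def __post_init__(self) -> None:
        for name in (
            "age_cutoff",
            "cdr_sb_mild_max",
            "fdg_meta_roi_abnormal_max",
            "tau_pet_abnormal_min",
            "csf_abeta42_abnormal_max",
            "csf_ptau_abnormal_min",
            "csf_ratio_abnormal_min",
            "plasma_ptau_abnormal_min",
            "hippocampus_template_volume",
            "amygdala_template_volume",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value != value:
                raise ValueError(f"threshold {name} must be a finite number, got {value!r}")
        if not self.amyloid_abnormal_min:
            raise ValueError("amyloid_abnormal_min must map at least one tracer to a cut-point")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return dataclasses.replace(self, **kwargs)


class _StrictYamlLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys instead of silently
    keeping the last one."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ValueError(f"duplicate key {key!r} in configuration file")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictYamlLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def load_threshold_config(config_file: str | Path | None, dialect: str = Dialect.MAYO) -> ThresholdConfig:
    """Build a dialect-complete :class:`ThresholdConfig`.

    ``config_file`` may be YAML or JSON (or ``None`` / empty for pure
    defaults); any key it specifies overrides the dialect default. Duplicate
    keys and unknown dialects or keys are rejected.
    """
    if dialect not in Dialect._ALL:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {Dialect._ALL}")

    overrides: dict = {}
    if config_file is not None:
        text = Path(config_file).read_text()
        if text.strip():
            if str(config_file).endswith(".json"):
                overrides = json.loads(text)
            else:
                overrides = yaml.load(text, Loader=_StrictYamlLoader)
            if not isinstance(overrides, dict):
                raise ValueError("configuration file must contain a mapping")

    valid = {f.name for f in dataclasses.fields(ThresholdConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    if "amyloid_abnormal_min" in overrides:
        overrides["amyloid_abnormal_min"] = {
            AmyloidTracer(k): float(v)
            for k, v in overrides["amyloid_abnormal_min"].items()
        }

    merged = {"dialect": dialect, **_DIALECT_DEFAULTS[dialect]}
    merged["amyloid_abnormal_min"] = dict(merged["amyloid_abnormal_min"])
    merged.update(overrides)
    return ThresholdConfig(**merged)
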