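"""Configuration objects for the synthetic cohort, classifier and pipeline.

All stochastic stages derive their random state from the single ``seed`` of
the enclosing config, so identical config + seed reproduces every artifact
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class GroupParams:
    """Spatio-temporal gait parameters of one cohort group.

    ``stride_time_sd`` / ``stride_length_sd`` are *between-subject* standard
    deviations (each subject draws a personal mean); stride-to-stride
    variability within a subject is controlled by the ``*_within_sd`` fields
    of :class:`CohortConfig`.
    """

    stride_time_mean: float = 1.1  # s
    stride_time_sd: float = 0.08
    stride_length_mean: float = 1.3  # m
    stride_length_sd: float = 0.10
    # pelvis range of motion per anatomical plane, degrees
    pelvis_rom_tilt: float = 3.0  # sagittal
    pelvis_rom_obliquity: float = 4.0  # frontal
    pelvis_rom_rotation: float = 8.0  # transversal

    def validate(self) -> None:
        if self.stride_time_mean <= 0 or self.stride_length_mean <= 0:
            raise ValueError("stride time/length means must be positive")
        for name in ("stride_time_sd", "stride_length_sd", "pelvis_rom_tilt",
                     "pelvis_rom_obliquity", "pelvis_rom_rotation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortConfig:
    """Generator settings for a synthetic two-group gait cohort.

    Defaults mirror the study conditions this pipeline targets: 24 healthy
    controls and 20 patients roughly two weeks after total hip arthroplasty
    (THA), recorded at 60 Hz. Patients show a reduced sagittal hip range of
    motion and a diminished extension peak on the operated side, a slightly
    altered pelvis ROM, and shorter, slower strides. Effect magnitudes are
    configurable; the directions are fixed by the clinical literature.
    """

    n_healthy: int = 24
    n_patient: int = 20
    fs: float = 60.0  # Hz
    trial_duration: float = 30.0  # s

    healthy: GroupParams = field(default_factory=GroupParams)
    patient: GroupParams = field(default_factory=lambda: GroupParams(
        stride_time_mean=1.2, stride_time_sd=0.08,
        stride_length_mean=1.15, stride_length_sd=0.10,
        pelvis_rom_tilt=4.0, pelvis_rom_obliquity=5.0, pelvis_rom_rotation=6.0,
    ))

    # healthy sagittal hip kinematics: flexion peak = extension_peak + rom
    hip_rom_healthy: float = 40.0  # deg
    hip_extension_peak: float = -10.0  # deg (extension negative)
    # operated-side deficits (patients only)
    delta_rom_operated: float = 8.0  # deg reduction of sagittal hip ROM
    delta_extension_operated: float = 5.0  # deg loss of the extension peak

    # variability, degrees
    intra_subject_sd: float = 1.5  # stride-to-stride hip ROM jitter
    inter_subject_sd: float = 2.0  # subject-level per-side random effect
    # within-subject stride-to-stride spatio-temporal jitter
    stride_time_within_sd: float = 0.02  # s
    stride_length_within_sd: float = 0.03  # m

    # paired reference-system channel
    ref_offset_range: float = 12.5  # deg, static offset ~ U(-range, range)
    ref_noise_sd: float = 0.3  # deg, white noise
    bilateral_offsets: bool = True  # one offset per angle type, both sides

    seed: int = 0

    def validate(self) -> None:
        if self.n_healthy < 0 or self.n_patient < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        for name in ("intra_subject_sd", "inter_subject_sd", "ref_noise_sd",
                     "ref_offset_range", "stride_time_within_sd",
                     "stride_length_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.delta_rom_operated >= self.hip_rom_healthy:
            raise ValueError("delta_rom_operated must be < hip_rom_healthy")
        self.healthy.validate()
        self.patient.validate()

    def group_params(self, group: str) -> GroupParams:
        if group == "healthy":
            return self.healthy
        if group == "patient":
            return self.patient
        raise ValueError(f"unknown group {group!r}")


@dataclass
class ClassifierConfig:
    """RBF-SVM settings: box constraint 1.7, auto kernel scale, standardized
    features, stratified 12-fold cross-validation."""

    box_constraint: float = 1.7
    kernel_scale: float | str = "auto"
    standardize: bool = True
    n_folds: int = 12
    positive_class: str = "patient"
    group_by_subject: bool = False  # optional leakage-free CV mode
    seed: int = 0

    def validate(self) -> None:
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if isinstance(self.kernel_scale, str) and self.kernel_scale != "auto":
            raise ValueError("kernel_scale must be 'auto' or a positive float")
        if not isinstance(self.kernel_scale, str) and self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        if self.positive_class not in ("patient", "healthy"):
            raise ValueError("positive_class must be 'patient' or 'healthy'")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: cohort generator + classifier + seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    write_trials: bool = True

    def validate(self) -> None:
        self.cohort.validate()
        self.classifier.validate()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _dataclass_from_dict(cls, data: dict[str, Any]):
    kwargs = dict(data)
    if cls is CohortConfig:
        for key in ("healthy", "patient"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = GroupParams(**kwargs[key])
    return cls(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; missing sections take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = _dataclass_from_dict(CohortConfig, raw.get("cohort", {}))
    classifier = _dataclass_from_dict(ClassifierConfig, raw.get("classifier", {}))
    cfg = PipelineConfig(
        cohort=cohort,
        classifier=classifier,
        seed=int(raw.get("seed", 0)),
        write_trials=bool(raw.get("write_trials", True)),
    )
    if "seed" in raw:
        cfg.cohort.seed = cfg.seed
        cfg.classifier.seed = cfg.seed
    cfg.validate()
    return cfg
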