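"""Pipeline configuration.

Field names mirror the standard symbols: t_bright/t_dark (target
intensity range), t_len (max search length), t_min/t_max (opacity
sensitivity), t_air (air threshold), w_reso (isotropic resolution),
sigma_smooth, w_hole (median window), t_blob (response threshold),
t_small (minimum candidate sphere radius), r_target (minimum target
short axis), w_train, w_F, D (feature dilation radii).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import yaml

from .anatomy import AnatomyParams
from .candidates import CandidateParams
from .filters import IntensityTargetRange, RadialSearchParams
from .fp_reduction import TrainingPolicy
from .preprocess import PreprocessParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # target intensity range
    t_bright: float = 100.0
    t_dark: float = -100.0
    # radial search
    t_len: float = 15.0
    t_min: float = 10.0
    t_max: float = 110.0
    n_directions: int = 42
    beta_tolerance: float = 1e-6
    step: float | None = None
    opacity_form: str = "printed"
    beta_mode: str = "product"
    # preprocessing
    w_reso: float = 0.625
    sigma_smooth: float = 1.0
    # anatomy
    t_air: float = -200.0
    second_lung_fraction: float = 0.2
    # candidates
    w_hole: int = 3
    t_blob: float = 20.0
    t_small: float = 2.0
    # filter choice
    filter_mode: str = "itrst"
    hessian_scale: float = 3.0
    hessian_t_blob: float = 2000.0
    # region of interest around the mediastinum, mm
    mask_dilation: float = 4.0
    # FP reduction
    r_target: float = 10.0
    w_train: float = 0.5
    w_F: float = 0.075
    svm_C: float = 1.0
    D: tuple = (0.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        # delegate validation to the per-stage parameter objects
        self.radial_params()
        self.target_range()
        self.preprocess_params()
        self.anatomy_params()
        self.candidate_params()
        self.training_policy()
        if self.filter_mode not in ("itrst", "rst", "hessian"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.hessian_scale <= 0:
            raise ValueError("hessian_scale must be positive")
        if self.mask_dilation < 0:
            raise ValueError("mask_dilation must be non-negative")

    def radial_params(self) -> RadialSearchParams:
        return RadialSearchParams(
            t_min=self.t_min, t_max=self.t_max, t_len=self.t_len,
            n_directions=self.n_directions, step=self.step,
            beta_tolerance=self.beta_tolerance,
            opacity_form=self.opacity_form, beta_mode=self.beta_mode,
        )

    def target_range(self) -> IntensityTargetRange:
        return IntensityTargetRange(t_dark=self.t_dark, t_bright=self.t_bright)

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(w_reso=self.w_reso, sigma_smooth=self.sigma_smooth)

    def anatomy_params(self) -> AnatomyParams:
        return AnatomyParams(
            t_air=self.t_air, second_lung_fraction=self.second_lung_fraction
        )

    def candidate_params(self) -> CandidateParams:
        t_blob = self.hessian_t_blob if self.filter_mode == "hessian" else self.t_blob
        return CandidateParams(
            w_hole=self.w_hole, t_blob=t_blob, t_small=self.t_small
        )

    def training_policy(self) -> TrainingPolicy:
        return TrainingPolicy(
            r_target=self.r_target, w_train=self.w_train, w_F=self.w_F
        )

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        if "D" in kwargs:
            kwargs["D"] = tuple(float(d) for d in kwargs["D"])
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "D" in data:
            data["D"] = tuple(float(d) for d in data["D"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["D"] = list(d["D"])
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
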