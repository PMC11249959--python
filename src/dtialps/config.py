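"""Pipeline configuration: a YAML file validated against a strict schema.

Unknown keys are rejected anywhere in the document.  Where a block is
omitted the documented defaults apply (phantom / cohort / longitudinal
generator settings, QC thresholds, analysis choices).  The single
global ``seed`` is expanded into independent per-stage seeds by
``stage_seed``.
"""

from __future__ import annotations

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .alps import QCThresholds
from .cohort import CohortSpec, GroupSpec, LongitudinalSpec
from .phantom import PhantomSpec
from .rois import ROI_LABELS, ROISet

# fixed stage identifiers for seed derivation
_STAGE_IDS = {"phantom": 1, "cohort": 2, "longitudinal": 3, "dwi": 4}


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ROIBlock(_Strict):
    label: str
    center: tuple[float, float, float]
    radius: float = 5.0

    @field_validator("label")
    @classmethod
    def _known_label(cls, v: str) -> str:
        if v not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}")
        return v


class QCBlock(_Strict):
    fa_min: float = 0.15
    align_min: float = 0.5
    cone_deg: float = 30.0
    count_min: int = 10


class PhantomBlock(_Strict):
    shape: tuple[int, int, int] = (64, 48, 48)
    voxel_size: float = 1.0
    lambda_par: float = 1.4e-3
    lambda_perp: float = 0.4e-3
    epsilon: float = 0.12e-3
    background_d: float = 0.8e-3
    tensor_noise_sd: float = 0.0
    n_subjects: int = 10


class GroupBlock(_Strict):
    n: int
    alps_mean: float
    alps_se: float
    age_mean: float
    age_sd: float
    female_frac: float
    edu_mean: float = 14.0
    edu_sd: float = 3.0


class CohortBlock(_Strict):
    groups: dict[str, GroupBlock] | None = None
    cdr_slope: float = -1.16
    log_nfl_slope: float = -0.28
    log_gfap_slope: float = -0.10
    onset_slope: float = -9.94
    n_sites: int = 5


class LongitudinalBlock(_Strict):
    visit_spacing_years: float = 1.0
    stratum_slopes: dict[str, float] = Field(
        default_factory=lambda: {"low": 0.20, "average": 0.05, "high": -0.01})
    random_intercept_sd: float = 0.15
    random_slope_sd: float = 0.04
    residual_sd: float = 0.12


class AnalysisBlock(_Strict):
    covariates: list[str] = Field(default_factory=lambda: ["age", "sex", "site"])
    plasma_covariates: list[str] = Field(
        default_factory=lambda: ["age", "sex", "site", "plasma_site"])
    strata_z: float = 1.0


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "results"
    rois: list[ROIBlock] | None = None
    qc: QCBlock = Field(default_factory=QCBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    longitudinal: LongitudinalBlock = Field(default_factory=LongitudinalBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)

    @field_validator("rois")
    @classmethod
    def _four_rois(cls, v):
        if v is not None and sorted(r.label for r in v) != sorted(ROI_LABELS):
            raise ValueError(f"rois must contain exactly the labels {ROI_LABELS}")
        return v

    # -- conversions into the library's spec objects -------------------

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed: SeedSequence(global seed, stage id), < 2^31."""
        ss = np.random.SeedSequence([int(self.seed), _STAGE_IDS[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        p = self.phantom
        return PhantomSpec(
            shape=p.shape, voxel_size=p.voxel_size, lambda_par=p.lambda_par,
            lambda_perp=p.lambda_perp, epsilon=p.epsilon,
            background_d=p.background_d, tensor_noise_sd=p.tensor_noise_sd,
            seed=self.stage_seed("phantom") if seed is None else seed,
        )

    def cohort_spec(self) -> CohortSpec:
        c = self.cohort
        kwargs = dict(
            cdr_slope=c.cdr_slope, log_nfl_slope=c.log_nfl_slope,
            log_gfap_slope=c.log_gfap_slope, onset_slope=c.onset_slope,
            n_sites=c.n_sites, seed=self.stage_seed("cohort"),
        )
        if c.groups is not None:
            kwargs["groups"] = {
                k: GroupSpec(g.n, g.alps_mean, g.alps_se, g.age_mean, g.age_sd,
                             g.female_frac, g.edu_mean, g.edu_sd)
                for k, g in c.groups.items()
            }
        return CohortSpec(**kwargs)

    def longitudinal_spec(self) -> LongitudinalSpec:
        lg = self.longitudinal
        return LongitudinalSpec(
            visit_spacing_years=lg.visit_spacing_years,
            stratum_slopes=dict(lg.stratum_slopes),
            random_intercept_sd=lg.random_intercept_sd,
            random_slope_sd=lg.random_slope_sd,
            residual_sd=lg.residual_sd,
            seed=self.stage_seed("longitudinal"),
        )

    def qc_thresholds(self) -> QCThresholds:
        q = self.qc
        return QCThresholds(fa_min=q.fa_min, align_min=q.align_min,
                            cone_deg=q.cone_deg, count_min=q.count_min)

    def roi_set(self) -> ROISet | None:
        if self.rois is None:
            return None
        return ROISet.from_dict([r.model_dump() for r in self.rois])


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # re-raise with the file named
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
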