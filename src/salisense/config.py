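"""Run configuration with schema validation.

Everything the simulator and the analysis stages can be told is collected
here as pydantic models; unknown keys are rejected so a typo in a YAML file
fails loudly before any stage runs.
"""

from __future__ import annotations

from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class GroupDemographics(BaseModel):
    """Marginal distributions of one participant group.

    ``*_range`` bounds are hard truncation limits; the matching mean is the
    mean of the *truncated* distribution (the generator solves for the
    underlying normal location).  SDs for the range-reported markers default
    to range/4, the conventional range-based estimate.
    """

    model_config = ConfigDict(extra="forbid")

    age_mean: float
    age_sd: float = Field(gt=0)
    fbg_mean: float = Field(gt=0)
    fbg_range: Tuple[float, float]
    tg_mean: float = Field(gt=0)
    tg_range: Tuple[float, float]
    hba1c_mean: float = Field(gt=0)
    hba1c_range: Tuple[float, float]
    glucose_2hpp_mean: Optional[float] = None
    glucose_2hpp_range: Optional[Tuple[float, float]] = None
    p_male: float = Field(ge=0, le=1)
    activity_mean: float = Field(ge=0)
    activity_sd: float = Field(gt=0)


#: Diabetic-group marginals of the reported clinical cohort (n=45).
DIABETIC_DEMOGRAPHICS = GroupDemographics(
    age_mean=59.97, age_sd=8.73,
    fbg_mean=146.37, fbg_range=(84.0, 287.0),
    tg_mean=184.62, tg_range=(81.0, 477.0),
    hba1c_mean=7.54, hba1c_range=(5.6, 11.7),
    glucose_2hpp_mean=225.21, glucose_2hpp_range=(149.0, 328.0),
    p_male=26 / 45,
    activity_mean=2.0, activity_sd=2.0,
)

#: Non-diabetic-group marginals (n=45); no 2-h postprandial glucose is taken.
NONDIABETIC_DEMOGRAPHICS = GroupDemographics(
    age_mean=53.66, age_sd=10.34,
    fbg_mean=96.39, fbg_range=(82.0, 109.0),
    tg_mean=168.72, tg_range=(52.0, 625.0),
    hba1c_mean=5.53, hba1c_range=(5.0, 6.3),
    p_male=20 / 45,
    activity_mean=2.5, activity_sd=2.0,
)


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic cohort and response generator.

    Defaults reproduce the printed cohort statistics: balanced 45+45 groups,
    group Euclidean-norm distributions 358.31 (±27.98) vs 328.47 (±31.60),
    receptor-FBG correlations 0.726 (MR+TBOH, binned FBG) and 0.871
    (TMA-AgNPs, raw FBG), and replicate RSDs 6.03% / 6.71%.
    """

    model_config = ConfigDict(extra="forbid")

    n_diabetic: int = Field(default=45, ge=0)
    n_nondiabetic: int = Field(default=45, ge=0)
    seed: int = 0

    # Group distributions of the total response (row Euclidean norm).
    norm_mean_d: float = Field(default=358.31, gt=0)
    norm_sd_d: float = Field(default=27.98, gt=0)
    norm_mean_nd: float = Field(default=328.47, gt=0)
    norm_sd_nd: float = Field(default=31.60, gt=0)
    #: Target-norm draws are truncated at this many SDs so no single row
    #: demands a colour shift a spot cannot render.
    norm_truncation: float = Field(default=2.5, gt=0)
    #: Per-channel ceiling of a calibrated colour difference; excess is
    #: redistributed norm-preservingly over the row's other responsive
    #: channels so rendered shifts never clip at the 8-bit limits.
    delta_cap: float = Field(default=200.0, gt=0, le=255)

    # Latent receptor-FBG correlations.
    rho_mr: float = Field(default=0.726, gt=-1, lt=1)
    rho_tma: float = Field(default=0.871, gt=-1, lt=1)

    # Replicate (device-to-device) reproducibility, percent RSD of the norm.
    replicate_rsd_d: float = Field(default=6.03, ge=0)
    replicate_rsd_nd: float = Field(default=6.71, ge=0)

    # Noise model.
    noise_sd: float = Field(default=2.5, ge=0)       # floor on non-responsive channels
    receptor_jitter: float = Field(default=0.05, ge=0)  # relative, per receptor
    channel_jitter: float = Field(default=6.0, ge=0)    # additive, per responsive channel
    pixel_noise_sd: float = Field(default=0.0, ge=0)    # rendered-image noise

    # Saturating response midpoints/scale (mg/dL FBG) for group-exclusive
    # receptors: diabetic-linked spots switch on a little above the 126
    # diagnostic cutoff, nondiabetic-linked spots switch off above the upper
    # end of normal glycaemia, so borderline subjects from either group
    # produce ambiguous near-zero exclusive-receptor signal.
    act_midpoint_diabetic: float = 132.0
    act_midpoint_nondiabetic: float = 97.0
    act_tau: float = Field(default=3.0, gt=0)

    # Fraction of max_delta_rgb used by the FBG-correlated receptors.
    corr_base: float = Field(default=0.45, gt=0, le=1)
    corr_amp: float = Field(default=0.08, gt=0)

    # FBG binning used for the MR+TBOH (S5) link: right-open intervals
    # [0,100), [100,126), [126,200), [200,inf) mg/dL.
    fbg_bin_edges: Tuple[float, ...] = (0.0, 100.0, 126.0, 200.0)
    #: Representative value of the open-ended top bin (midpoints are used
    #: for the bounded bins).
    fbg_top_bin_value: float = 250.0

    demographics_diabetic: GroupDemographics = DIABETIC_DEMOGRAPHICS
    demographics_nondiabetic: GroupDemographics = NONDIABETIC_DEMOGRAPHICS

    @model_validator(mode="after")
    def _check_bins(self):
        edges = self.fbg_bin_edges
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("fbg_bin_edges must be strictly increasing with >= 2 edges")
        return self

    def demographics(self, group: str) -> GroupDemographics:
        return self.demographics_diabetic if group == "diabetic" else self.demographics_nondiabetic


class LayoutConfig(BaseModel):
    """Grid geometry of the rendered sensor: rows x cols circular spots."""

    model_config = ConfigDict(extra="forbid")

    canvas_width: int = Field(default=300, gt=0)
    canvas_height: int = Field(default=200, gt=0)
    rows: int = Field(default=3, gt=0)
    cols: int = Field(default=4, gt=0)
    radius: int = Field(default=20, gt=0)

    @model_validator(mode="after")
    def _twelve_spots(self):
        if self.rows * self.cols != 12:
            raise ValueError("rows * cols must equal 12")
        return self


class AnalysisConfig(BaseModel):
    """Options for the statistics and discrimination stages."""

    model_config = ConfigDict(extra="forbid")

    ttest_variant: str = Field(default="pooled", pattern="^(pooled|welch)$")
    #: Norm-threshold override; None means the grand mean of the analysed data.
    threshold: Optional[float] = None
    variance_target: float = Field(default=0.95, gt=0, le=1)
    n_components: Optional[int] = Field(default=None, gt=0)
    cv_scheme: str = Field(default="loo", pattern="^(loo|kfold|resubstitution)$")
    kfold_k: int = Field(default=5, ge=2)
    ridge: float = Field(default=1e-8, ge=0)
    fbg_bin_edges: Tuple[float, ...] = (0.0, 100.0, 126.0, 200.0)
    fbg_top_bin_value: float = 250.0


class RunConfig(BaseModel):
    """Top-level configuration for an end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: Optional[int] = None
    log_level: str = Field(default="INFO", pattern="^(DEBUG|INFO|WARNING|ERROR)$")
    generator: GeneratorConfig = GeneratorConfig()
    layout: LayoutConfig = LayoutConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @model_validator(mode="after")
    def _propagate_seed(self):
        if self.seed is not None:
            object.__setattr__(self.generator, "seed", int(self.seed))
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
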