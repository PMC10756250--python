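"""Configuration dataclasses for every pipeline stage.

Defaults encode the study conditions: 1 mm isotropic voxels on an orbit-cropped
field of view, group-conditional eye geometry for myopic / emmetropic /
hyperopic children, T2-like fat-suppressed contrast, and the segmentation
hyper-parameters (affine atlas registration, 100-tree random forest,
background bias, atlas probability floor).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

MYOPIA = "myopia"
EMMETROPIA = "emmetropia"
HYPEROPIA = "hyperopia"
GROUPS = (HYPEROPIA, EMMETROPIA, MYOPIA)


@dataclass
class GridConfig:
    """Orbit-cropped acquisition grid: axis 0 = LR, 1 = PA, 2 = IS (RAS)."""

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class GroupGeometry:
    """Mean (SD) of true eye geometry and refraction within one SE group.

    Lengths in mm, volumes in mm^3, refraction in diopters.
    """

    se_mean: float
    se_sd: float
    se_lo: float  # truncation bounds keeping SE inside the group band
    se_hi: float
    ps_length: tuple[float, float]
    height: tuple[float, float]
    width: tuple[float, float]
    acd: tuple[float, float]
    lens_thickness: tuple[float, float]
    lens_volume: tuple[float, float]
    corneal_radius: tuple[float, float]


def _default_groups() -> dict[str, GroupGeometry]:
    # Group-conditional geometry for 10-year-old eyes; hyperopic eyes are the
    # shortest and most oblate, myopic eyes the longest.
    return {
        # ACD rises with myopia so that the group-mean sphericities
        # (height^2/AL^2 - 1) land near the printed group shape values
        # (~0.11 hyperopic, ~0.06 emmetropic, ~0.005 myopic).
        HYPEROPIA: GroupGeometry(
            se_mean=2.8, se_sd=0.8, se_lo=2.0, se_hi=8.0,
            ps_length=(16.2, 0.6), height=(22.9, 0.8), width=(23.3, 0.9),
            acd=(2.30, 0.25), lens_thickness=(3.2, 0.10),
            lens_volume=(81.0, 10.0), corneal_radius=(7.76, 0.25),
        ),
        EMMETROPIA: GroupGeometry(
            se_mean=0.85, se_sd=0.55, se_lo=-0.499, se_hi=1.999,
            ps_length=(16.9, 0.7), height=(23.5, 0.9), width=(23.7, 0.9),
            acd=(2.75, 0.25), lens_thickness=(3.2, 0.10),
            lens_volume=(84.0, 10.0), corneal_radius=(7.79, 0.25),
        ),
        MYOPIA: GroupGeometry(
            se_mean=-1.7, se_sd=1.2, se_lo=-10.0, se_hi=-0.5,
            ps_length=(17.7, 0.9), height=(24.1, 0.9), width=(24.0, 1.0),
            acd=(3.15, 0.25), lens_thickness=(3.2, 0.10),
            lens_volume=(88.0, 10.0), corneal_radius=(7.72, 0.25),
        ),
    }


@dataclass
class IntensityModel:
    """Mean tissue intensities (arbitrary units) for T2-like fat-sat contrast."""

    vitreous: float = 1000.0
    aqueous: float = 950.0
    lens: float = 250.0
    orbit: float = 350.0
    air: float = 50.0


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic orbital-MRI cohort."""

    group_proportions: dict[str, float] = field(
        default_factory=lambda: {MYOPIA: 0.123, HYPEROPIA: 0.075, EMMETROPIA: 0.802}
    )
    groups: dict[str, GroupGeometry] = field(default_factory=_default_groups)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    noise_sd: float = 20.0
    motion_blur_mm: float = 0.0
    # shared latent size factor: loading per geometric dimension (fraction of
    # the within-group SD carried by the common factor); 0.7 reproduces the
    # ~0.6-0.7 inter-dimension correlations seen in school-age cohorts
    size_loading: float = 0.7
    # covariate emulation: mean, sd, loading on the latent size factor
    body_height: tuple[float, float, float] = (141.7, 6.5, 0.45)
    birth_weight: tuple[float, float, float] = (3434.0, 564.0, 0.30)
    gestational_age: tuple[float, float, float] = (39.8, 1.8, 0.08)
    age: tuple[float, float] = (10.1, 0.59)
    girl_fraction: float = 0.515
    # axial-length growth rate (mm/y) and its correlation with SE
    al_growth: tuple[float, float] = (0.21, 0.09)
    al_growth_se_corr: float = -0.40
    # eye placement (world mm): right/left eye x positions, eye center y/z
    eye_x: tuple[float, float] = (72.0, 24.0)
    eye_yz: tuple[float, float] = (40.0, 32.0)
    center_jitter_mm: float = 1.5
    rotation_sd_deg: float = 2.5
    # optical-biometry emulation
    delta_al_mm: float = 0.18           # biometry AL minus true (MRI) AL
    al_noise_sd: float = 0.454          # SD of the biometry-vs-MRI difference
    acd_offset_mm: float = 0.9          # optical ACD includes the cornea
    acd_noise_sd: float = 0.2
    cycloplegia_fail_fraction: float = 0.10
    scan_quality_fail_fraction: float = 0.0


@dataclass
class RegConfig:
    """Atlas-to-target registration settings."""

    transform: str = "affine"            # identity | translation | rigid | affine
    metric: str = "mean_squares"         # mean_squares | mattes
    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0)
    iterations: int = 100
    learning_rate: float = 1.0
    label_interp: str = "linear"         # linear (soft one-hot) | nearest
    sampling_fraction: float = 0.25


@dataclass
class RFConfig:
    """Random-forest voxel-classifier settings."""

    n_trees: int = 100
    max_depth: int | None = None
    max_features: str = "sqrt"
    voxels_per_class: int = 2500         # per training subject, per class (cap)
    n_jobs: int = 1


@dataclass
class SegmentationConfig:
    """Hyper-parameters of the atlas x classifier fusion pipeline."""

    reg: RegConfig = field(default_factory=RegConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    scales_mm: tuple[float, ...] = (1.0, 1.6, 4.0)
    background_bias: float = 0.5         # multiplicative down-weight on background
    floor_eps: float = 0.01              # additive floor on atlas probabilities
    atlases_per_target: int = 5          # atlases registered per target image
    roi_dilation_mm: float = 4.0         # classify only near the fused atlas prior


@dataclass
class PipelineConfig:
    """Umbrella configuration for an end-to-end run."""

    seed: int = 0
    n_subjects: int = 12
    k_folds: int = 3
    grid: GridConfig = field(default_factory=GridConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sphericity_threshold: float = 0.005
    myopia_cutoff: float = -0.5
    hyperopia_cutoff: float = 2.0
    swap_sphericity_labels: bool = False


def config_to_dict(cfg: Any) -> Any:
    """Recursively convert nested config dataclasses to plain JSON-able data."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, dict):
        return {str(k): config_to_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    return cfg


def config_hash(cfg: Any) -> str:
    """Stable short hash of a config, for provenance blocks."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
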