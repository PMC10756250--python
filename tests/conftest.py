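"""Shared fixtures: coarse phantom grids and small rendered cohorts.

Unit tests run on a 2 mm grid covering the same orbital FOV as the default
1 mm grid — geometry and contrast are identical, voxel counts are 8x lower.
"""

import dataclasses

import numpy as np
import pytest

from oculomri.config import CohortConfig, GridConfig, GroupGeometry
from oculomri.phantom import render_phantom, sample_phantom_spec
from oculomri.segmentation import LabelledSubject


def zero_sd_config(**overrides) -> CohortConfig:
    """Cohort config with every variance source switched off: each subject
    is exactly the group-mean eye, unrotated and centered."""
    cfg = CohortConfig(**overrides)
    cfg.groups = {
        name: dataclasses.replace(
            g,
            se_sd=0.0,
            ps_length=(g.ps_length[0], 0.0),
            height=(g.height[0], 0.0),
            width=(g.width[0], 0.0),
            acd=(g.acd[0], 0.0),
            lens_thickness=(g.lens_thickness[0], 0.0),
            lens_volume=(g.lens_volume[0], 0.0),
            corneal_radius=(g.corneal_radius[0], 0.0),
        )
        for name, g in cfg.groups.items()
    }
    cfg.noise_sd = 0.0
    cfg.center_jitter_mm = 0.0
    cfg.rotation_sd_deg = 0.0
    return cfg


@pytest.fixture(scope="session")
def coarse_grid() -> GridConfig:
    return GridConfig(shape=(48, 48, 32), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def coarse_cohort(coarse_grid) -> list[LabelledSubject]:
    """Six rendered phantoms on the 2 mm grid, fixed seed."""
    cfg = CohortConfig()
    rng = np.random.default_rng(11)
    out = []
    for i in range(6):
        spec = sample_phantom_spec(cfg, rng, f"coarse-{i:02d}")
        scan, labels = render_phantom(spec, coarse_grid)
        out.append(LabelledSubject(spec.subject_id, scan, labels))
    return out


@pytest.fixture(scope="session")
def emmetropic_label_map():
    """Noiseless group-mean emmetropic phantom at 1 mm voxels."""
    cfg = zero_sd_config()
    rng = np.random.default_rng(0)
    spec = sample_phantom_spec(cfg, rng, "emm-mean", group="emmetropia")
    _, labels = render_phantom(spec)
    return spec, labels
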