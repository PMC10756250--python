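"""Synthetic orbital-MRI phantom cohort with ground-truth segmentations.

Each phantom eye is a three-compartment model on an orbit-cropped 3D grid:

* the globe is an ellipsoid with semi-axes along the eye's anatomic
  anterior-posterior (AP), superior-inferior (SI) and left-right (LR) axes;
* the lens is a small oblate ellipsoid on the AP axis whose anterior surface
  touches the anterior-chamber plane;
* the anterior chamber (AC) is the spherical-cap slab of the globe anterior
  to that plane; the posterior segment (PS) is the rest of the globe.

True geometry is drawn from group-conditional normals (myopia / emmetropia /
hyperopia), so axial elongation, sphericity and volume co-vary with refractive
error the way they do in school-age cohorts.  A shared latent "size" factor
couples eye dimensions to body height, birth weight and gestational age.
Optical biometry is emulated from the true geometry with a configurable
instrument offset (axial length reads long relative to the MRI truth) and
measurement noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .config import (
    GROUPS,
    CohortConfig,
    GridConfig,
    GroupGeometry,
    IntensityModel,
    config_hash,
    config_to_dict,
)
from .io import OcularLabelMap, ScanVolume, side_codes, write_label_map, write_scan

MAX_REJECTIONS = 100
_EYE_JITTER_FRAC = 0.2  # share of within-group SD that is independent per eye


@dataclass
class EyeSpec:
    """Ground-truth geometry of one eye, in its own (AP, SI, LR) frame."""

    ps_semi_axes: np.ndarray      # globe semi-axes (AP, SI, LR), mm
    lens_semi_axes: np.ndarray    # lens semi-axes (AP, SI, LR), mm
    lens_center_offset: float     # lens center along AP from globe center, mm
    ac_depth: float               # anterior-chamber depth along AP, mm
    center: np.ndarray            # world position of the globe center, mm
    rotation_deg: np.ndarray      # small extrinsic xyz Euler rotation, deg

    def __post_init__(self) -> None:
        self.ps_semi_axes = np.asarray(self.ps_semi_axes, dtype=float)
        self.lens_semi_axes = np.asarray(self.lens_semi_axes, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    # ---- true (analytic) biometry -------------------------------------
    @property
    def al_true(self) -> float:
        """Full AP extent of the globe (PS + lens + AC), mm."""
        return 2.0 * self.ps_semi_axes[0]

    @property
    def lens_thickness_true(self) -> float:
        return 2.0 * self.lens_semi_axes[0]

    @property
    def ps_length_true(self) -> float:
        return self.al_true - self.ac_depth - self.lens_thickness_true

    @property
    def height_true(self) -> float:
        return 2.0 * self.ps_semi_axes[1]

    @property
    def width_true(self) -> float:
        return 2.0 * self.ps_semi_axes[2]


@dataclass
class PhantomSpec:
    """Generative ground truth for one synthetic subject."""

    subject_id: str
    eyes: dict[str, EyeSpec]                 # keys: 'right', 'left'
    se_true: float
    group_true: str
    noise_sd: float
    motion_blur_mm: float = 0.0
    covariates: dict[str, float | str] = field(default_factory=dict)

    def validate(self) -> None:
        for side, eye in self.eyes.items():
            if np.any(eye.ps_semi_axes <= 0) or np.any(eye.lens_semi_axes <= 0):
                raise ValueError(f"{self.subject_id}/{side}: semi-axes must be > 0")
            if eye.ac_depth <= 0:
                raise ValueError(f"{self.subject_id}/{side}: ac_depth must be > 0")
        sep = np.linalg.norm(self.eyes["right"].center - self.eyes["left"].center)
        if sep <= 40.0:
            raise ValueError(
                f"{self.subject_id}: eye centers must be > 40 mm apart (got {sep:.1f})"
            )


# ---------------------------------------------------------------------------
# sampling


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed after 1000 draws")


def _mixture_se_moments(config: CohortConfig) -> tuple[float, float]:
    m = sum(config.group_proportions[g] * config.groups[g].se_mean for g in GROUPS)
    v = sum(
        config.group_proportions[g]
        * (config.groups[g].se_sd ** 2 + config.groups[g].se_mean ** 2)
        for g in GROUPS
    ) - m**2
    return m, float(np.sqrt(max(v, 1e-12)))


def _lens_radius(volume: float, thickness: float) -> float:
    # V = 4/3 pi (t/2) r^2  ->  r
    return float(np.sqrt(volume / ((4.0 / 3.0) * np.pi * (thickness / 2.0))))


def sample_phantom_spec(
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    group: str | None = None,
) -> PhantomSpec:
    """Draw one subject's ground-truth spec from the cohort model.

    ``group`` fixes the refraction group; otherwise it is drawn from the
    configured proportions.  Dimensions are drawn from group-conditional
    normals linked by a shared latent size factor; physically impossible draws
    (non-positive sizes, lens + AC exceeding the globe) are rejected and
    redrawn, erroring after 100 rejections.
    """
    if group is None:
        names = list(config.group_proportions)
        probs = np.array([config.group_proportions[g] for g in names], dtype=float)
        probs = probs / probs.sum()
        group = str(names[int(rng.choice(len(names), p=probs))])
    if group not in config.groups:
        raise ValueError(f"unknown refraction group {group!r}")
    geo: GroupGeometry = config.groups[group]

    se_true = _truncated_normal(rng, geo.se_mean, geo.se_sd, geo.se_lo, geo.se_hi)
    z_size = rng.normal()

    lam = config.size_loading
    jit = _EYE_JITTER_FRAC
    resid = np.sqrt(max(1.0 - lam**2 - jit**2, 0.0))

    def draw_dim(mean_sd: tuple[float, float]) -> tuple[float, float]:
        """Subject-level draw plus an independent per-eye jitter; returns
        the value for (right, left)."""
        mean, sd = mean_sd
        base = mean + sd * (lam * z_size + resid * rng.normal())
        return (base + sd * jit * rng.normal(), base + sd * jit * rng.normal())

    rejections = 0
    while True:
        ps_len = draw_dim(geo.ps_length)
        height = draw_dim(geo.height)
        width = draw_dim(geo.width)
        acd = draw_dim(geo.acd)
        lens_t = draw_dim(geo.lens_thickness)
        lens_v = draw_dim(geo.lens_volume)
        ok = all(
            v > 0
            for pair in (ps_len, height, width, acd, lens_t, lens_v)
            for v in pair
        )
        if ok:
            break
        rejections += 1
        if rejections > MAX_REJECTIONS:
            raise RuntimeError(
                f"{subject_id}: >{MAX_REJECTIONS} rejected geometry draws; "
                "check the cohort configuration"
            )

    eyes: dict[str, EyeSpec] = {}
    for i, side in enumerate(("right", "left")):
        al = ps_len[i] + acd[i] + lens_t[i]
        a_ap, a_si, a_lr = al / 2.0, height[i] / 2.0, width[i] / 2.0
        l_ap = lens_t[i] / 2.0
        l_r = _lens_radius(lens_v[i], lens_t[i])
        center = np.array(
            [config.eye_x[i], config.eye_yz[0], config.eye_yz[1]], dtype=float
        )
        # jitter clipped at 2 SD so the eyes stay comfortably separated
        j = config.center_jitter_mm
        center += np.clip(rng.normal(0.0, j, size=3), -2 * j, 2 * j)
        rot = rng.normal(0.0, config.rotation_sd_deg, size=3)
        eyes[side] = EyeSpec(
            ps_semi_axes=np.array([a_ap, a_si, a_lr]),
            lens_semi_axes=np.array([l_ap, l_r, l_r]),
            lens_center_offset=a_ap - acd[i] - l_ap,
            ac_depth=acd[i],
            center=center,
            rotation_deg=rot,
        )

    def cov(mean: float, sd: float, loading: float) -> float:
        r = np.sqrt(max(1.0 - loading**2, 0.0))
        return float(mean + sd * (loading * z_size + r * rng.normal()))

    se_m, se_s = _mixture_se_moments(config)
    z_se = (se_true - se_m) / se_s
    rho = config.al_growth_se_corr
    al_growth = config.al_growth[0] + config.al_growth[1] * (
        rho * z_se + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal()
    )
    covariates = {
        "age": float(rng.normal(*config.age)),
        "sex": "girl" if rng.random() < config.girl_fraction else "boy",
        "body_height": cov(*config.body_height),
        "birth_weight": cov(*config.birth_weight),
        "gestational_age": cov(*config.gestational_age),
        "al_growth": float(al_growth),
        "corneal_radius": float(
            rng.normal(geo.corneal_radius[0], geo.corneal_radius[1])
        ),
        "scan_quality_pass": bool(
            rng.random() >= config.scan_quality_fail_fraction
        ),
    }

    spec = PhantomSpec(
        subject_id=subject_id,
        eyes=eyes,
        se_true=se_true,
        group_true=group,
        noise_sd=config.noise_sd,
        motion_blur_mm=config.motion_blur_mm,
        covariates=covariates,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# rendering


def _grid_affine(grid: GridConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _eye_frame_coords(eye: EyeSpec, xyz: np.ndarray) -> np.ndarray:
    """World points (..., 3) -> eye frame (LR, AP, SI) about the globe center."""
    p = xyz - eye.center
    return p @ eye.rotation  # columns of R are the eye's local axes in world

def _eye_masks(eye: EyeSpec, xyz: np.ndarray) -> dict[str, np.ndarray]:
    q = _eye_frame_coords(eye, xyz)
    lr, ap, si = q[..., 0], q[..., 1], q[..., 2]
    a_ap, a_si, a_lr = eye.ps_semi_axes
    l_ap, l_si, l_lr = eye.lens_semi_axes
    globe = (lr / a_lr) ** 2 + (ap / a_ap) ** 2 + (si / a_si) ** 2 <= 1.0
    if l_ap > 0 and l_si > 0 and l_lr > 0:
        lens = (
            (lr / l_lr) ** 2
            + ((ap - eye.lens_center_offset) / l_ap) ** 2
            + (si / l_si) ** 2
            <= 1.0
        )
    else:
        lens = np.zeros_like(globe)
    ac = globe & ~lens & (ap > a_ap - eye.ac_depth)
    ps = globe & ~lens & ~ac
    return {"ps": ps, "lens": lens & globe, "ac": ac}


def render_phantom(
    spec: PhantomSpec,
    grid: GridConfig | None = None,
    intensity: "IntensityModel | None" = None,
) -> tuple[ScanVolume, OcularLabelMap]:
    """Voxelize one subject onto the acquisition grid.

    Returns the T2-like intensity volume (tissue means + optional motion blur
    + additive Gaussian noise seeded from the spec's subject id, so rendering
    is a pure function of the spec) and the ground-truth label map.  Raises if
    a globe extends outside the FOV.
    """
    grid = grid or GridConfig()
    affine = _grid_affine(grid)
    shape = tuple(grid.shape)

    fov_lo = np.asarray(grid.origin)
    fov_hi = fov_lo + np.asarray(grid.fov_mm)
    for side, eye in spec.eyes.items():
        r = float(np.max(eye.ps_semi_axes))
        if np.any(eye.center - r < fov_lo) or np.any(eye.center + r > fov_hi):
            raise ValueError(
                f"{spec.subject_id}: {side} eye extends outside the FOV"
            )

    idx = np.indices(shape, dtype=np.float32)
    xyz = np.stack(
        [idx[d] * grid.spacing[d] + grid.origin[d] for d in range(3)], axis=-1
    )

    labels = np.zeros(shape, dtype=np.int16)
    im = intensity if intensity is not None else IntensityModel()
    image = np.full(shape, im.air, dtype=np.float32)

    # orbital soft tissue around each globe
    for eye in spec.eyes.values():
        q = _eye_frame_coords(eye, xyz)
        semi = eye.ps_semi_axes[[2, 0, 1]] + 8.0  # (LR, AP, SI) order
        orbit = np.sum((q / semi) ** 2, axis=-1) <= 1.0
        image[orbit] = im.orbit

    tissue_value = {"ps": im.vitreous, "lens": im.lens, "ac": im.aqueous}
    for side, eye in spec.eyes.items():
        codes = side_codes(side)
        masks = _eye_masks(eye, xyz)
        for region in ("ps", "ac", "lens"):  # lens last: carve out of PS/AC
            m = masks[region]
            labels[m] = codes[region]
            image[m] = tissue_value[region]

    if spec.motion_blur_mm > 0:
        sigma = [spec.motion_blur_mm / s for s in grid.spacing]
        image = ndimage.gaussian_filter(image, sigma=sigma)
    if spec.noise_sd > 0:
        seed = zlib.crc32(f"{spec.subject_id}/render".encode()) % (2**31)
        noise_rng = np.random.default_rng(seed)
        image = image + noise_rng.normal(0.0, spec.noise_sd, size=shape).astype(
            np.float32
        )

    scan = ScanVolume(data=image, affine=affine, subject_id=spec.subject_id)
    label_map = OcularLabelMap(
        labels=labels, affine=affine, subject_id=spec.subject_id
    )
    return scan, label_map


def analytic_ellipsoid_mask(
    semi_axes,
    center,
    grid: GridConfig,
    rotation: np.ndarray | None = None,
    soft: bool = True,
    ramp_width_vox: float = 2.0,
) -> np.ndarray:
    """Voxelize an analytic ellipsoid, optionally with partial volume.

    With ``soft=True`` each voxel holds a fuzzy membership derived from the
    approximate signed distance to the surface (clipped linear ramp of
    ``ramp_width_vox`` voxels), so interpolated 0.5-level measurements recover
    the analytic surface to a small fraction of a voxel.  With ``soft=False``
    the mask is the plain center-inside voxelization.
    """
    semi = np.asarray(semi_axes, dtype=float)
    center = np.asarray(center, dtype=float)
    idx = np.indices(grid.shape, dtype=np.float32)
    xyz = np.stack(
        [idx[d] * grid.spacing[d] + grid.origin[d] for d in range(3)], axis=-1
    )
    q = xyz - center
    if rotation is not None:
        q = q @ np.asarray(rotation, dtype=float)
    f = np.sqrt(np.sum((q / semi) ** 2, axis=-1))
    if not soft:
        return f <= 1.0
    grad = np.sqrt(np.sum((q / semi**2) ** 2, axis=-1)) / np.maximum(f, 1e-9)
    dist = (1.0 - f) / np.maximum(grad, 1e-9)  # + inside, mm
    h = ramp_width_vox * float(np.mean(grid.spacing))
    return np.clip(0.5 + dist / h, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# optical-biometry emulation


def emulate_optical_biometry(
    spec: PhantomSpec,
    rng: np.random.Generator,
    delta_al: float = 0.18,
    al_noise_sd: float = 0.454,
    acd_offset: float = 0.9,
    acd_noise_sd: float = 0.2,
    cycloplegia_fail_fraction: float = 0.10,
) -> dict[str, float | str]:
    """Emulate an IOL-Master-style record from the ground-truth geometry.

    Axial length reads ``delta_al`` longer than the true AP extent on average
    (the instrument measures cornea to retinal pigment epithelium, whereas the
    segmentation stops at the vitreoretinal surface), with Gaussian
    measurement noise.  Pupil diameter is sampled so a configurable fraction
    fails the >= 6.0 mm cycloplegia rule.
    """
    eye = spec.eyes["right"]
    al_b = eye.al_true + delta_al + (rng.normal(0.0, al_noise_sd) if al_noise_sd else 0.0)
    acd_b = eye.ac_depth + acd_offset + (
        rng.normal(0.0, acd_noise_sd) if acd_noise_sd else 0.0
    )
    cylinder = -abs(rng.normal(0.0, 0.5))
    sphere = spec.se_true - cylinder / 2.0
    if rng.random() < cycloplegia_fail_fraction:
        pupil = float(rng.uniform(4.5, 5.9))
    else:
        pupil = float(6.0 + abs(rng.normal(1.2, 0.5)))
    cov = spec.covariates
    return {
        "subject_id": spec.subject_id,
        "al_biometry": float(al_b),
        "cr": float(cov.get("corneal_radius", 7.78)),
        "acd_biometry": float(acd_b),
        "sphere": float(sphere),
        "cylinder": float(cylinder),
        "pupil_diameter": pupil,
        "age": float(cov.get("age", 10.1)),
        "sex": str(cov.get("sex", "girl")),
        "body_height": float(cov.get("body_height", 141.7)),
        "birth_weight": float(cov.get("birth_weight", 3434.0)),
        "gestational_age": float(cov.get("gestational_age", 39.8)),
        "al_growth": float(cov.get("al_growth", 0.21)),
    }


def spec_true_row(spec: PhantomSpec, side: str = "right") -> dict[str, float | str]:
    """Flatten one eye's analytic ground-truth biometry into a table row."""
    eye = spec.eyes[side]
    al = eye.al_true
    h, w = eye.height_true, eye.width_true
    return {
        "subject_id": spec.subject_id,
        "group_true": spec.group_true,
        "se_true": spec.se_true,
        "al_true": al,
        "ps_length_true": eye.ps_length_true,
        "acd_true": eye.ac_depth,
        "lens_thickness_true": eye.lens_thickness_true,
        "height_true": h,
        "width_true": w,
        "hs_true": (h / al) ** 2 - 1.0,
        "vs_true": (w / al) ** 2 - 1.0,
        "scan_quality_pass": spec.covariates.get("scan_quality_pass", True),
    }


def sample_cohort_records(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Tabular cohort (true geometry + emulated biometry) without rendering.

    Used for cohort-scale statistics where voxelizing thousands of volumes
    would add nothing: the generative truth already defines the quantities.
    """
    rows = []
    for i in range(n):
        spec = sample_phantom_spec(config, rng, subject_id=f"sub-{i:04d}")
        row = spec_true_row(spec)
        row.update(
            emulate_optical_biometry(
                spec,
                rng,
                delta_al=config.delta_al_mm,
                al_noise_sd=config.al_noise_sd,
                acd_offset=config.acd_offset_mm,
                acd_noise_sd=config.acd_noise_sd,
                cycloplegia_fail_fraction=config.cycloplegia_fail_fraction,
            )
        )
        rows.append(row)
    columns = list(rows[0].keys()) if rows else list(
        spec_true_row(
            sample_phantom_spec(config, np.random.default_rng(0))
        ).keys()
    )
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# cohort generation to disk


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path,
    rng: np.random.Generator,
    n: int,
    grid: GridConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write ``n`` rendered subjects (scan + labels as .nii.gz), a cohort CSV
    and a manifest JSON; returns the manifest dict."""
    grid = grid or GridConfig()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}: {exc}") from exc

    specs = [
        sample_phantom_spec(config, rng, subject_id=f"sub-{i:04d}") for i in range(n)
    ]
    rows = []
    files: list[dict[str, str]] = []
    for spec in specs:
        scan, labels = render_phantom(spec, grid, intensity=config.intensity)
        scan_path = out_dir / f"{spec.subject_id}_scan.nii.gz"
        label_path = out_dir / f"{spec.subject_id}_labels.nii.gz"
        write_scan(scan, scan_path)
        write_label_map(labels, label_path)
        files.append(
            {
                "subject_id": spec.subject_id,
                "scan": scan_path.name,
                "labels": label_path.name,
            }
        )
        row = spec_true_row(spec)
        row.update(
            emulate_optical_biometry(
                spec,
                rng,
                delta_al=config.delta_al_mm,
                al_noise_sd=config.al_noise_sd,
                acd_offset=config.acd_offset_mm,
                acd_noise_sd=config.acd_noise_sd,
                cycloplegia_fail_fraction=config.cycloplegia_fail_fraction,
            )
        )
        rows.append(row)

    cohort_csv = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_csv, index=False)
    from .io import LABEL_CODES

    (out_dir / "label_codes.json").write_text(
        json.dumps({str(k): v for k, v in LABEL_CODES.items()}, indent=2)
    )
    manifest = {
        "n_subjects": n,
        "seed": seed,
        "config_hash": config_hash(config),
        "grid": config_to_dict(grid),
        "cohort_csv": cohort_csv.name,
        "label_codes": "label_codes.json",
        "subjects": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
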