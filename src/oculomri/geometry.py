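"""Per-eye anatomic coordinate system and 3D biometry from a label map.

The anterior-posterior (AP) axis of an eye runs from the posterior-segment
centroid to the lens centroid.  The superior-inferior (SI) axis is orthogonal
to the plane spanned by AP and the inter-eye direction (right-PS centroid to
left-PS centroid), with its sign fixed to point superiorly in world
coordinates; the left-right (LR) axis completes the right-handed set.

Lengths are measured sub-voxel as chords of the trilinearly interpolated
compartment masks at the 0.5 level; volumes are voxel counts times the voxel
volume.  Sphericity compares a transverse dimension with the axial length:
S = d^2 / AL^2 - 1, oblate when S exceeds a small positive threshold, prolate
below the negative threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import OcularLabelMap, side_codes

OBLATE = "oblate"
SPHERICAL = "spherical"
PROLATE = "prolate"

_DEFAULT_THRESHOLD = 0.005


@dataclass
class EyeAxes:
    """Orthonormal right-handed anatomic axes of one eye, in world mm."""

    ap: np.ndarray
    si: np.ndarray
    lr: np.ndarray
    ps_centroid: np.ndarray
    lens_centroid: np.ndarray
    side: str

    def __post_init__(self) -> None:
        for name in ("ap", "si", "lr"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} axis is not unit length")
        for a, b in (("ap", "si"), ("ap", "lr"), ("si", "lr")):
            if abs(float(getattr(self, a) @ getattr(self, b))) > 1e-6:
                raise ValueError(f"axes {a} and {b} are not orthogonal")


@dataclass
class EyeBiometry:
    """Lengths (mm), volumes (mm^3), sphericities and shape class of one eye."""

    side: str
    al_mri: float
    ps_length: float
    acd_mri: float
    lens_thickness: float
    height: float
    width: float
    ps_volume: float
    lens_volume: float
    ac_volume: float
    hs: float
    vs: float
    shape_h: str
    shape_v: str

    def as_row(self) -> dict[str, float | str]:
        return {f"{k}": v for k, v in self.__dict__.items()}


def _centroid_world(label_map: OcularLabelMap, code: int) -> np.ndarray:
    """Unweighted mean of voxel centers carrying ``code``, in world mm."""
    idx = np.argwhere(label_map.labels == code)
    if idx.size == 0:
        name = label_map.codebook.get(code, str(code))
        raise ValueError(
            f"{label_map.subject_id}: no voxels for class {name!r} (code {code})"
        )
    return label_map.voxel_to_world(idx.mean(axis=0))


def compute_axes(label_map: OcularLabelMap, side: str) -> EyeAxes:
    """Derive the AP/SI/LR anatomic axes for one eye from its segmentation."""
    codes = side_codes(side)
    other = side_codes("left" if side == "right" else "right")
    ps_c = _centroid_world(label_map, codes["ps"])
    lens_c = _centroid_world(label_map, codes["lens"])
    right_ps = ps_c if side == "right" else _centroid_world(label_map, other["ps"])
    left_ps = ps_c if side == "left" else _centroid_world(label_map, other["ps"])

    ap = lens_c - ps_c
    n = np.linalg.norm(ap)
    if n < 1e-9:
        raise ValueError(f"{side}: PS and lens centroids coincide")
    ap = ap / n

    u = left_ps - right_ps
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise ValueError("left and right PS centroids coincide")
    u = u / nu

    si = np.cross(ap, u)
    ns = np.linalg.norm(si)
    if ns < 1e-6:
        raise ValueError(
            f"{side}: AP axis and inter-eye direction are collinear"
        )
    si = si / ns
    if si[2] < 0:  # superior = +z in RAS world coordinates
        si = -si
    lr = np.cross(ap, si)
    lr = lr / np.linalg.norm(lr)
    return EyeAxes(ap=ap, si=si, lr=lr, ps_centroid=ps_c, lens_centroid=lens_c,
                   side=side)


def _line_level_extent(
    mask: np.ndarray,
    affine: np.ndarray,
    point: np.ndarray,
    direction: np.ndarray,
    step_frac: float = 0.25,
) -> tuple[float, np.ndarray]:
    """Extent between the first and last 0.5-level crossings of the
    interpolated mask along the line through ``point`` with ``direction``.

    Returns (extent_mm, sampled profile).  Extent is 0 when the line never
    enters the mask; raises when the mask does not fall below 0.5 before the
    FOV boundary on either side (the structure is cut by the FOV).
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    step = step_frac * float(spacing.min())

    inv = np.linalg.inv(affine)
    # world-space FOV half-diagonal bounds the needed parameter range
    corner = np.array(mask.shape, dtype=float)
    diag = float(np.linalg.norm(corner * spacing))
    t = np.arange(-diag, diag + step, step)
    pts = point[None, :] + t[:, None] * direction[None, :]
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    prof = ndimage.map_coordinates(
        mask.astype(np.float32), vox.T, order=1, mode="constant", cval=0.0
    )
    above = prof >= 0.5
    if not above.any():
        return 0.0, prof
    i0 = int(np.argmax(above))
    i1 = len(above) - 1 - int(np.argmax(above[::-1]))
    inside = np.all((vox >= 0) & (vox <= np.array(mask.shape) - 1), axis=1)
    first_in = int(np.argmax(inside))
    last_in = len(inside) - 1 - int(np.argmax(inside[::-1]))
    if i0 <= first_in + 1 or i1 >= last_in - 1:
        raise ValueError("line never exits the mask within the FOV")

    def cross(ia: int, ib: int) -> float:
        # linear interpolation of the 0.5 crossing between samples ia, ib
        va, vb = prof[ia], prof[ib]
        if vb == va:
            return t[ib]
        f = (0.5 - va) / (vb - va)
        return float(t[ia] + f * (t[ib] - t[ia]))

    t_first = cross(i0 - 1, i0)
    t_last = cross(i1 + 1, i1)
    return float(t_last - t_first), prof


def chord_length(
    mask: np.ndarray,
    affine: np.ndarray,
    anchor_point: np.ndarray,
    direction: np.ndarray,
    step_frac: float = 0.25,
) -> float:
    """Sub-voxel chord of a binary mask along a line through ``anchor_point``.

    The anchor must lie inside the mask (interpolated value >= 0.5).
    """
    anchor_point = np.asarray(anchor_point, dtype=float)
    inv = np.linalg.inv(affine)
    vox = anchor_point @ inv[:3, :3].T + inv[:3, 3]
    val = ndimage.map_coordinates(
        mask.astype(np.float32), vox.reshape(3, 1), order=1, mode="constant"
    )[0]
    if val < 0.5:
        raise ValueError("anchor point lies outside the mask")
    extent, _ = _line_level_extent(mask, affine, anchor_point, direction, step_frac)
    return extent


def classify_shape(s: float, threshold: float = _DEFAULT_THRESHOLD) -> str:
    """Oblate if S > threshold, prolate if S < -threshold, else spherical
    (boundary values count as spherical)."""
    if not np.isfinite(s):
        raise ValueError(f"sphericity must be finite, got {s}")
    if s > threshold:
        return OBLATE
    if s < -threshold:
        return PROLATE
    return SPHERICAL


def compartment_volume(label_map: OcularLabelMap, class_code: int) -> float:
    """Voxel-count volume (mm^3) of one labelled compartment."""
    if class_code not in label_map.codebook:
        raise ValueError(f"unknown class code {class_code}")
    count = int(np.count_nonzero(label_map.labels == class_code))
    return count * label_map.voxel_volume()


def measure_biometry(
    label_map: OcularLabelMap,
    side: str,
    sphericity_threshold: float = _DEFAULT_THRESHOLD,
    swap_sphericity_labels: bool = False,
) -> EyeBiometry:
    """Full 3D biometry of one eye from its six-region segmentation.

    Height and width are chords of the PS mask along the SI and LR axes
    through the PS centroid.  Along the AP line through the PS centroid the
    eye's length (AP extent of PS+lens+AC) is split into PS length, lens
    thickness and anterior-chamber depth.  ``hs`` pairs height with axial
    length and ``vs`` pairs width with axial length, as conventionally
    printed; ``swap_sphericity_labels`` exchanges the two for the
    alternative anatomical reading.
    """
    axes = compute_axes(label_map, side)
    codes = side_codes(side)
    ps_mask = label_map.mask(codes["ps"])
    lens_mask = label_map.mask(codes["lens"])
    ac_mask = label_map.mask(codes["ac"])
    union = ps_mask | lens_mask | ac_mask
    aff = label_map.affine
    c = axes.ps_centroid

    height = chord_length(ps_mask, aff, c, axes.si)
    width = chord_length(ps_mask, aff, c, axes.lr)
    ps_length = chord_length(ps_mask, aff, c, axes.ap)
    al_mri = chord_length(union, aff, c, axes.ap)
    lens_thickness, _ = _line_level_extent(lens_mask, aff, c, axes.ap)
    acd_mri, _ = _line_level_extent(ac_mask, aff, c, axes.ap)

    hs = (height / al_mri) ** 2 - 1.0
    vs = (width / al_mri) ** 2 - 1.0
    if swap_sphericity_labels:
        hs, vs = vs, hs
    return EyeBiometry(
        side=side,
        al_mri=al_mri,
        ps_length=ps_length,
        acd_mri=acd_mri,
        lens_thickness=lens_thickness,
        height=height,
        width=width,
        ps_volume=compartment_volume(label_map, codes["ps"]),
        lens_volume=compartment_volume(label_map, codes["lens"]),
        ac_volume=compartment_volume(label_map, codes["ac"]),
        hs=hs,
        vs=vs,
        shape_h=classify_shape(hs, sphericity_threshold),
        shape_v=classify_shape(vs, sphericity_threshold),
    )
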