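"""NIfTI I/O and the in-memory grid containers shared by all pipeline stages.

Volumes are stored in RAS world coordinates: array axis 0 runs left->right
(+x), axis 1 posterior->anterior (+y), axis 2 inferior->superior (+z), with a
4x4 voxel-to-world affine in millimetres.  Label maps share the grid of the
scan they segment and use the fixed seven-code book in :data:`LABEL_CODES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Code book for the six ocular regions plus background.
LABEL_CODES: dict[int, str] = {
    0: "background",
    1: "ps_right",
    2: "ps_left",
    3: "lens_right",
    4: "lens_left",
    5: "ac_right",
    6: "ac_left",
}

N_CLASSES = len(LABEL_CODES)

#: Region -> (right code, left code)
REGION_CODES = {"ps": (1, 2), "lens": (3, 4), "ac": (5, 6)}


def side_codes(side: str) -> dict[str, int]:
    """Return {'ps': code, 'lens': code, 'ac': code} for 'left' or 'right'."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    idx = 0 if side == "right" else 1
    return {region: codes[idx] for region, codes in REGION_CODES.items()}


@dataclass
class ScanVolume:
    """A 3D intensity volume on a regular grid with world (mm) geometry."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScanVolume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ScanVolume intensities must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @property
    def direction(self) -> np.ndarray:
        """Unit direction-cosine matrix (columns = world directions of axes)."""
        return self.affine[:3, :3] / self.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "ScanVolume | OcularLabelMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class OcularLabelMap:
    """Integer segmentation on a scan grid using :data:`LABEL_CODES`."""

    labels: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    codebook: dict[int, str] = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("label array must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - set(self.codebook)
        if bad:
            raise ValueError(f"labels outside code book: {sorted(bad)}")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given codes."""
        return np.isin(self.labels, codes)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "ScanVolume | OcularLabelMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


def read_scan(path: str | Path) -> ScanVolume:
    """Read a NIfTI-1 volume; raises FileNotFoundError/ValueError naming the path."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    return ScanVolume(data=data, affine=np.asarray(img.affine), subject_id=path.stem)


def write_scan(scan: ScanVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1, preserving dtype, grid and affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(scan.data, scan.affine)
    img.set_qform(scan.affine, code=1)
    img.set_sform(scan.affine, code=1)
    nib.save(img, str(path))
    return path


def read_label_map(path: str | Path) -> OcularLabelMap:
    scan = read_scan(path)
    labels = np.rint(scan.data).astype(np.int16)
    return OcularLabelMap(labels=labels, affine=scan.affine, subject_id=scan.subject_id)


def write_label_map(label_map: OcularLabelMap, path: str | Path) -> Path:
    vol = ScanVolume(
        data=label_map.labels.astype(np.int16),
        affine=label_map.affine,
        subject_id=label_map.subject_id,
    )
    return write_scan(vol, path)
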