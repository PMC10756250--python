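"""Six-region eye segmentation: atlas registration x voxel classification.

The method combines two per-voxel class-probability maps and takes their
product:

1. **Atlas fusion** — labelled atlas images are registered to the target
   scan (affine by default) and their warped labels averaged into a spatial
   prior over the seven classes (background + PS/lens/AC for each eye).
2. **Voxel classification** — a random forest fed 48 scale-space features
   per voxel (Gaussian-smoothed intensity, first and second derivatives,
   gradient magnitude, Laplacian, Hessian eigenvalues and determinant at
   scales 1.0, 1.6 and 4.0 mm) produces an intensity-driven probability map.
   The background-class probability is multiplicatively down-weighted (the
   "bias") so that eye tissue that locally resembles background is not
   over-ruled.

The two maps are multiplied voxel-wise (with a small additive floor on the
atlas prior so a zero prior cannot annihilate the classifier) and the argmax
gives the final label; ties break toward the lower class code.  Evaluation is
by Dice overlap under seeded k-fold cross-validation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .config import RegConfig, RFConfig, SegmentationConfig
from .io import LABEL_CODES, N_CLASSES, OcularLabelMap, ScanVolume

_LPS_FLIP = np.diag([-1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# SimpleITK bridging (RAS world <-> LPS)


def _to_sitk(scan: ScanVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(scan.data.transpose(2, 1, 0).astype(np.float32))
    )
    img.SetSpacing(tuple(float(s) for s in scan.spacing))
    img.SetOrigin(tuple(_LPS_FLIP @ scan.origin))
    img.SetDirection(tuple((_LPS_FLIP @ scan.direction).ravel()))
    return img


def _from_sitk(img: sitk.Image, subject_id: str = "") -> ScanVolume:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing())
    direction = _LPS_FLIP @ np.asarray(img.GetDirection()).reshape(3, 3)
    origin = _LPS_FLIP @ np.asarray(img.GetOrigin())
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing
    affine[:3, 3] = origin
    return ScanVolume(data=np.ascontiguousarray(data), affine=affine,
                      subject_id=subject_id)


# ---------------------------------------------------------------------------
# probability maps


@dataclass
class ClassProbabilityMap:
    """Per-voxel probability vector over the 7 label codes, summing to 1."""

    probs: np.ndarray          # (7, nx, ny, nz) float32
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4 or self.probs.shape[0] != N_CLASSES:
            raise ValueError(f"probs must be ({N_CLASSES}, nx, ny, nz)")
        if np.any(self.probs < -1e-6):
            raise ValueError("probabilities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]  # type: ignore[return-value]

    def normalized(self) -> "ClassProbabilityMap":
        total = self.probs.sum(axis=0, keepdims=True)
        total[total == 0] = 1.0
        return ClassProbabilityMap(probs=self.probs / total, affine=self.affine)

    def argmax_labels(self, subject_id: str = "") -> OcularLabelMap:
        labels = np.argmax(self.probs, axis=0).astype(np.int16)
        return OcularLabelMap(labels=labels, affine=self.affine,
                              subject_id=subject_id)

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class WarpedAtlas:
    """One atlas's label contribution resampled onto the target grid."""

    probs: np.ndarray          # (7, nx, ny, nz)
    affine: np.ndarray
    converged: bool
    metric_initial: float
    metric_final: float
    transform: sitk.Transform | None = None
    atlas_id: str = ""


def _make_transform(name: str) -> sitk.Transform:
    if name == "translation":
        return sitk.TranslationTransform(3)
    if name == "rigid":
        return sitk.Euler3DTransform()
    if name == "affine":
        return sitk.AffineTransform(3)
    raise ValueError(f"unknown transform family {name!r}")


def register_atlas(
    atlas_scan: ScanVolume,
    atlas_labels: OcularLabelMap,
    target_scan: ScanVolume,
    reg_config: RegConfig | None = None,
    seed: int | None = None,
) -> WarpedAtlas:
    """Register an atlas to a target and warp its labels onto the target grid.

    Returns soft per-class maps (one-hot labels resampled with linear
    interpolation by default).  If the optimizer diverges — the final metric
    is worse than the starting point, or the images do not overlap — the
    result is flagged ``converged=False`` so fusion can exclude it.
    """
    cfg = reg_config or RegConfig()
    fixed = _to_sitk(target_scan)
    moving = _to_sitk(atlas_scan)

    if cfg.transform == "identity":
        transform: sitk.Transform = sitk.Transform(3, sitk.sitkIdentity)
        converged, m0, m1 = True, 0.0, 0.0
    else:
        # identity start: atlases and targets share the acquisition FOV, so
        # no re-centering is wanted — volumes with genuinely disjoint FOVs
        # must surface as diverged instead of being silently aligned.  The
        # rotation/scaling center sits at the fixed-image center.
        initial = _make_transform(cfg.transform)
        if hasattr(initial, "SetCenter"):
            mid = [(s - 1) / 2.0 for s in fixed.GetSize()]
            initial.SetCenter(
                fixed.TransformContinuousIndexToPhysicalPoint(mid)
            )
        reg = sitk.ImageRegistrationMethod()
        if cfg.metric == "mean_squares":
            reg.SetMetricAsMeanSquares()
        elif cfg.metric == "mattes":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        else:
            raise ValueError(f"unknown metric {cfg.metric!r}")
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction,
                                        seed if seed is not None else 0)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.learning_rate,
            minStep=1e-4,
            numberOfIterations=cfg.iterations,
            relaxationFactor=0.6,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
        reg.SetInitialTransform(initial, inPlace=False)
        try:
            m0 = reg.MetricEvaluate(fixed, moving)
            transform = reg.Execute(fixed, moving)
            m1 = reg.GetMetricValue()
            converged = bool(np.isfinite(m1)) and m1 <= m0 + 1e-9
        except RuntimeError:
            transform = initial
            m0, m1 = np.nan, np.nan
            converged = False
        if converged:
            # require genuine FOV overlap under the final transform
            marker = -1.0e30
            probe = sitk.Resample(moving, fixed, transform,
                                  sitk.sitkNearestNeighbor, marker)
            frac = float(np.mean(sitk.GetArrayViewFromImage(probe) > marker / 2))
            if frac < 0.05:
                converged = False

    probs = _warp_labels(atlas_labels, target_scan, transform, cfg.label_interp)
    return WarpedAtlas(
        probs=probs,
        affine=target_scan.affine.copy(),
        converged=converged,
        metric_initial=float(m0),
        metric_final=float(m1),
        transform=transform,
        atlas_id=atlas_scan.subject_id,
    )


def _warp_labels(
    atlas_labels: OcularLabelMap,
    target_scan: ScanVolume,
    transform: sitk.Transform,
    label_interp: str,
) -> np.ndarray:
    fixed = _to_sitk(
        ScanVolume(np.zeros(target_scan.shape, dtype=np.float32),
                   target_scan.affine)
    )
    out = np.zeros((N_CLASSES, *target_scan.shape), dtype=np.float32)
    if label_interp == "nearest":
        lab_img = _to_sitk(
            ScanVolume(atlas_labels.labels.astype(np.float32),
                       atlas_labels.affine)
        )
        warped = sitk.Resample(lab_img, fixed, transform,
                               sitk.sitkNearestNeighbor, 0.0)
        lab = np.rint(
            sitk.GetArrayFromImage(warped).transpose(2, 1, 0)
        ).astype(np.int16)
        for code in LABEL_CODES:
            out[code] = lab == code
    elif label_interp == "linear":
        for code in range(1, N_CLASSES):
            onehot = (atlas_labels.labels == code).astype(np.float32)
            img = _to_sitk(ScanVolume(onehot, atlas_labels.affine))
            warped = sitk.Resample(img, fixed, transform, sitk.sitkLinear, 0.0)
            out[code] = sitk.GetArrayFromImage(warped).transpose(2, 1, 0)
        # whatever mass is left (including regions mapping outside the atlas)
        # belongs to background
        out[0] = np.clip(1.0 - out[1:].sum(axis=0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown label_interp {label_interp!r}")
    return out


def fuse_atlases(warped: Sequence[WarpedAtlas | np.ndarray]) -> ClassProbabilityMap:
    """Per-voxel class frequency across warped atlases, normalized to sum 1.

    Diverged registrations are excluded; an empty (or all-diverged) input is
    an error.
    """
    arrays = []
    affine = None
    for w in warped:
        if isinstance(w, WarpedAtlas):
            if not w.converged:
                continue
            arrays.append(w.probs)
            affine = w.affine
        else:
            arrays.append(np.asarray(w, dtype=np.float32))
    if not arrays:
        raise ValueError("fuse_atlases needs at least one converged atlas")
    if affine is None:
        affine = np.eye(4)
    mean = np.mean(arrays, axis=0, dtype=np.float32)
    return ClassProbabilityMap(probs=mean, affine=affine).normalized()


# ---------------------------------------------------------------------------
# scale-space features


@dataclass
class FeatureStack:
    """48 per-voxel scale-space features in a fixed, documented order.

    For each scale sigma in ``scales_mm``:
    smoothed, dx, dy, dz, dxx, dyy, dzz, dxy, dxz, dyz, gradient magnitude,
    Laplacian, Hessian eigenvalues (ascending), Hessian determinant.
    Derivatives are taken in mm (spacing-corrected Gaussian derivatives).
    """

    features: np.ndarray       # (nx, ny, nz, 48) float32
    names: list[str]
    affine: np.ndarray

    @property
    def n_features(self) -> int:
        return self.features.shape[-1]

    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_features)


def _hessian_eigs_det(h: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    shape = h["xx"].shape
    H = np.empty((*shape, 3, 3), dtype=np.float32)
    H[..., 0, 0] = h["xx"]; H[..., 1, 1] = h["yy"]; H[..., 2, 2] = h["zz"]
    H[..., 0, 1] = H[..., 1, 0] = h["xy"]
    H[..., 0, 2] = H[..., 2, 0] = h["xz"]
    H[..., 1, 2] = H[..., 2, 1] = h["yz"]
    eigs = np.linalg.eigvalsh(H.reshape(-1, 3, 3)).reshape(*shape, 3)
    det = (
        h["xx"] * (h["yy"] * h["zz"] - h["yz"] ** 2)
        - h["xy"] * (h["xy"] * h["zz"] - h["yz"] * h["xz"])
        + h["xz"] * (h["xy"] * h["yz"] - h["yy"] * h["xz"])
    )
    return eigs.astype(np.float32), det.astype(np.float32)


def extract_features(
    scan: ScanVolume, scales_mm: Sequence[float] = (1.0, 1.6, 4.0)
) -> FeatureStack:
    """Compute the 48-feature scale-space stack for every voxel."""
    if not np.all(np.isfinite(scan.data)):
        raise ValueError("scan intensities must be finite")
    data = scan.data.astype(np.float32)
    spacing = scan.spacing
    feats: list[np.ndarray] = []
    names: list[str] = []
    axes = "xyz"
    for scale in scales_mm:
        sig = [scale / s for s in spacing]

        def g(order: tuple[int, int, int]) -> np.ndarray:
            out = ndimage.gaussian_filter(data, sigma=sig, order=order,
                                          mode="nearest")
            denom = np.prod([spacing[a] ** order[a] for a in range(3)])
            return (out / denom).astype(np.float32)

        sm = g((0, 0, 0))
        d1 = {a: g(tuple(int(i == k) for i in range(3)))
              for k, a in enumerate(axes)}
        h = {}
        for i in range(3):
            for j in range(i, 3):
                order = [0, 0, 0]
                order[i] += 1
                order[j] += 1
                h[axes[i] + axes[j]] = g(tuple(order))
        grad = np.sqrt(d1["x"] ** 2 + d1["y"] ** 2 + d1["z"] ** 2)
        lap = h["xx"] + h["yy"] + h["zz"]
        eigs, det = _hessian_eigs_det(h)

        tag = f"s{scale:g}"
        feats += [sm, d1["x"], d1["y"], d1["z"],
                  h["xx"], h["yy"], h["zz"], h["xy"], h["xz"], h["yz"],
                  grad, lap, eigs[..., 0], eigs[..., 1], eigs[..., 2], det]
        names += [f"{tag}_{n}" for n in
                  ("smoothed", "dx", "dy", "dz", "dxx", "dyy", "dzz",
                   "dxy", "dxz", "dyz", "gradmag", "laplacian",
                   "hess_ev1", "hess_ev2", "hess_ev3", "hess_det")]
    stack = np.stack(feats, axis=-1)
    return FeatureStack(features=stack, names=names, affine=scan.affine.copy())


# ---------------------------------------------------------------------------
# random-forest voxel classifier


@dataclass
class ClassifierModel:
    """Trained voxel classifier mapping a 48-vector to 7 class probabilities."""

    rf: RandomForestClassifier
    n_features: int
    feature_names: list[str] = field(default_factory=list)
    version: str = "1"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(N, n_features) -> (N, 7) aligned to label codes 0..6."""
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        raw = self.rf.predict_proba(X)
        out = np.zeros((X.shape[0], N_CLASSES), dtype=np.float32)
        for col, code in enumerate(self.rf.classes_):
            out[:, int(code)] = raw[:, col]
        return out

    def save(self, path) -> None:
        joblib.dump({"version": self.version, "n_features": self.n_features,
                     "feature_names": self.feature_names, "rf": self.rf}, path)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        blob = joblib.load(path)
        return cls(rf=blob["rf"], n_features=blob["n_features"],
                   feature_names=blob.get("feature_names", []),
                   version=blob.get("version", "1"))


def sample_training_voxels(
    stack: FeatureStack,
    labels: OcularLabelMap,
    voxels_per_class: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced voxel subsample of one labelled subject."""
    X = stack.flat()
    y = labels.labels.reshape(-1)
    idx_parts = []
    for code in np.unique(y):
        idx = np.flatnonzero(y == code)
        if idx.size > voxels_per_class:
            idx = rng.choice(idx, size=voxels_per_class, replace=False)
        idx_parts.append(idx)
    sel = np.concatenate(idx_parts)
    return X[sel], y[sel]


def train_classifier(
    feature_stacks: Iterable[FeatureStack],
    label_maps: Iterable[OcularLabelMap],
    rf_config: RFConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClassifierModel:
    """Train the random forest on class-balanced voxel subsamples.

    Every label code must occur somewhere in the training data; missing
    classes are an error (the classifier could never predict them).
    """
    cfg = rf_config or RFConfig()
    rng = rng or np.random.default_rng(0)
    Xs, ys = [], []
    n_features = None
    for stack, labels in zip(feature_stacks, label_maps):
        n_features = stack.n_features
        X, y = sample_training_voxels(stack, labels, cfg.voxels_per_class, rng)
        Xs.append(X)
        ys.append(y)
    if not Xs:
        raise ValueError("no training subjects supplied")
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    missing = set(LABEL_CODES) - set(int(c) for c in np.unique(y))
    if missing:
        names = [LABEL_CODES[c] for c in sorted(missing)]
        raise ValueError(f"classes absent from training data: {names}")
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        n_jobs=cfg.n_jobs,
        random_state=int(rng.integers(2**31)),
    )
    rf.fit(X, y)
    return ClassifierModel(rf=rf, n_features=n_features or X.shape[1],
                           feature_names=[])


def classify_voxels(
    model: ClassifierModel,
    feature_stack: FeatureStack,
    background_bias: float = 0.5,
    roi_mask: np.ndarray | None = None,
) -> ClassProbabilityMap:
    """Classifier probability map with the background class down-weighted.

    ``background_bias`` multiplies the background probability before
    per-voxel renormalization (1.0 is a no-op).  When ``roi_mask`` is given,
    only voxels inside it are classified and the rest are background with
    probability 1 — the atlas prior vanishes there anyway, so this only
    saves time.
    """
    if not (0.0 < background_bias <= 1.0):
        raise ValueError("background_bias must be in (0, 1]")
    shape = feature_stack.features.shape[:3]
    probs = np.zeros((N_CLASSES, *shape), dtype=np.float32)
    probs[0] = 1.0
    if roi_mask is None:
        roi_mask = np.ones(shape, dtype=bool)
    X = feature_stack.features[roi_mask]
    if X.size:
        p = model.predict_proba(X)
        p[:, 0] *= background_bias
        p /= p.sum(axis=1, keepdims=True)
        probs[:, roi_mask] = p.T
    return ClassProbabilityMap(probs=probs, affine=feature_stack.affine.copy())


def combine_maps(
    atlas_map: ClassProbabilityMap,
    classifier_map: ClassProbabilityMap,
    floor_eps: float = 0.01,
    subject_id: str = "",
) -> OcularLabelMap:
    """Voxel-wise product of (atlas prior + floor) and classifier map, argmax.

    The additive floor keeps a unanimous-zero atlas prior from annihilating
    the classifier.  Ties break toward the lower class code (background
    first), deterministically.
    """
    if not atlas_map.same_grid(classifier_map):
        raise ValueError("atlas and classifier maps are on different grids")
    prod = (atlas_map.probs + floor_eps) * classifier_map.probs
    labels = np.argmax(prod, axis=0).astype(np.int16)
    return OcularLabelMap(labels=labels, affine=atlas_map.affine.copy(),
                          subject_id=subject_id)


# ---------------------------------------------------------------------------
# evaluation


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


@dataclass
class LabelledSubject:
    """One cohort member: scan plus ground-truth segmentation."""

    subject_id: str
    scan: ScanVolume
    labels: OcularLabelMap


@dataclass
class DiceReport:
    """Per-class Dice summary of a cross-validation run."""

    per_subject: pd.DataFrame          # columns: subject_id, fold, class, dice
    fold_assignment: dict[str, int]

    def summary(self) -> pd.DataFrame:
        g = self.per_subject.groupby("class")["dice"]
        out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
        out.index.name = "class"
        return out

    def mean_dice(self, class_name: str) -> float:
        sel = self.per_subject[self.per_subject["class"] == class_name]
        if sel.empty:
            raise KeyError(f"no Dice rows for class {class_name!r}")
        return float(sel["dice"].mean())


def _roi_from_prior(
    prior: ClassProbabilityMap, dilation_mm: float, spacing: np.ndarray
) -> np.ndarray:
    nonbg = prior.probs[1:].sum(axis=0) > 1e-3
    it = max(1, int(np.ceil(dilation_mm / float(np.min(spacing)))))
    return ndimage.binary_dilation(nonbg, iterations=it)


def segment_scan(
    target: ScanVolume,
    atlases: Sequence[LabelledSubject],
    model: ClassifierModel,
    config: SegmentationConfig | None = None,
    seed: int = 0,
) -> OcularLabelMap:
    """Full single-scan segmentation: register+fuse atlases, classify, combine.

    Features are extracted on a padded bounding box around the fused-prior
    region of interest; outside it the atlas prior is unanimous background,
    so the final argmax is background there regardless of the classifier.
    """
    cfg = config or SegmentationConfig()
    warped = []
    for atlas in atlases:
        s = (seed + zlib.crc32(f"{atlas.subject_id}->{target.subject_id}".encode())) % (2**31)
        warped.append(
            register_atlas(atlas.scan, atlas.labels, target, cfg.reg, seed=s)
        )
    prior = fuse_atlases(warped)
    roi = _roi_from_prior(prior, cfg.roi_dilation_mm, target.spacing)

    # padded ROI bounding box so the Gaussian filters see real context
    margin_mm = 2.0 * max(cfg.scales_mm)
    idx = np.argwhere(roi)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    pad = np.ceil(margin_mm / target.spacing).astype(int)
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, target.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_affine = target.affine.copy()
    sub_affine[:3, 3] = target.voxel_to_world(lo.astype(float))
    sub_scan = ScanVolume(np.ascontiguousarray(target.data[sl]), sub_affine,
                          subject_id=target.subject_id)
    stack = extract_features(sub_scan, cfg.scales_mm)
    clf_sub = classify_voxels(model, stack, cfg.background_bias,
                              roi_mask=roi[sl])
    probs = np.zeros((N_CLASSES, *target.shape), dtype=np.float32)
    probs[0] = 1.0
    probs[(slice(None),) + sl] = clf_sub.probs
    clf_map = ClassProbabilityMap(probs=probs, affine=target.affine.copy())
    return combine_maps(prior, clf_map, cfg.floor_eps,
                        subject_id=target.subject_id)


def cross_validate(
    cohort: Sequence[LabelledSubject],
    k: int,
    config: SegmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DiceReport:
    """Seeded k-fold cross-validation of the full segmentation pipeline.

    In each fold the atlases and the classifier come from the training split
    only; Dice is recorded per class for every test subject and summarized
    over all test subjects in all folds.
    """
    cfg = config or SegmentationConfig()
    rng = rng or np.random.default_rng(0)
    n = len(cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")

    order = rng.permutation(n)
    folds = [sorted(order[i::k]) for i in range(k)]
    fold_of = {cohort[i].subject_id: f for f, idx in enumerate(folds) for i in idx}

    # per-subject training subsample, extracted once and reused across folds
    sample_seeds = {s.subject_id: int(rng.integers(2**31)) for s in cohort}
    sample_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def training_sample(subj: LabelledSubject) -> tuple[np.ndarray, np.ndarray]:
        if subj.subject_id not in sample_cache:
            stack = extract_features(subj.scan, cfg.scales_mm)
            srng = np.random.default_rng(sample_seeds[subj.subject_id])
            sample_cache[subj.subject_id] = sample_training_voxels(
                stack, subj.labels, cfg.rf.voxels_per_class, srng
            )
        return sample_cache[subj.subject_id]

    rows = []
    for f, test_idx in enumerate(folds):
        test = [cohort[i] for i in test_idx]
        train = [s for i, s in enumerate(cohort) if i not in set(test_idx)]
        fold_rng = np.random.default_rng(int(rng.integers(2**31)))

        Xs, ys = zip(*(training_sample(s) for s in train))
        X, y = np.concatenate(Xs), np.concatenate(ys)
        rf = RandomForestClassifier(
            n_estimators=cfg.rf.n_trees, max_depth=cfg.rf.max_depth,
            max_features=cfg.rf.max_features, n_jobs=cfg.rf.n_jobs,
            random_state=int(fold_rng.integers(2**31)),
        )
        rf.fit(X, y)
        model = ClassifierModel(rf=rf, n_features=X.shape[1])

        for subj in test:
            n_atlas = min(cfg.atlases_per_target, len(train))
            pick = fold_rng.choice(len(train), size=n_atlas, replace=False)
            atlases = [train[i] for i in sorted(pick)]
            pred = segment_scan(subj.scan, atlases, model, cfg,
                                seed=int(fold_rng.integers(2**31)))
            for code, name in LABEL_CODES.items():
                if code == 0:
                    continue
                d = dice(subj.labels.labels == code, pred.labels == code)
                rows.append({"subject_id": subj.subject_id, "fold": f,
                             "class": name, "dice": d})

    report = DiceReport(
        per_subject=pd.DataFrame(rows, columns=["subject_id", "fold", "class", "dice"]),
        fold_assignment=fold_of,
    )
    return report
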