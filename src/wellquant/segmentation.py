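"""Binary cell-vs-background segmentation of well images, and its evaluation.

Two mask sources are provided behind one interface:

* ``segment_baseline`` — a deterministic, training-free classical pipeline
  (local-variance texture filter, Otsu threshold, hole filling, small-object
  removal). In brightfield, suspension cells read as a bright core inside a
  dark halo, so local intensity variance is high over cells and low over the
  empty well floor.
* a trainable per-pixel classifier (``train_segmenter`` / ``predict``) — a
  random forest over a multi-scale filter bank (Gaussian smoothings,
  gradient magnitude, Laplacian, local standard deviation), in the spirit of
  interactive texture-classification tools widely used for microscopy.
  Multi-scale features let it separate cells from much larger, smoother
  bubble artifacts that fool single-scale thresholding.

Agreement between masks is scored with the Jaccard index (intersection over
union, IoU), and two mask sources are compared through the per-image
difference in percent well-area coverage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, morphology
from sklearn.ensemble import RandomForestClassifier

from .geometry import CircleROI, WellImage

__all__ = [
    "SegMask",
    "SegModel",
    "ModelComparison",
    "segment_baseline",
    "train_segmenter",
    "predict",
    "iou",
    "coverage_fraction",
    "compare_models",
]


@dataclass
class SegMask:
    """Binary cell mask aligned to a WellImage; 1 = cell-covered."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SegModel:
    """A mask source: the classical baseline or a trained pixel classifier."""

    backend: Literal["classical_baseline", "trained_cnn"]
    parameters: object | None = None
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend == "trained_cnn" and not self.training_manifest:
            raise ValueError("a trained model must carry its training manifest")


@dataclass(frozen=True)
class ModelComparison:
    """Mean/SD of the per-image absolute coverage difference, in % points."""

    mean_coverage_diff_pct: float
    sd_coverage_diff_pct: float
    n_images: int


# ---------------------------------------------------------------------------
# feature bank

_GAUSS_SIGMAS = (1.0, 2.0, 4.0, 8.0)
_STD_WINDOWS = (3, 7, 15)


def _local_std(img: np.ndarray, size: int) -> np.ndarray:
    mean = ndimage.uniform_filter(img, size=size)
    sq = ndimage.uniform_filter(img * img, size=size)
    return np.sqrt(np.clip(sq - mean * mean, 0.0, None))


def _features(image: WellImage) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, F), on the unit intensity scale.

    Intensities are scaled by the dtype range (not per-image min/max) so a
    sparse or empty frame keeps the same absolute contrast as a busy one.
    """
    if np.issubdtype(image.pixels.dtype, np.integer):
        img = image.pixels.astype(float) / np.iinfo(image.pixels.dtype).max
    else:
        img = image.pixels.astype(float)
        hi = img.max()
        if hi > 1.0:
            img = img / hi
    feats = [img]
    for s in _GAUSS_SIGMAS:
        feats.append(ndimage.gaussian_filter(img, s))
    for s in (1.0, 2.0):
        feats.append(ndimage.gaussian_gradient_magnitude(img, s))
    feats.append(ndimage.gaussian_laplace(img, 2.0))
    for w in _STD_WINDOWS:
        feats.append(_local_std(img, w))
    return np.stack(feats, axis=-1)


# ---------------------------------------------------------------------------
# classical baseline

def segment_baseline(
    image: WellImage,
    roi: CircleROI,
    *,
    min_object_px: int | None = None,
) -> SegMask:
    """Deterministic texture segmentation with no training step.

    Local standard deviation (window ~ one cell radius) is thresholded by
    Otsu inside the ROI; the resulting cell-halo annuli are closed and
    filled so each cell becomes a solid disk, then specks smaller than a
    fraction of a cell are dropped. Everything outside the ROI is 0.
    """
    img = image.pixels.astype(float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return SegMask(np.zeros(image.shape, dtype=bool))
    img = (img - lo) / (hi - lo)

    cell_r_px = max(2.0, 7.5 / image.pixel_scale_um_per_px)
    win = max(3, int(round(cell_r_px)) | 1)
    texture = _local_std(img, win)

    inside = roi.contains(image.shape)
    if not inside.any():
        raise ValueError("ROI has no interior pixels")
    # The std window straddling the well rim lights up a closed ring that
    # hole-filling would flood; keep a rim-wide band out of the analysis.
    core = CircleROI(
        roi.center_x_px, roi.center_y_px, max(1.0, roi.radius_px - win)
    ).contains(image.shape)
    vals = texture[core]
    if vals.size == 0 or np.ptp(vals) < 1e-6:
        return SegMask(np.zeros(image.shape, dtype=bool))
    thr = filters.threshold_otsu(vals)
    # Guard against Otsu splitting pure sensor noise on cell-free frames.
    thr = max(thr, 0.05)
    mask = (texture > thr) & core
    mask = ndimage.binary_fill_holes(mask)
    # The sliding window dilates each cell footprint by ~win/2; shrink back.
    mask = morphology.erosion(mask, morphology.disk(win // 2))
    if min_object_px is None:
        min_object_px = max(4, int(0.2 * np.pi * cell_r_px**2))
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    mask &= inside
    return SegMask(mask)


# ---------------------------------------------------------------------------
# trainable pixel classifier

def _dataset_fingerprint(dataset: Sequence[tuple[WellImage, SegMask]]) -> str:
    h = hashlib.sha256()
    for img, msk in dataset:
        h.update(np.ascontiguousarray(img.pixels).tobytes())
        h.update(np.ascontiguousarray(msk.pixels).tobytes())
    return h.hexdigest()[:16]


def train_segmenter(
    dataset: Sequence[tuple[WellImage, SegMask]],
    *,
    seed: int = 0,
    n_estimators: int = 40,
    max_pixels_per_image: int = 4000,
) -> SegModel:
    """Fit the per-pixel random-forest segmenter on labeled image/mask pairs.

    A class-balanced subsample of ``max_pixels_per_image`` pixels per image
    keeps fitting to seconds on one CPU. Fully deterministic for a fixed
    seed and dataset; the returned manifest records the dataset fingerprint,
    seed, and sampling settings.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    for img, msk in dataset:
        if img.shape != msk.shape:
            raise ValueError("image/mask shape mismatch in dataset")

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for img, msk in dataset:
        feats = _features(img).reshape(-1, 1 + len(_GAUSS_SIGMAS) + 2 + 1 + len(_STD_WINDOWS))
        labels = msk.pixels.ravel()
        pos = np.flatnonzero(labels)
        neg = np.flatnonzero(~labels)
        n_half = max_pixels_per_image // 2
        if pos.size:
            take = rng.choice(pos, size=min(pos.size, n_half), replace=False)
            xs.append(feats[take])
            ys.append(np.ones(take.size, dtype=int))
        if neg.size:
            take = rng.choice(neg, size=min(neg.size, n_half), replace=False)
            xs.append(feats[take])
            ys.append(np.zeros(take.size, dtype=int))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.unique(y).size < 2:
        raise ValueError("dataset labels are single-class; cannot train")

    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=14,
        n_jobs=1,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    clf.fit(X, y)
    manifest = {
        "dataset_fingerprint": _dataset_fingerprint(dataset),
        "n_images": len(dataset),
        "seed": seed,
        "n_estimators": n_estimators,
        "max_pixels_per_image": max_pixels_per_image,
    }
    return SegModel(backend="trained_cnn", parameters=clf, training_manifest=manifest)


def predict(model: SegModel, image: WellImage, roi: CircleROI) -> SegMask:
    """Produce a binary mask from a model; zero outside the ROI.

    Trained models score each pixel and binarize at 0.5; the baseline
    backend delegates to :func:`segment_baseline`.
    """
    if model.backend == "classical_baseline":
        return segment_baseline(image, roi)
    if model.parameters is None:
        raise ValueError("model has no trained parameters")
    clf: RandomForestClassifier = model.parameters  # type: ignore[assignment]
    feats = _features(image)
    h, w, f = feats.shape
    inside = roi.contains((h, w))
    scores = np.zeros((h, w), dtype=float)
    if inside.any():
        proba = clf.predict_proba(feats[inside])
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores[inside] = proba[:, pos_col]
    return SegMask((scores > 0.5) & inside)


# ---------------------------------------------------------------------------
# evaluation

def iou(pred: SegMask, truth: SegMask) -> float:
    """Jaccard index |pred AND truth| / |pred OR truth|; empty/empty := 1."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    union = np.logical_or(pred.pixels, truth.pixels).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(pred.pixels, truth.pixels).sum()
    return float(inter) / float(union)


def coverage_fraction(mask: SegMask, roi: CircleROI) -> float:
    """Percent of ROI-interior pixels that are cell-positive."""
    inside = roi.contains(mask.shape)
    denom = int(inside.sum())
    if denom == 0:
        raise ValueError("ROI has no interior pixels")
    return 100.0 * float((mask.pixels & inside).sum()) / denom


def compare_models(
    masks_a: Sequence[SegMask],
    masks_b: Sequence[SegMask],
    roi: CircleROI,
) -> ModelComparison:
    """Per-image |coverage_a - coverage_b| in percentage points, mean and SD.

    SD uses the sample (n-1) denominator and is 0 for a single image.
    """
    if len(masks_a) != len(masks_b):
        raise ValueError("mask lists must have equal length")
    if len(masks_a) == 0:
        raise ValueError("need at least one image")
    diffs = np.array(
        [
            abs(coverage_fraction(a, roi) - coverage_fraction(b, roi))
            for a, b in zip(masks_a, masks_b)
        ]
    )
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return ModelComparison(
        mean_coverage_diff_pct=float(diffs.mean()),
        sd_coverage_diff_pct=sd,
        n_images=int(diffs.size),
    )
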