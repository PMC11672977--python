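"""Sliding-window inference, case prediction and TTA uncertainty scoring.

Whole volumes are predicted in overlapping windows whose probabilities are
blended with Gaussian importance weights and renormalized.  The end-to-end
path preprocesses a CT, infers, takes the voxel-wise argmax (ties break
toward background) and reverts the label map to the native grid.

Uncertainty is quantified by test-time augmentation: the volume is predicted
once unaugmented (segmented volume ``V0`` per lesion class) and ``n`` more
times under mild invertible spatial transforms (volumes ``Vi``).  The
uncertainty score per class is

    score = (1/n) * sum_i |Vi - V0| / (Vi + V0),

the mean normalized absolute volume divergence, which lies in [0, 1]; when
``Vi + V0 = 0`` both runs agree the class is absent and the term counts as
zero.  The ICH and PHE scores are averaged into a subject-level score, and a
subject whose score exceeds a configurable threshold is flagged for review.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import (CTVolume, NormalizedVolume, preprocess_case,
                         revert_to_original)

__all__ = [
    "SlidingWindowPlan",
    "PredictConfig",
    "TTAConfig",
    "UncertaintyResult",
    "plan_sliding_windows",
    "sliding_window_infer",
    "predict_case",
    "volume_of",
    "uncertainty_score",
    "tta_predict",
    "calibrate_threshold",
    "SpatialTransform",
]


@dataclass
class SlidingWindowPlan:
    window_size: tuple[int, int, int]
    origins: list[tuple[int, int, int]]
    overlap: float
    blend: str                                  # "uniform" | "gaussian"
    pad: tuple[tuple[int, int], ...]            # symmetric zero padding
    image_shape: tuple[int, int, int]

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(s + lo + hi for s, (lo, hi) in zip(self.image_shape, self.pad))


def _axis_origins(size: int, window: int, overlap: float) -> list[int]:
    if size <= window:
        return [0]
    stride = max(int(np.ceil(window * (1.0 - overlap))), 1)
    origins = list(range(0, size - window, stride))
    origins.append(size - window)               # clamp last window to the edge
    return sorted(set(origins))


def plan_sliding_windows(image_shape, window, overlap: float = 0.5,
                         blend: str = "gaussian") -> SlidingWindowPlan:
    """Plan overlapping windows covering the (possibly padded) image.

    Origins advance at stride ``ceil(window * (1 - overlap))``; the final
    origin is clamped so the last window ends at the image edge.  Axes
    shorter than the window are symmetrically zero-padded.
    """
    window = tuple(int(w) for w in window)
    if any(w <= 0 for w in window):
        raise ValueError(f"window must be positive, got {window}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if blend not in ("uniform", "gaussian"):
        raise ValueError(f"unknown blend mode {blend!r}")
    image_shape = tuple(int(s) for s in image_shape)
    pad = []
    padded = []
    for s, w in zip(image_shape, window):
        extra = max(w - s, 0)
        pad.append((extra // 2, extra - extra // 2))
        padded.append(max(s, w))
    axes = [_axis_origins(p, w, overlap) for p, w in zip(padded, window)]
    origins = [tuple(o) for o in itertools.product(*axes)]
    return SlidingWindowPlan(window_size=window, origins=origins,
                             overlap=overlap, blend=blend, pad=tuple(pad),
                             image_shape=image_shape)


def _importance_map(window: tuple[int, int, int], blend: str) -> np.ndarray:
    if blend == "uniform":
        return np.ones(window, dtype=np.float32)
    # Gaussian centered in the window, sigma = window / 8 (importance
    # weighting that trusts window centers more than edges)
    grids = np.meshgrid(*[np.arange(w) - (w - 1) / 2.0 for w in window],
                        indexing="ij")
    q = sum((g / (w / 8.0)) ** 2 for g, w in zip(grids, window))
    m = np.exp(-0.5 * q).astype(np.float32)
    return np.maximum(m, 1e-4 * m.max())


def sliding_window_infer(model, vol, plan: SlidingWindowPlan) -> np.ndarray:
    """Blend per-window fused predictions into a class-probability volume.

    ``model`` needs a ``predict_probs(patch) -> (C, D, H, W)`` method (the
    dual model fuses its two branches there).  Output is simplex-normalized
    per voxel and cropped back to the unpadded shape, ``(C, *image_shape)``.
    """
    voxels = vol.voxels if isinstance(vol, NormalizedVolume) else np.asarray(vol)
    if voxels.shape != plan.image_shape:
        raise ValueError(f"volume shape {voxels.shape} does not match plan "
                         f"{plan.image_shape}")
    padded = np.pad(voxels, plan.pad)
    w = plan.window_size
    imp = _importance_map(w, plan.blend)
    accum = None
    weight = np.zeros(padded.shape, dtype=np.float32)
    for origin in plan.origins:
        sl = tuple(slice(o, o + ww) for o, ww in zip(origin, w))
        probs = np.asarray(model.predict_probs(padded[sl]), dtype=np.float32)
        if probs.ndim != 4 or probs.shape[1:] != w:
            raise ValueError(f"model returned shape {probs.shape} for window {w}")
        if accum is None:
            accum = np.zeros((probs.shape[0], *padded.shape), dtype=np.float32)
        accum[(slice(None),) + sl] += probs * imp
        weight[sl] += imp
    accum /= weight[None]
    accum /= accum.sum(axis=0, keepdims=True)
    crop = tuple(slice(lo, lo + s) for (lo, _), s in zip(plan.pad, plan.image_shape))
    return accum[(slice(None),) + crop]


@dataclass
class PredictConfig:
    target_spacing: tuple[float, float, float] = (5.0, 2.75, 2.75)
    overlap: float = 0.5
    blend: str = "gaussian"
    window_level: float = 40.0
    window_width: float = 80.0


def predict_case(model, ct: CTVolume, cfg: PredictConfig | None = None) -> np.ndarray:
    """End-to-end prediction: preprocess, infer, argmax, revert to CT grid.

    Argmax ties break toward the lower label index, i.e. background wins.
    """
    cfg = cfg or PredictConfig()
    pre, record = preprocess_case(ct, cfg.target_spacing,
                                  level=cfg.window_level, width=cfg.window_width)
    plan = plan_sliding_windows(pre.voxels.shape, model.cfg.patch_size,
                                cfg.overlap, cfg.blend)
    probs = sliding_window_infer(model, pre, plan)
    labels = probs.argmax(axis=0).astype(np.uint8)   # first max = lowest label
    return revert_to_original(labels, record)


def volume_of(mask: np.ndarray, label: int, spacing) -> float:
    """Volume in mL of one label: voxel count x voxel volume (mm^3) / 1000."""
    count = int((np.asarray(mask) == label).sum())
    return count * float(np.prod(spacing)) / 1000.0


def uncertainty_score(v0: float, vi: list[float]) -> float:
    """Mean normalized absolute volume divergence (range [0, 1]).

    A term with ``Vi + V0 = 0`` means both segmentations agree the class is
    absent and contributes 0.
    """
    vi = list(vi)
    if len(vi) == 0:
        raise ValueError("need at least one augmented volume")
    if v0 < 0 or any(v < 0 for v in vi):
        raise ValueError("volumes must be non-negative")
    terms = []
    for v in vi:
        denom = v + v0
        terms.append(abs(v - v0) / denom if denom > 0 else 0.0)
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

@dataclass
class SpatialTransform:
    """An invertible flip / in-plane rotation / isotropic zoom combination.

    Forward order: zoom, rotate about the slice axis, left-right flip.  The
    inverse (applied to label grids with nearest-neighbor interpolation)
    reverses the order and signs and restores the original grid shape
    exactly.
    """

    flip_lr: bool = False
    angle_deg: float = 0.0
    zoom: float = 1.0

    def is_identity(self) -> bool:
        return not self.flip_lr and self.angle_deg == 0.0 and self.zoom == 1.0

    def apply(self, vol: np.ndarray, order: int = 1) -> np.ndarray:
        out = np.asarray(vol)
        if self.zoom != 1.0:
            out = ndimage.zoom(out, self.zoom, order=order, mode="nearest",
                               grid_mode=True, prefilter=False)
        if self.angle_deg != 0.0:
            out = ndimage.rotate(out, self.angle_deg, axes=(1, 2),
                                 reshape=False, order=order, mode="constant",
                                 cval=0.0, prefilter=False)
        if self.flip_lr:
            out = out[:, :, ::-1]
        return np.ascontiguousarray(out)

    def invert_labels(self, labels: np.ndarray,
                      original_shape: tuple[int, int, int]) -> np.ndarray:
        out = np.asarray(labels)
        if self.flip_lr:
            out = out[:, :, ::-1]
        if self.angle_deg != 0.0:
            out = ndimage.rotate(out, -self.angle_deg, axes=(1, 2),
                                 reshape=False, order=0, mode="constant",
                                 cval=0, prefilter=False)
        if out.shape != tuple(original_shape):
            factors = [o / c for o, c in zip(original_shape, out.shape)]
            out = ndimage.zoom(out, factors, order=0, mode="nearest",
                               grid_mode=True, prefilter=False)
            if out.shape != tuple(original_shape):
                raise ValueError("transform could not be inverted to the "
                                 f"original shape {original_shape}")
        return np.ascontiguousarray(out).astype(labels.dtype)


@dataclass
class TTAConfig:
    n: int = 8
    flip: bool = True
    rotate_deg: float = 10.0          # rotations uniform in +/- this range
    zoom_range: tuple[float, float] = (0.9, 1.1)
    identity_only: bool = False       # degenerate family for calibration tests
    seed: int = 0
    threshold: float = 0.2            # subject-score cutoff for flagging

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("TTA count must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

    def sample_transform(self, rng: np.random.Generator) -> SpatialTransform:
        if self.identity_only:
            return SpatialTransform()
        return SpatialTransform(
            flip_lr=bool(self.flip and rng.random() < 0.5),
            angle_deg=float(rng.uniform(-self.rotate_deg, self.rotate_deg)),
            zoom=float(rng.uniform(*self.zoom_range)),
        )


@dataclass
class UncertaintyResult:
    per_class: dict                 # label -> {"v0", "vi", "score"}
    subject_score: float
    flagged: bool
    threshold: float


def tta_predict(model, ct: CTVolume, tta: TTAConfig,
                cfg: PredictConfig | None = None
                ) -> tuple[np.ndarray, UncertaintyResult]:
    """Predict a case and score its uncertainty by test-time augmentation.

    The returned segmentation is the unaugmented prediction on the original
    grid.  Each augmented pass transforms the preprocessed volume, predicts,
    inverts the transform on the label grid, reverts to the original grid
    and measures per-class volumes there.
    """
    cfg = cfg or PredictConfig()
    rng = np.random.default_rng(tta.seed)
    pre, record = preprocess_case(ct, cfg.target_spacing,
                                  level=cfg.window_level, width=cfg.window_width)

    def infer(voxels: np.ndarray) -> np.ndarray:
        plan = plan_sliding_windows(voxels.shape, model.cfg.patch_size,
                                    cfg.overlap, cfg.blend)
        probs = sliding_window_infer(model, voxels, plan)
        return probs.argmax(axis=0).astype(np.uint8)

    labels0 = revert_to_original(infer(pre.voxels), record)
    v0 = {c: volume_of(labels0, c, ct.spacing) for c in (1, 2)}

    vi: dict[int, list[float]] = {1: [], 2: []}
    for _ in range(tta.n):
        tf = tta.sample_transform(rng)
        aug = tf.apply(pre.voxels, order=1)
        pred = infer(np.clip(aug, 0.0, 1.0))
        back = tf.invert_labels(pred, pre.voxels.shape)
        full = revert_to_original(back, record)
        for c in (1, 2):
            vi[c].append(volume_of(full, c, ct.spacing))

    per_class = {}
    scores = []
    for c, name in ((1, "ich"), (2, "phe")):
        s = uncertainty_score(v0[c], vi[c])
        per_class[name] = {"v0": v0[c], "vi": vi[c], "score": s}
        scores.append(s)
    subject = float(np.mean(scores))
    return labels0, UncertaintyResult(per_class=per_class,
                                      subject_score=subject,
                                      flagged=subject > tta.threshold,
                                      threshold=tta.threshold)


def calibrate_threshold(subject_scores, target_flag_rate: float) -> float:
    """Threshold whose flag rate on a reference cohort matches the target."""
    if not 0.0 <= target_flag_rate <= 1.0:
        raise ValueError("target flag rate must be in [0, 1]")
    scores = np.sort(np.asarray(list(subject_scores), dtype=float))
    if scores.size == 0:
        raise ValueError("need at least one reference score")
    return float(np.quantile(scores, 1.0 - target_flag_rate))
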