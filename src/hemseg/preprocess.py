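"""Head-CT preprocessing for hemorrhage/edema segmentation.

The pipeline mirrors standard non-contrast CT preparation for lesion
segmentation networks:

1. **Skull stripping** — keep voxels in the soft-tissue Hounsfield range
   [0, 200] HU (air, fat and bone fall outside it), clean the mask with
   morphological opening/closing, and keep the largest connected component.
2. **Brain windowing** — linear window level 40 / width 80 HU mapped to
   [0, 1], the standard radiology brain window.
3. **Foreground cropping** — tight bounding box around the brain mask.
4. **Resampling** — to a common voxel spacing (in clinical use, the mean
   spacing of the training cohort; e.g. 3.75 x 0.46 x 0.46 mm).

Every geometric step is recorded in a :class:`PreprocessRecord` so that a
predicted label map can be reverted voxel-for-voxel to the original CT grid.

Arrays follow the ``(slice, row, column)`` axis convention with 0-based,
half-open voxel extents; spacing triples are mm per voxel along those axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "BrainMask",
    "NormalizedVolume",
    "PreprocessRecord",
    "strip_skull",
    "apply_brain_window",
    "crop_to_foreground",
    "resample_volume",
    "preprocess_case",
    "revert_to_original",
    "mean_spacing",
]

# Soft-tissue HU range retained during skull stripping: below 0 HU lie air
# and fat, above 200 HU lies bone.
HU_BRAIN_RANGE = (0.0, 200.0)
DEFAULT_WINDOW_LEVEL = 40.0
DEFAULT_WINDOW_WIDTH = 80.0


@dataclass
class CTVolume:
    """A 3D scalar CT grid in Hounsfield units with geometric metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.ndim != 3:
            raise ValueError(f"CT grid must be rank 3, got rank {self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BrainMask:
    """Binary mask aligned voxel-for-voxel with its CTVolume."""

    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(np.uint8)
        if not np.isin(self.voxels, (0, 1)).all():
            raise ValueError("brain mask must be binary")


@dataclass
class NormalizedVolume:
    """Windowed volume with values in [0, 1] plus the window used."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    level: float = DEFAULT_WINDOW_LEVEL
    width: float = DEFAULT_WINDOW_WIDTH

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("normalized volume must lie in [0, 1]")


@dataclass
class PreprocessRecord:
    """Invertible record of the crop/resample applied to one case."""

    original_shape: tuple[int, int, int]
    original_spacing: tuple[float, float, float]
    crop_offset: tuple[int, int, int]
    cropped_shape: tuple[int, int, int]
    target_spacing: tuple[float, float, float]

    def __post_init__(self):
        self.original_shape = tuple(int(v) for v in self.original_shape)
        self.original_spacing = tuple(float(v) for v in self.original_spacing)
        self.crop_offset = tuple(int(v) for v in self.crop_offset)
        self.cropped_shape = tuple(int(v) for v in self.cropped_shape)
        self.target_spacing = tuple(float(v) for v in self.target_spacing)
        for o, c, s in zip(self.crop_offset, self.cropped_shape, self.original_shape):
            if o < 0 or o + c > s:
                raise ValueError("crop box exceeds original grid")
        if any(t <= 0 for t in self.target_spacing):
            raise ValueError("target spacing must be positive")

    @property
    def preprocessed_shape(self) -> tuple[int, int, int]:
        """Shape after resampling the cropped box to the target spacing."""
        return _resampled_shape(self.cropped_shape, self.original_spacing,
                                self.target_spacing)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessRecord":
        return cls(**json.loads(Path(path).read_text()))


def _ellipsoid_structure(radius: tuple[int, int, int]) -> np.ndarray:
    """Anisotropic ball structuring element with per-axis voxel radii."""
    rz, ry, rx = (max(int(r), 0) for r in radius)
    z, y, x = np.ogrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = ((z / max(rz, 1)) ** 2 + (y / max(ry, 1)) ** 2 + (x / max(rx, 1)) ** 2)
    return d <= 1.0


def strip_skull(ct: CTVolume,
                morph_radius: int | tuple[int, int, int] = (1, 2, 2),
                keep_largest: bool = True) -> BrainMask:
    """Isolate brain tissue by HU thresholding plus morphological cleanup.

    Voxels outside [0, 200] HU (air/fat below, bone above) are discarded;
    binary opening then closing removes scalp and soft-tissue fragments, and
    optionally only the largest connected component is retained.

    The radius is anisotropy-aware: by default 2 voxels in-plane and 1
    across slices, since clinical CT slices are far thicker than pixels.
    """
    if isinstance(morph_radius, (int, np.integer)):
        morph_radius = (morph_radius, morph_radius, morph_radius)
    lo, hi = HU_BRAIN_RANGE
    raw = (ct.voxels >= lo) & (ct.voxels <= hi)
    if not raw.any():
        raise ValueError("no brain tissue in HU range")
    if any(r > 0 for r in morph_radius):
        struct = _ellipsoid_structure(tuple(morph_radius))
        mask = ndimage.binary_opening(raw, structure=struct)
        mask = ndimage.binary_closing(mask, structure=struct)
        # closing may re-annex out-of-range voxels at the boundary; the HU
        # contract (mask only inside [0, 200]) takes precedence
        mask &= raw
    else:
        mask = raw
    if keep_largest and mask.any():
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise ValueError("no brain tissue in HU range")
    return BrainMask(mask.astype(np.uint8))


def apply_brain_window(ct: CTVolume,
                       level: float = DEFAULT_WINDOW_LEVEL,
                       width: float = DEFAULT_WINDOW_WIDTH) -> NormalizedVolume:
    """Linear radiology window: [level - width/2, level + width/2] -> [0, 1].

    With the default brain window (level 40, width 80) the floor is 0 HU and
    the ceiling 80 HU, so HU 40 maps to 0.5.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    floor = level - width / 2.0
    out = np.clip((ct.voxels - floor) / width, 0.0, 1.0).astype(np.float32)
    return NormalizedVolume(out, ct.spacing, level=level, width=width)


def crop_to_foreground(vol: NormalizedVolume, brain: BrainMask,
                       margin: int = 0) -> tuple[NormalizedVolume, PreprocessRecord]:
    """Crop to the tight bounding box of the brain mask (plus margin)."""
    mask = brain.voxels.astype(bool)
    if mask.shape != vol.voxels.shape:
        raise ValueError("brain mask shape differs from volume shape")
    if not mask.any():
        raise ValueError("empty foreground")
    lo, hi = [], []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        lo.append(max(int(idx[0]) - margin, 0))
        hi.append(min(int(idx[-1]) + 1 + margin, mask.shape[ax]))
    cropped = vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    record = PreprocessRecord(
        original_shape=vol.voxels.shape,
        original_spacing=vol.spacing,
        crop_offset=tuple(lo),
        cropped_shape=cropped.shape,
        target_spacing=vol.spacing,   # updated if a resample follows
    )
    return NormalizedVolume(cropped, vol.spacing, vol.level, vol.width), record


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (platform-stable, unlike banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _resampled_shape(shape, spacing, target) -> tuple[int, int, int]:
    new = _round_half_away(np.asarray(shape) * np.asarray(spacing)
                           / np.asarray(target, dtype=float))
    return tuple(int(max(n, 1)) for n in new)


def resample_volume(voxels: np.ndarray,
                    spacing: tuple[float, float, float],
                    target_spacing: tuple[float, float, float],
                    mode: str = "continuous") -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample a grid to a new voxel spacing.

    Output shape along each axis is ``round(shape * spacing / target)`` with
    a minimum of 1.  ``continuous`` interpolates linearly; ``label`` uses
    nearest-neighbor and therefore introduces no new label values.
    """
    if mode not in ("continuous", "label"):
        raise ValueError(f"unknown resample mode {mode!r}")
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"source spacing must be positive, got {spacing}")
    voxels = np.asarray(voxels)
    new_shape = _resampled_shape(voxels.shape, spacing, target_spacing)
    if new_shape == voxels.shape and tuple(spacing) == tuple(target_spacing):
        return voxels.copy(), tuple(float(t) for t in target_spacing)
    order = 1 if mode == "continuous" else 0
    zoom = [n / o for n, o in zip(new_shape, voxels.shape)]
    out = ndimage.zoom(voxels, zoom, order=order, mode="nearest",
                       grid_mode=True, prefilter=False)
    assert out.shape == new_shape, (out.shape, new_shape)
    if mode == "label":
        out = out.astype(voxels.dtype)
    return out, tuple(float(t) for t in target_spacing)


def preprocess_case(ct: CTVolume,
                    target_spacing: tuple[float, float, float],
                    level: float = DEFAULT_WINDOW_LEVEL,
                    width: float = DEFAULT_WINDOW_WIDTH,
                    margin: int = 0,
                    morph_radius: int | tuple[int, int, int] = (1, 2, 2),
                    ) -> tuple[NormalizedVolume, PreprocessRecord]:
    """Full preprocessing: strip -> window -> crop -> resample.

    Non-brain voxels are set to the window floor (0) before cropping so air
    and bone never leak into the network input.  The returned record is
    sufficient to revert a predicted mask to the original grid.
    """
    brain = strip_skull(ct, morph_radius=morph_radius)
    windowed = apply_brain_window(ct, level=level, width=width)
    windowed.voxels[brain.voxels == 0] = 0.0
    cropped, record = crop_to_foreground(windowed, brain, margin=margin)
    resampled, _ = resample_volume(cropped.voxels, cropped.spacing,
                                   target_spacing, mode="continuous")
    record.target_spacing = tuple(float(t) for t in target_spacing)
    out = NormalizedVolume(np.clip(resampled, 0.0, 1.0), record.target_spacing,
                           level, width)
    return out, record


def revert_to_original(mask: np.ndarray, record: PreprocessRecord) -> np.ndarray:
    """Map a label grid from the preprocessed grid back to the original CT grid.

    Nearest-neighbor resample back to the cropped box at the original
    spacing, then paste into a zero-filled grid of the original shape at the
    recorded crop offset.  The label set is preserved.
    """
    mask = np.asarray(mask)
    expected = record.preprocessed_shape
    if mask.shape != expected:
        raise ValueError(
            f"mask shape {mask.shape} does not match preprocessed shape {expected}")
    if mask.shape == record.cropped_shape and \
            record.target_spacing == record.original_spacing:
        back = mask.copy()
    else:
        zoom = [c / m for c, m in zip(record.cropped_shape, mask.shape)]
        back = ndimage.zoom(mask, zoom, order=0, mode="nearest",
                            grid_mode=True, prefilter=False).astype(mask.dtype)
        assert back.shape == tuple(record.cropped_shape)
    out = np.zeros(record.original_shape, dtype=mask.dtype)
    o, c = record.crop_offset, record.cropped_shape
    out[o[0]:o[0] + c[0], o[1]:o[1] + c[1], o[2]:o[2] + c[2]] = back
    return out


def mean_spacing(spacings) -> tuple[float, float, float]:
    """Component-wise mean spacing of a cohort (the resampling target)."""
    arr = np.asarray(list(spacings), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected a sequence of spacing triples")
    return tuple(arr.mean(axis=0))
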