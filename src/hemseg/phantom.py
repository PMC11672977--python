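"""Synthetic head-CT phantoms with hematoma and edema ground truth.

Each phantom emulates the Hounsfield-unit structure the segmentation method
relies on: an ellipsoidal high-HU skull shell with a thin scalp layer
outside it, brain parenchyma around 35 HU, CSF-filled ventricles around
8 HU, a hyperdense intracerebral hematoma (ICH, ~65 HU) built as a smooth
random blob of a requested volume, and a contiguous hypodense perihematomal
edema (PHE) rim around it (~18 HU — below brain, above CSF).  Optional
intraventricular blood (IVH) is hyperdense but labeled background, matching
the clinical convention that IVH is excluded from the ICH label.  Additive
Gaussian HU noise and anisotropic voxel spacing (thick slices, finer
in-plane) complete the picture.

The phantoms are geometric, not anatomic: they exercise every stage of the
pipeline (HU thresholds, windowing, cropping, learning, uncertainty) without
claiming neuroanatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "CohortRanges",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_HU",
]

# Tissue HU means; ordering ICH > brain > PHE > CSF > air, skull > 200.
DEFAULT_HU = {
    "air": -1000.0,
    "skull": 1200.0,
    "scalp": 30.0,
    "brain": 35.0,
    "csf": 8.0,
    "ich": 65.0,
    "phe": 18.0,
}

LABEL_BACKGROUND, LABEL_ICH, LABEL_PHE = 0, 1, 2


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head CT.

    Defaults describe a desk-scale head: a 32 x 96 x 96 grid at
    5.0 x 2.75 x 2.75 mm spacing (160 mm axially, ~264 mm field of view
    in-plane), a 15 mL hematoma with a 6 mm edema rim, and 4 HU noise.
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 2.75, 2.75)
    ich_volume_ml: float = 15.0
    phe_rim_mm: float = 6.0
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd: float = 4.0
    ivh_fraction: float = 0.0
    location: str = "supratentorial"
    seed: int = 0

    def __post_init__(self):
        if self.ich_volume_ml < 0 or self.phe_rim_mm < 0:
            raise ValueError("lesion sizes must be non-negative")
        if self.location not in ("supratentorial", "infratentorial"):
            raise ValueError(f"unknown location {self.location!r}")
        hu = self.hu_means
        if not (hu["ich"] > hu["brain"] > hu["phe"] > hu["csf"] > hu["air"]):
            raise ValueError("HU ordering must satisfy ICH > brain > PHE > CSF > air")
        if hu["skull"] <= 200:
            raise ValueError("skull HU must exceed 200")


@dataclass
class PhantomCase:
    """A phantom CT with its ground-truth labels and realized geometry."""

    ct: CTVolume
    gt: np.ndarray              # 0 background, 1 ICH, 2 PHE
    meta: dict

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.uint8)
        if not np.isin(self.gt, (0, 1, 2)).all():
            raise ValueError("ground truth labels must be in {0, 1, 2}")


def _mm_grids(shape, spacing):
    """Voxel-center coordinates in mm, origin at the grid center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center_mm, radii_mm) -> np.ndarray:
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one phantom; voxel-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    hu = spec.hu_means
    grids = _mm_grids(shape, spacing)
    extent = [n * s for n, s in zip(shape, spacing)]

    # Head geometry: outer skull ellipsoid, 6 mm bone shell, 3 mm scalp.
    # In-plane radii are smaller than axial (heads are narrower than the
    # scanner field of view).
    skull_r = [0.40 * extent[0], 0.35 * extent[1], 0.35 * extent[2]]
    brain_r = [r - 6.0 for r in skull_r]
    scalp_r = [r + 3.0 for r in skull_r]
    scalp = _ellipsoid(grids, (0, 0, 0), scalp_r)
    skull_outer = _ellipsoid(grids, (0, 0, 0), skull_r)
    brain = _ellipsoid(grids, (0, 0, 0), brain_r)
    skull = skull_outer & ~brain
    scalp_only = scalp & ~skull_outer

    # Ventricles: paired para-median ellipsoids at mid-height.
    vent_r = (10.0, 14.0, 7.0)
    vents = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        vents |= _ellipsoid(grids, (0.0, 0.0, side * 14.0), vent_r)
    vents &= brain

    voxvol_mm3 = float(np.prod(spacing))
    target_vox = spec.ich_volume_ml * 1000.0 / voxvol_mm3

    ich = np.zeros(shape, dtype=bool)
    phe = np.zeros(shape, dtype=bool)
    ivh = False
    if target_vox >= 1:
        # Placement region: the hematoma plus its rim must stay inside the
        # brain and clear of the ventricles.
        margin = spec.phe_rim_mm + 4.0
        interior_dist = ndimage.distance_transform_edt(brain, sampling=spacing)
        allowed = (interior_dist > margin) & ~ndimage.binary_dilation(
            vents, _ball_structure(4.0, spacing))
        # placement cut defined on the reachable region itself, so it scales
        # with any grid/brain geometry (z grows toward the skull base)
        z_mm = grids[0]
        zs = z_mm[allowed]
        if zs.size == 0:
            raise ValueError("requested lesion larger than brain region")
        z_min, z_range = float(zs.min()), float(np.ptp(zs))
        if spec.location == "supratentorial":
            region = allowed & (z_mm <= z_min + 0.60 * z_range)
        else:
            region = allowed & (z_mm >= z_min + 0.70 * z_range)
        if region.sum() < target_vox:
            raise ValueError("requested lesion larger than brain region")

        # Smooth random field localized around a random seed point, then a
        # volume-matching threshold found by bisection on the field value.
        centers = np.argwhere(region)
        cz, cy, cx = centers[rng.integers(len(centers))]
        lesion_radius_mm = (3.0 * spec.ich_volume_ml * 1000.0 / (4 * np.pi)) ** (1 / 3)
        field_sigma_vox = [max(lesion_radius_mm * 0.5 / s, 0.5) for s in spacing]
        noise_field = ndimage.gaussian_filter(
            rng.standard_normal(shape), field_sigma_vox)
        envelope = np.exp(-0.5 * sum(
            ((g - g[cz, cy, cx]) / (1.3 * lesion_radius_mm)) ** 2 for g in grids))
        fld = (noise_field - noise_field.mean()) / (noise_field.std() + 1e-9)
        fld = (fld + 2.5) * envelope
        fld[~region] = -np.inf

        def blob_at(thr: float) -> np.ndarray:
            """Largest connected component above the threshold."""
            cand = fld >= thr
            labels, ncomp = ndimage.label(cand)
            if ncomp > 1:
                sizes = ndimage.sum_labels(cand, labels, np.arange(1, ncomp + 1))
                cand = labels == (1 + int(np.argmax(sizes)))
            return cand

        # bisection on the threshold, matching the *component* volume so
        # that trimming satellites cannot bias the realized volume
        lo, hi = 0.0, float(fld.max())
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if int(blob_at(mid).sum()) > target_vox:
                lo = mid
            else:
                hi = mid
        best = None
        for thr in (lo, hi):
            cand = blob_at(thr)
            err = abs(int(cand.sum()) - target_vox)
            if best is None or err < best[0]:
                best = (err, cand)
        ich = best[1]

        if spec.phe_rim_mm > 0 and ich.any():
            dist = ndimage.distance_transform_edt(~ich, sampling=spacing)
            phe = (dist <= spec.phe_rim_mm) & brain & ~ich & ~vents

        ivh = bool(rng.random() < spec.ivh_fraction)

    # Assemble HU volume.
    vol = np.full(shape, hu["air"], dtype=np.float32)
    vol[scalp_only] = hu["scalp"]
    vol[skull] = hu["skull"]
    vol[brain] = hu["brain"]
    vol[vents] = hu["csf"]
    vol[phe] = hu["phe"]
    vol[ich] = hu["ich"]
    if ivh:
        # blood layering in the dependent part of one ventricle; background label
        ivh_mask = vents & (grids[2] > 10.0) & (grids[1] > 0.0)
        vol[ivh_mask] = hu["ich"]
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)

    gt = np.zeros(shape, dtype=np.uint8)
    gt[phe] = LABEL_PHE
    gt[ich] = LABEL_ICH

    meta = {
        "ich_ml": float(ich.sum()) * voxvol_mm3 / 1000.0,
        "phe_ml": float(phe.sum()) * voxvol_mm3 / 1000.0,
        "location": spec.location,
        "ivh": ivh,
        "seed": spec.seed,
    }
    return PhantomCase(CTVolume(vol, spacing), gt, meta)


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    r = [max(int(np.ceil(radius_mm / s)), 1) for s in spacing]
    z, y, x = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
    return ((z * spacing[0]) ** 2 + (y * spacing[1]) ** 2
            + (x * spacing[2]) ** 2) <= radius_mm ** 2


@dataclass
class CohortRanges:
    """Sampling ranges for per-case phantom specs in a synthetic cohort."""

    ich_volume_ml: tuple[float, float] = (8.0, 25.0)
    phe_rim_mm: tuple[float, float] = (4.0, 8.0)
    infratentorial_fraction: float = 0.15
    ivh_fraction: float = 0.15
    follow_up_fraction: float = 0.5   # patients carrying a second scan
    noise_sd: float = 4.0
    shape: tuple[int, int, int] = (32, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 2.75, 2.75)

    def __post_init__(self):
        for name in ("ich_volume_ml", "phe_rim_mm"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: {(lo, hi)}")
        for name in ("infratentorial_fraction", "ivh_fraction", "follow_up_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_cohort(n: int, ranges: CohortRanges | None = None,
                    seed: int = 0) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Sample ``n`` phantom cases plus a manifest table.

    Synthetic patient IDs are assigned; a fraction of patients contribute a
    baseline and a follow-up scan (two cases), which is what patient-grouped
    cross-validation must respect.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)

    cases: list[PhantomCase] = []
    rows: list[dict] = []
    patient = 0
    while len(cases) < n:
        patient += 1
        scans = 2 if (rng.random() < ranges.follow_up_fraction
                      and len(cases) + 2 <= n) else 1
        location = ("infratentorial"
                    if rng.random() < ranges.infratentorial_fraction
                    else "supratentorial")
        base_ich = rng.uniform(*ranges.ich_volume_ml)
        base_rim = rng.uniform(*ranges.phe_rim_mm)
        for t in range(scans):
            # follow-up scans show mild hematoma/edema evolution
            growth = 1.0 if t == 0 else float(rng.uniform(0.9, 1.3))
            spec = PhantomSpec(
                shape=ranges.shape,
                spacing=ranges.spacing,
                ich_volume_ml=base_ich * growth,
                phe_rim_mm=base_rim * (1.0 if t == 0 else float(rng.uniform(1.0, 1.3))),
                noise_sd=ranges.noise_sd,
                ivh_fraction=ranges.ivh_fraction,
                location=location,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            case = generate_phantom(spec)
            case_id = f"case{len(cases):04d}"
            cases.append(case)
            rows.append({
                "case_id": case_id,
                "patient_id": f"pat{patient:04d}",
                "timepoint": "baseline" if t == 0 else "followup",
                "location": location,
                "ich_ml": case.meta["ich_ml"],
                "phe_ml": case.meta["phe_ml"],
                "ivh": case.meta["ivh"],
                "seed": spec.seed,
            })
    manifest = pd.DataFrame(rows)
    return cases, manifest
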