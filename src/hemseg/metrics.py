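"""Segmentation evaluation: Dice, Hausdorff distance, Volume Similarity.

Definitions (A = prediction voxel set, B = ground truth voxel set):

* Dice = 2|A intersect B| / (|A| + |B|); 1 when both sets are empty.
* Hausdorff distance (HD) = the maximum, over both directions, of the
  largest surface-to-nearest-surface distance in mm.  The surface of a mask
  is the set of its voxels with at least one face-neighbor outside the
  mask.  The true maximum is reported by default; a robust percentile
  (e.g. 95) is available via ``percentile``.  HD is undefined (NaN, with a
  warning) when either mask is empty.
* Volume Similarity (VS) = 1 - |V_A - V_B| / (V_A + V_B); 1 when both are
  empty, 0 when exactly one is empty.

Cohort summaries report mean +/- sd, median and interquartile bounds per
class and metric, optionally excluding uncertainty-flagged cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MetricsReport",
    "dice_coefficient",
    "hausdorff_distance",
    "volume_similarity",
    "evaluate_case",
    "summarize_cohort",
    "CLASS_NAMES",
]

CLASS_NAMES = {1: "ich", 2: "phe"}
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _as_bool(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a).astype(bool), np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _as_bool(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / (sa + sb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask voxels with >= 1 face-neighbor outside the mask."""
    mask = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT,
                                      border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff_distance(a: np.ndarray, b: np.ndarray, spacing,
                       percentile: float | None = None) -> float:
    """Spacing-aware bidirectional maximum surface distance in mm."""
    a, b = _as_bool(a, b)
    if not a.any() or not b.any():
        warnings.warn("Hausdorff distance undefined for an empty mask",
                      stacklevel=2)
        return float("nan")
    sp = np.asarray(spacing, dtype=float)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def volume_similarity(a: np.ndarray, b: np.ndarray, spacing=None) -> float:
    """1 - |V_a - V_b| / (V_a + V_b); spacing cancels, counts suffice."""
    a, b = _as_bool(a, b)
    va, vb = int(a.sum()), int(b.sum())
    if va + vb == 0:
        return 1.0
    return 1.0 - abs(va - vb) / (va + vb)


def evaluate_case(pred: np.ndarray, gt: np.ndarray, spacing,
                  percentile: float | None = None) -> dict:
    """Per-class (ICH, PHE) Dice / HD / VS for one case."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shapes differ: {pred.shape} vs {gt.shape}")
    for arr, name in ((pred, "prediction"), (gt, "ground truth")):
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1, 2}}")
    out = {}
    for label, name in CLASS_NAMES.items():
        p, g = pred == label, gt == label
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hd = hausdorff_distance(p, g, spacing, percentile)
        out[name] = {
            "dice": dice_coefficient(p, g),
            "hd": hd,
            "vs": volume_similarity(p, g),
        }
    return out


@dataclass
class MetricsReport:
    per_case: pd.DataFrame       # case_id, class, dice, hd, vs, flagged
    cohort: pd.DataFrame         # per class & metric: mean, sd, median, q25, q75


def per_case_table(results: dict[str, dict], flags: dict[str, bool] | None = None
                   ) -> pd.DataFrame:
    """Flatten ``{case_id: evaluate_case(...)}`` into a long table."""
    rows = []
    for case_id, classes in results.items():
        for cname, metrics in classes.items():
            rows.append({"case_id": case_id, "class": cname, **metrics,
                         "flagged": bool(flags.get(case_id, False)) if flags else False})
    return pd.DataFrame(rows)


def summarize_cohort(per_case: pd.DataFrame | dict,
                     exclude_flagged: bool = False,
                     flags: dict[str, bool] | None = None) -> MetricsReport:
    """Cohort summary (mean +/- sd, median, IQR) per class and metric."""
    if isinstance(per_case, dict):
        per_case = per_case_table(per_case, flags)
    if len(per_case) == 0:
        raise ValueError("no cases to summarize")
    table = per_case
    if exclude_flagged and "flagged" in table.columns:
        table = table[~table["flagged"].astype(bool)]
        if len(table) == 0:
            raise ValueError("all cases flagged; nothing to summarize")
    rows = []
    for cname, grp in table.groupby("class"):
        for metric in ("dice", "hd", "vs"):
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                rows.append({"class": cname, "metric": metric, "n": 0,
                             "mean": np.nan, "sd": np.nan, "median": np.nan,
                             "q25": np.nan, "q75": np.nan})
                continue
            rows.append({
                "class": cname, "metric": metric, "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            })
    return MetricsReport(per_case=per_case.copy(), cohort=pd.DataFrame(rows))
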