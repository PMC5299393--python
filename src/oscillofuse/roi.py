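"""Spherical ROI summaries and trait correlations.

Around each cluster peak, a 5 mm spherical region of interest is built;
the mean linear-fit (beta) coefficient of all voxels inside the sphere
is the per-subject ROI summary. ROI summaries are correlated with trait
scores (e.g. Barratt Impulsiveness Scale subscales) using Pearson's r;
the family of tests is corrected with the Benjamini–Hochberg FDR
procedure, whose family size m may exceed the number of reported tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import bh_adjust  # re-exported: one step-up implementation

__all__ = [
    "ROISpec",
    "sphere_mask",
    "sphere_roi_mean",
    "pearson_with_pvalue",
    "pvalue_from_r",
    "bh_adjust",
    "correlate_rois_with_traits",
]


@dataclass
class ROISpec:
    """A sphere in millimeter space: center, radius (default 5 mm), label."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


def sphere_mask(shape: tuple[int, int, int], affine: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the ROI sphere.

    Membership is by Euclidean distance of the voxel center (mapped
    through the affine) from the ROI center — no partial-volume
    weighting.
    """
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    mm = (vox @ affine.T)[:, :3]
    d2 = np.sum((mm - np.asarray(roi.center_mm)) ** 2, axis=1)
    return (d2 <= roi.radius_mm**2).reshape(shape)


def sphere_roi_mean(
    subject_maps: dict[int, np.ndarray],
    roi: ROISpec,
    affine: np.ndarray,
) -> pd.Series:
    """Mean map value inside the ROI sphere, per subject."""
    shapes = {m.shape for m in subject_maps.values()}
    if len(shapes) != 1:
        raise ValueError("subject maps must share a grid")
    shape = shapes.pop()
    mask = sphere_mask(shape, affine, roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.label or roi.center_mm} intersects no voxels")
    return pd.Series(
        {s: float(np.asarray(m)[mask].mean()) for s, m in subject_maps.items()},
        name=roi.label or "roi",
    )


def pvalue_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r with n observations (t with n-2 df)."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return float(2 * stats.t.sf(t, n - 2))


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Pearson correlation with the exact two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    return r, pvalue_from_r(r, len(x))


def correlate_rois_with_traits(
    roi_summaries: pd.DataFrame,
    traits: pd.DataFrame,
    family_m: int | None = None,
) -> pd.DataFrame:
    """All (ROI, trait subscale) Pearson correlations with BH correction.

    ``roi_summaries``: subjects x ROI-label columns. ``traits``: subjects
    x subscale columns (aligned on index). ``family_m`` defaults to
    n_rois * n_subscales; it may be set larger to count family members
    that were examined but not entered.
    """
    common = roi_summaries.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common subjects")
    rows = []
    for roi in roi_summaries.columns:
        for sub in traits.columns:
            r, p = pearson_with_pvalue(
                roi_summaries.loc[common, roi], traits.loc[common, sub]
            )
            rows.append({"roi": roi, "trait": sub, "r": r, "n": len(common), "p": p})
    table = pd.DataFrame(rows)
    m = family_m if family_m is not None else len(table)
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy(), m=m)
    table["family_m"] = m
    return table
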