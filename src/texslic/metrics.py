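"""Undersegmentation error and boundary match.

Both metrics score a superpixel segmentation against a ground-truth target
region.

*Undersegmentation error* (UE) measures "overflow": take every superpixel
that intersects the target region ``g``, form their union, and report the
area of that union beyond ``g`` normalized by ``|g|``::

    UE = ( | U { s_i : s_i n g != {} } | - |g| ) / |g|

UE is 0 exactly when every intersecting superpixel lies wholly inside the
target.  The raw ratio can exceed 1 when large superpixels graze the
target; the value is reported unclipped.

*Boundary match* (BM) is the fraction of superpixel-boundary pixels that
lie on (or, with a tolerance, within a Chebyshev distance of) the
ground-truth boundary::

    BM = | SP n dilate(GT, tol) | / |SP|

With ``tol=0`` this is the strict boundary intersection.  Note the
denominator counts *all* superpixel boundary pixels, including internal
boundaries between superpixels inside uniform regions, so BM saturates
well below 1 whenever the segmentation has more regions than the truth.
:func:`boundary_recall` (denominator ``|GT|``) is provided as the
companion measure that asks whether every true boundary was found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .superpixel import boundary_mask

__all__ = [
    "EvalResult",
    "undersegmentation_error",
    "undersegmentation_error_multi",
    "boundary_match",
    "boundary_recall",
    "mask_boundary",
    "evaluate",
]


@dataclass
class EvalResult:
    """UE / BM scores of one segmentation against one ground truth."""

    ue: float
    bm: float
    per_region: dict[int, float] | None = None

    def to_dict(self) -> dict:
        out = {"UE": self.ue, "BM": self.bm}
        if self.per_region is not None:
            out["per_region"] = {str(k): v for k, v in self.per_region.items()}
        return out


def undersegmentation_error(labels: np.ndarray, region: np.ndarray) -> float:
    """UE of a label map against one binary target region.

    ``region`` is a boolean (or 0/1) raster of the same shape; it must be
    non-empty.
    """
    lab = np.asarray(labels)
    g = np.asarray(region).astype(bool)
    if lab.shape != g.shape:
        raise ValueError("labels and region must share a shape")
    area = int(g.sum())
    if area == 0:
        raise ValueError("ground-truth region is empty")
    touching = np.unique(lab[g])
    union = int(np.isin(lab, touching).sum())
    return (union - area) / area


def undersegmentation_error_multi(
    labels: np.ndarray, truth: np.ndarray
) -> tuple[float, dict[int, float]]:
    """Per-region UE for a multi-region truth label raster, plus the
    area-weighted mean across regions."""
    truth = np.asarray(truth)
    per: dict[int, float] = {}
    weights: dict[int, int] = {}
    for r in np.unique(truth):
        mask = truth == r
        per[int(r)] = undersegmentation_error(labels, mask)
        weights[int(r)] = int(mask.sum())
    total = sum(weights.values())
    mean = sum(per[r] * weights[r] for r in per) / total
    return mean, per


def mask_boundary(truth: np.ndarray) -> np.ndarray:
    """Ground-truth boundary raster from a region mask or label image,
    using the same 4-neighbor rule as the superpixel boundary."""
    return boundary_mask(np.asarray(truth).astype(np.int32))


def boundary_match(
    sp_boundary: np.ndarray, gt_boundary: np.ndarray, tol: int = 0
) -> float:
    """Fraction of superpixel-boundary pixels within ``tol`` (Chebyshev)
    of the ground-truth boundary.  ``tol=0`` is the strict intersection."""
    sp = np.asarray(sp_boundary).astype(bool)
    gt = np.asarray(gt_boundary).astype(bool)
    if sp.shape != gt.shape:
        raise ValueError("boundary rasters must share a shape")
    n_sp = int(sp.sum())
    if n_sp == 0:
        raise ValueError("superpixel boundary is empty")
    if tol > 0:
        gt = ndimage.maximum_filter(gt, size=2 * tol + 1)
    return int((sp & gt).sum()) / n_sp


def boundary_recall(
    sp_boundary: np.ndarray, gt_boundary: np.ndarray, tol: int = 0
) -> float:
    """Fraction of ground-truth boundary pixels within ``tol`` (Chebyshev)
    of some superpixel boundary pixel."""
    sp = np.asarray(sp_boundary).astype(bool)
    gt = np.asarray(gt_boundary).astype(bool)
    if sp.shape != gt.shape:
        raise ValueError("boundary rasters must share a shape")
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("ground-truth boundary is empty")
    if tol > 0:
        sp = ndimage.maximum_filter(sp, size=2 * tol + 1)
    return int((gt & sp).sum()) / n_gt


def evaluate(
    labels: np.ndarray,
    truth: np.ndarray,
    target_region: int | None = None,
    bm_tol: int = 0,
) -> EvalResult:
    """Score a label map against a truth raster.

    ``truth`` may be binary (nonzero = target) or a label image; with a
    label image the UE reported is the area-weighted mean over regions
    (per-region values are attached) unless ``target_region`` picks one
    region out.  BM always uses the truth raster's full boundary.
    """
    truth = np.asarray(truth)
    regions = np.unique(truth)
    if target_region is not None:
        ue = undersegmentation_error(labels, truth == target_region)
        per = None
    elif regions.size <= 2:
        target = regions.max()
        ue = undersegmentation_error(labels, truth == target)
        per = None
    else:
        ue, per = undersegmentation_error_multi(labels, truth)
    bm = boundary_match(boundary_mask(labels), mask_boundary(truth), tol=bm_tol)
    return EvalResult(ue=ue, bm=bm, per_region=per)
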