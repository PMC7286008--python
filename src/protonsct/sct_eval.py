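"""Image-domain accuracy of synthetic CTs.

The headline image metric is the mean absolute HU error (MAE) between CT
and sCT over the external body contour, aggregated as mean +/- SD over a
cohort.  The body contour is segmented automatically: threshold, largest
connected component, morphological hole filling (so internal air cavities
count as part of the body, as they do in a clinical external contour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = ["MAEReport", "body_contour", "mae_hu", "aggregate_mae"]


@dataclass
class MAEReport:
    per_subject_mae: list[float]
    cohort_mean: float
    cohort_sd: float
    contour_voxel_counts: list[int] | None = None

    def summary(self) -> str:
        lines = ["MAE report (HU)", "---------------"]
        for i, m in enumerate(self.per_subject_mae):
            lines.append(f"subject {i}: {m:8.2f}")
        lines.append(f"cohort: {self.cohort_mean:.2f} +/- {self.cohort_sd:.2f}")
        return "\n".join(lines)


def body_contour(ct: ImageVolume | np.ndarray, hu_threshold: float = -400.0) -> np.ndarray:
    """External body contour mask of a CT volume.

    Largest connected component of ``HU > hu_threshold``, hole-filled per 2D
    slice and in 3D so that internal air cavities are included.
    """
    data = ct.data if isinstance(ct, ImageVolume) else np.asarray(ct)
    fg = data > hu_threshold
    if not fg.any():
        raise ValueError(f"no voxels above {hu_threshold} HU: threshold too high or image is all air")
    lab, nlab = ndimage.label(fg)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    filled = np.zeros_like(fg)
    for z in range(fg.shape[0]):
        filled[z] = ndimage.binary_fill_holes(fg[z])
    return filled | ndimage.binary_fill_holes(fg)


def mae_hu(ct: ImageVolume | np.ndarray, sct: ImageVolume | np.ndarray,
           mask: np.ndarray | None = None) -> float:
    """Mean absolute HU difference over ``mask`` (whole volume if None)."""
    a = ct.data if isinstance(ct, ImageVolume) else np.asarray(ct)
    b = sct.data if isinstance(sct, ImageVolume) else np.asarray(sct)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: ct {a.shape} vs sct {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {a.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.abs(a[mask].astype(np.float64) - b[mask].astype(np.float64)).mean())


def aggregate_mae(per_subject: list[float], contour_voxel_counts: list[int] | None = None) -> MAEReport:
    """Cohort mean and sample SD of per-subject MAE values."""
    if not len(per_subject):
        raise ValueError("no per-subject MAE values")
    vals = np.asarray(per_subject, dtype=np.float64)
    if len(vals) == 1:
        warnings.warn("single subject: reporting SD as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1))
    return MAEReport(per_subject_mae=[float(v) for v in vals],
                     cohort_mean=float(vals.mean()), cohort_sd=sd,
                     contour_voxel_counts=contour_voxel_counts)


def evaluate_sct(ct: ImageVolume, sct: ImageVolume, hu_threshold: float = -400.0):
    """MAE over the intersection of the CT- and sCT-derived body contours.

    Returns ``(mae, mask)``; using the intersection makes the metric
    symmetric in the two images.
    """
    mask = body_contour(ct, hu_threshold) & body_contour(sct, hu_threshold)
    return mae_hu(ct, sct, mask), mask
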