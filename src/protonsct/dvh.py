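"""Cumulative dose-volume histograms and DVH metrics.

The clinically reported quantities are D_X (the minimum dose received by
the hottest X% of an ROI; D95 measures target coverage, D2 near-maximum
dose) and Dmean, expressed either in Gy or as a percentage of the
prescription dose.  CT-vs-sCT comparisons are absolute metric differences
in % of prescription, tabulated per (organ, metric) with cohort mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DoseGrid

__all__ = [
    "DVHCurve", "MetricTable", "compute_dvh", "metric_dx", "metric_dmean",
    "metric_table", "diff_table", "cohort_table", "DVH_METRICS",
]

DVH_METRICS = ("D95", "D5", "D2", "Dmean")


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the ROI receiving at least each dose."""

    dose_axis: np.ndarray      # Gy, ascending from 0
    volume_fraction: np.ndarray

    def validate(self) -> None:
        if (np.diff(self.volume_fraction) > 1e-12).any():
            raise ValueError("volume_fraction must be non-increasing")
        if abs(self.volume_fraction[0] - 1.0) > 1e-12:
            raise ValueError("cumulative DVH must start at 1.0")
        if self.volume_fraction[-1] != 0.0:
            raise ValueError("cumulative DVH must end at 0")


def compute_dvh(dose: DoseGrid | np.ndarray, mask: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative >=-dose histogram of the masked voxels on a fixed grid."""
    d = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if mask.shape != d.shape:
        raise ValueError(f"mask shape {mask.shape} != dose shape {d.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = d[mask].astype(np.float64)
    top = vals.max() + bin_width
    axis = np.arange(0.0, top + bin_width, bin_width)
    frac = (vals[None, :] >= axis[:, None]).mean(axis=1)
    frac[0] = 1.0  # all voxels receive >= 0 Gy
    return DVHCurve(dose_axis=axis, volume_fraction=frac)


def metric_dx(dvh: DVHCurve, x: float) -> float:
    """D_X in Gy: the dose level at which the cumulative curve crosses X%.

    Linear interpolation between DVH samples; ties broken toward the higher
    dose (conservative for coverage metrics).
    """
    if not 0.0 < x < 100.0:
        raise ValueError(f"x must be in (0, 100), got {x}")
    target = x / 100.0
    vf = dvh.volume_fraction
    axis = dvh.dose_axis
    # vf is non-increasing: find the last index with vf >= target
    idx = np.nonzero(vf >= target)[0]
    if len(idx) == 0:
        return 0.0
    i = idx[-1]
    if i == len(vf) - 1 or vf[i] == target:
        return float(axis[i])
    # interpolate between (axis[i], vf[i]) and (axis[i+1], vf[i+1])
    v0, v1 = vf[i], vf[i + 1]
    if v0 == v1:
        return float(axis[i + 1])
    t = (v0 - target) / (v0 - v1)
    return float(axis[i] + t * (axis[i + 1] - axis[i]))


def metric_dmean(dose: DoseGrid | np.ndarray, mask: np.ndarray) -> float:
    """Mean dose (Gy) over the ROI."""
    d = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(d[mask].mean())


class MetricTable:
    """DVH metrics per (roi, metric), in Gy and % of prescription.

    Backed by a pandas DataFrame indexed by (roi, metric) with columns
    ``gy`` and ``pct``; missing organs are explicit NA rows.  An optional
    ``scenario`` tag marks nominal vs worst-case tables.
    """

    def __init__(self, frame: pd.DataFrame, prescription: float, scenario: str = "nominal"):
        self.frame = frame
        self.prescription = float(prescription)
        self.scenario = scenario

    @classmethod
    def from_values(cls, values: dict[tuple[str, str], float], prescription: float,
                    scenario: str = "nominal") -> "MetricTable":
        idx = pd.MultiIndex.from_tuples(values.keys(), names=["roi", "metric"])
        gy = pd.Series(list(values.values()), index=idx, dtype=float)
        frame = pd.DataFrame({"gy": gy, "pct": gy / prescription * 100.0})
        return cls(frame, prescription, scenario)

    def value(self, roi: str, metric: str, unit: str = "gy") -> float:
        return float(self.frame.loc[(roi, metric), unit])

    def keys(self):
        return list(self.frame.index)

    def __repr__(self) -> str:
        return f"MetricTable({self.scenario}, presc={self.prescription} Gy)\n{self.frame}"


def metric_table(dose: DoseGrid, masks: dict[str, np.ndarray | None], prescription: float,
                 bin_width: float = 0.1, scenario: str = "nominal") -> MetricTable:
    """Evaluate D95/D5/D2/Dmean for every ROI; a None mask yields NA rows
    (organ not contoured)."""
    values: dict[tuple[str, str], float] = {}
    for roi, mask in masks.items():
        if mask is None or not np.asarray(mask).any():
            for m in DVH_METRICS:
                values[(roi, m)] = np.nan
            continue
        dvh = compute_dvh(dose, mask, bin_width)
        values[(roi, "D95")] = metric_dx(dvh, 95)
        values[(roi, "D5")] = metric_dx(dvh, 5)
        values[(roi, "D2")] = metric_dx(dvh, 2)
        values[(roi, "Dmean")] = metric_dmean(dose, mask)
    return MetricTable.from_values(values, prescription, scenario)


def diff_table(metrics_ct: MetricTable, metrics_sct: MetricTable,
               prescription: float | None = None) -> pd.DataFrame:
    """Absolute CT-vs-sCT metric differences in % of prescription.

    Rows where either table is NA stay NA.  Raises if the two tables do not
    share the same (roi, metric) keys.
    """
    presc = prescription or metrics_ct.prescription
    a, b = metrics_ct.frame, metrics_sct.frame
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"metric tables disagree on keys: {list(missing)}")
    diff = (a["gy"] - b["gy"]).abs() / presc * 100.0
    return pd.DataFrame({"diff_pct": diff})


def cohort_table(per_subject: list[pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-subject difference tables into one cohort table.

    One column per subject plus mean and SD columns; NA entries (organ not
    contoured for that subject) are excluded from the statistics.
    """
    if not per_subject:
        raise ValueError("no subject tables")
    cols = {f"P{i + 1}": t["diff_pct"] for i, t in enumerate(per_subject)}
    out = pd.DataFrame(cols)
    out["mean"] = out.mean(axis=1, skipna=True)
    out["sd"] = out[list(cols)].std(axis=1, ddof=1, skipna=True)
    return out
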