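"""Simplified analytic proton dose model.

This engine exists to propagate HU differences between a CT and a synthetic
CT into dose differences.  It is deliberately *not* a clinical dose engine:
no Monte-Carlo transport, no nuclear interactions or scatter, axis-aligned
opposed beams only.  The chain it does implement is the physically relevant
one for range sensitivity:

HU --(piecewise-linear calibration)--> relative stopping power (RSP)
   --(cumulative line integral)-->     water-equivalent path length (WEPL)
   --(parametric Bragg curve)-->       depth dose per spot
   --(lateral Gaussian, spot sum)-->   beam dose, plan dose.

Plans are built by a deterministic heuristic: per opposed beam, spot ranges
span the target's WEPL extent (a spread-out Bragg peak) and lateral spot
positions cover the target cross-section; all weights are scaled so the
mean CTV dose equals the prescription on the planning image.  Setup and
range uncertainty enter as an image translation about the isocenter and a
multiplicative RSP scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "CalibrationCurve", "BeamSpec", "PlanSpec", "DoseGrid",
    "hu_to_rsp", "wepl_volume", "wepl_profile", "bragg_curve",
    "compute_beam_dose", "make_plan", "compute_plan_dose",
]

AIR_HU = -1000.0


@dataclass
class CalibrationCurve:
    """Piecewise-linear HU -> relative stopping power calibration.

    The default control points are representative of published
    stoichiometric fits (air ~0, water 1.0, cortical bone 1.6).
    """

    points: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.001), (0.0, 1.0), (1000.0, 1.6), (2000.0, 2.2))

    def validate(self) -> None:
        hu = np.array([p[0] for p in self.points])
        rsp = np.array([p[1] for p in self.points])
        if (np.diff(hu) <= 0).any():
            raise ValueError("calibration HU values must be strictly increasing")
        if (rsp < 0).any():
            raise ValueError("calibration RSP values must be >= 0")


def hu_to_rsp(hu, curve: CalibrationCurve | None = None):
    """Convert HU to RSP by linear interpolation, clamped at the curve ends."""
    curve = curve or CalibrationCurve()
    curve.validate()
    arr = np.asarray(hu, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite HU values")
    xs = np.array([p[0] for p in curve.points])
    ys = np.array([p[1] for p in curve.points])
    out = np.interp(arr, xs, ys)
    return float(out) if np.isscalar(hu) else out


@dataclass
class BeamSpec:
    """One axis-aligned scanned pencil beam.

    ``gantry_angle`` 90 enters from the -x face travelling +x; 270 is the
    opposed direction.  Spot lateral positions are mm in the (z, y) plane
    relative to the isocenter; nominal ranges are mm water-equivalent depth
    from the entry face.
    """

    gantry_angle: float = 90.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spot_z: tuple[float, ...] = (0.0,)
    spot_y: tuple[float, ...] = (0.0,)
    spot_range: tuple[float, ...] = (80.0,)
    spot_weight: tuple[float, ...] = (1.0,)
    lateral_sigma: float = 6.0

    def validate(self) -> None:
        n = len(self.spot_range)
        if n == 0:
            raise ValueError("beam must have at least one spot")
        if not (len(self.spot_z) == len(self.spot_y) == len(self.spot_weight) == n):
            raise ValueError("spot arrays must have equal length")
        if any(w < 0 for w in self.spot_weight):
            raise ValueError("spot weights must be >= 0")
        if self.gantry_angle not in (90.0, 270.0):
            raise ValueError(f"only axis-aligned beams (90 or 270 deg) are supported, "
                             f"got {self.gantry_angle}")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")


@dataclass
class PlanSpec:
    beams: list[BeamSpec]
    prescription: float = 60.0
    target_roi: str = "CTV"

    def validate(self) -> None:
        if not self.beams:
            raise ValueError("plan must contain at least one beam")
        if self.prescription <= 0:
            raise ValueError("prescription must be > 0")
        for b in self.beams:
            b.validate()

    def to_dict(self) -> dict:
        return {"beams": [asdict(b) for b in self.beams],
                "prescription": self.prescription, "target_roi": self.target_roi}

    @classmethod
    def from_dict(cls, d: dict) -> "PlanSpec":
        beams = [BeamSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in b.items()})
                 for b in d["beams"]]
        return cls(beams=beams, prescription=d["prescription"], target_roi=d["target_roi"])


@dataclass
class DoseGrid:
    """Dose in Gy on the image grid."""

    dose: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if not np.isfinite(self.dose).all():
            raise ValueError("non-finite dose values")
        if (self.dose < 0).any():
            raise ValueError("negative dose values")


def _mm_axes(shape, spacing):
    return [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]


def wepl_volume(rsp: np.ndarray, gantry_angle: float, spacing) -> np.ndarray:
    """Cumulative water-equivalent depth (mm) along the beam direction.

    WEPL at a voxel is the running sum of RSP x voxel length from the entry
    face up to and including that voxel.
    """
    dx = spacing[2]
    if gantry_angle == 90.0:
        return np.cumsum(rsp, axis=2) * dx
    if gantry_angle == 270.0:
        return np.flip(np.cumsum(np.flip(rsp, axis=2), axis=2), axis=2) * dx
    raise ValueError(f"only axis-aligned beams supported, got angle {gantry_angle}")


def wepl_profile(rsp: np.ndarray, gantry_angle: float, spacing, z: int, y: int) -> np.ndarray:
    """WEPL along a single ray at voxel row (z, y)."""
    nz, ny, _ = rsp.shape
    if not (0 <= z < nz and 0 <= y < ny):
        raise ValueError(f"ray (z={z}, y={y}) outside volume of shape {rsp.shape}")
    return wepl_volume(rsp, gantry_angle, spacing)[z, y]


def bragg_curve(nominal_range: float, wepl, distal_sigma: float = 3.0):
    """Parametric pristine Bragg curve, peak normalised to ~1 at the range.

    A slowly rising entrance plateau is gated off smoothly past the range
    and a Gaussian peak of width ``distal_sigma`` sits at ``nominal_range``;
    the dose falls smoothly to zero within a few ``distal_sigma`` beyond the
    peak.  Peak-to-entrance ratio is ~5.
    """
    if nominal_range <= 0:
        raise ValueError("nominal_range must be > 0")
    w = np.asarray(wepl, dtype=np.float64)
    gate = 1.0 / (1.0 + np.exp(np.clip((w - nominal_range) / (distal_sigma / 2.0), -60, 60)))
    plateau = 0.25 * (1.0 + np.clip(w, 0.0, nominal_range) / nominal_range) * gate
    peak = np.exp(-0.5 * ((w - nominal_range) / distal_sigma) ** 2)
    out = plateau + peak
    return float(out) if np.isscalar(wepl) else out


def compute_beam_dose(image: ImageVolume, beam: BeamSpec,
                      curve: CalibrationCurve | None = None,
                      range_scale: float = 1.0,
                      distal_sigma: float = 3.0) -> DoseGrid:
    """Dose of one beam: per-spot Bragg curve at the WEPL depth times a
    lateral Gaussian, summed with spot weights.

    ``range_scale`` multiplies the RSP volume and models range uncertainty
    (1.03 = +3% range error).
    """
    beam.validate()
    rsp = hu_to_rsp(image.data, curve) * range_scale
    wepl = wepl_volume(rsp, beam.gantry_angle, image.spacing)
    zmm, ymm, _ = _mm_axes(image.shape, image.spacing)
    zmm = zmm - beam.isocenter[0]
    ymm = ymm - beam.isocenter[1]
    dose = np.zeros(image.shape)
    sig2 = 2.0 * beam.lateral_sigma**2
    cut = 5.0 * beam.lateral_sigma
    for sz, sy, rng_mm, w in zip(beam.spot_z, beam.spot_y, beam.spot_range, beam.spot_weight):
        if w == 0.0:
            continue
        dz = zmm - sz
        dy = ymm - sy
        lat = np.exp(-(dz[:, None]**2 + dy[None, :]**2) / sig2)
        lat[np.sqrt(dz[:, None]**2 + dy[None, :]**2) > cut] = 0.0  # hard 5-sigma corridor
        dose += w * bragg_curve(rng_mm, wepl, distal_sigma) * lat[:, :, None]
    return DoseGrid(dose, image.spacing)


def make_plan(image: ImageVolume, target_mask: np.ndarray, prescription: float = 60.0,
              angles: tuple[float, ...] = (90.0, 270.0),
              curve: CalibrationCurve | None = None,
              lateral_sigma: float = 6.0, lateral_step: float = 4.0,
              lateral_margin: float = 6.0,
              range_step: float = 3.0, range_margin: float = 4.0) -> PlanSpec:
    """Deterministic opposed-beam SOBP plan normalised to the prescription.

    For each beam the spot ranges span the target's WEPL extent (plus a
    small margin) and lateral positions cover the target cross-section; a
    single global weight scale sets mean CTV dose = prescription on the
    planning image.
    """
    if not target_mask.any():
        raise ValueError("empty target mask")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    rsp = hu_to_rsp(image.data, curve)
    zmm, ymm, _ = _mm_axes(image.shape, image.spacing)
    beams = []
    for angle in angles:
        wepl = wepl_volume(rsp, angle, image.spacing)
        wt = wepl[target_mask]
        ranges = np.arange(max(wt.min() - range_margin, range_step),
                           wt.max() + range_margin + range_step, range_step)
        if len(ranges) == 0:
            raise ValueError("target outside beam coverage")
        zs = zmm[np.any(target_mask, axis=(1, 2))]
        ys = ymm[np.any(target_mask, axis=(0, 2))]
        lat_z = (np.arange(zs.min() - lateral_margin, zs.max() + lateral_margin + lateral_step,
                           lateral_step) if len(zs) > 1 else np.array([zs.mean()]))
        lat_y = (np.arange(ys.min() - lateral_margin, ys.max() + lateral_margin + lateral_step,
                           lateral_step) if len(ys) > 1 else np.array([ys.mean()]))
        spot_z, spot_y, spot_r, spot_w = [], [], [], []
        for sz in lat_z:
            for sy in lat_y:
                for r in ranges:
                    spot_z.append(float(sz))
                    spot_y.append(float(sy))
                    spot_r.append(float(r))
                    # mild distal weighting flattens the SOBP
                    spot_w.append(float(0.5 + 0.5 * (r - ranges.min()) / max(np.ptp(ranges), 1e-9)))
        beams.append(BeamSpec(gantry_angle=angle, spot_z=tuple(spot_z), spot_y=tuple(spot_y),
                              spot_range=tuple(spot_r), spot_weight=tuple(spot_w),
                              lateral_sigma=lateral_sigma))
    plan = PlanSpec(beams=beams, prescription=prescription)
    total = np.zeros(image.shape)
    for b in plan.beams:
        total += compute_beam_dose(image, b, curve).dose
    mean_ctv = total[target_mask].mean()
    if mean_ctv <= 0:
        raise ValueError("plan delivers no dose to the target")
    scale = float(prescription / mean_ctv)
    for b in plan.beams:
        b.spot_weight = tuple(float(w * scale) for w in b.spot_weight)
    return plan


def compute_plan_dose(plan: PlanSpec, image: ImageVolume, scenario=None,
                      curve: CalibrationCurve | None = None) -> DoseGrid:
    """Plan dose under one uncertainty scenario.

    The scenario's setup shift s (mm) displaces the patient relative to the
    fixed beam geometry: the image is translated by -s (linear
    interpolation, air fill) before dose computation, and callers evaluating
    anatomy-fixed ROIs must translate their masks by -s as well.  The range
    error scales RSP multiplicatively.
    """
    plan.validate()
    shift = np.zeros(3)
    range_error = 0.0
    if scenario is not None:
        shift = np.asarray(getattr(scenario, "setup_shift"), dtype=np.float64)
        range_error = float(getattr(scenario, "range_error"))
    img = image
    shift = _effective_shift(shift, image.shape)
    if np.any(shift != 0):
        shift_vox = -shift / np.asarray(image.spacing)
        moved = ndimage.shift(image.data.astype(np.float64), shift_vox, order=1,
                              mode="constant", cval=AIR_HU)
        img = ImageVolume(moved, image.spacing)
    dose = np.zeros(image.shape)
    for beam in plan.beams:
        dose += compute_beam_dose(img, beam, curve, range_scale=1.0 + range_error).dose
    return DoseGrid(dose, image.spacing)


def _effective_shift(shift_mm: np.ndarray, shape) -> np.ndarray:
    """Zero out shift components along single-voxel axes: a 2D slice stack
    has no out-of-plane extent, so those components are not representable."""
    out = np.asarray(shift_mm, dtype=np.float64).copy()
    for ax, n in enumerate(shape):
        if n == 1:
            out[ax] = 0.0
    return out


def shift_mask(mask: np.ndarray, setup_shift_mm, spacing) -> np.ndarray:
    """Translate a binary ROI mask by -s, matching the image convention in
    :func:`compute_plan_dose` (nearest-neighbour, so masks stay binary)."""
    shift = _effective_shift(np.asarray(setup_shift_mm, dtype=np.float64), mask.shape)
    shift_vox = -shift / np.asarray(spacing)
    if not np.any(shift_vox):
        return mask
    out = ndimage.shift(mask.astype(np.float64), shift_vox, order=0, mode="constant", cval=0.0)
    return out > 0.5
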