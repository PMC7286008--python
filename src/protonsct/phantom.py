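"""Seeded paired MRI/CT head phantoms.

Every downstream stage of the package (MI loss, GAN training, dose
computation, robustness analysis) is exercised on procedurally generated
head phantoms: a circular/spherical head with a skull shell, internal air
cavities, soft tissue and a tumor target.  The phantoms reproduce the one
property that makes MRI-to-CT synthesis hard: the MRI intensity map is
*non-monotonic* with respect to HU — cortical bone and air are both dark on
a T1-weighted image although they sit at opposite ends of the HU scale.

The MRI of each pair is additionally perturbed by a small random rigid
transform so that MRI/CT pairs are non-aligned, emulating clinical pairs
acquired in separate sessions.  The transform parameters are recorded in
the sample so tests can verify the bounds.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, write_volume

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "PairedSample",
    "PhantomSpecError",
    "default_tissue_classes",
    "make_phantom",
    "make_cohort",
    "write_sample",
]

# integer labels in the label volume
LABEL_AIR = 0
LABEL_SOFT = 1
LABEL_BONE = 2
LABEL_TUMOR = 3

_LABEL_BY_NAME = {"air": LABEL_AIR, "soft_tissue": LABEL_SOFT, "bone": LABEL_BONE, "tumor": LABEL_TUMOR}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates an invariant."""


@dataclass
class TissueClass:
    """HU and MRI intensity distribution of one tissue type."""

    name: str
    hu_mean: float
    hu_sd: float
    mri_mean: float
    mri_sd: float

    def validate(self) -> None:
        if not (-1000.0 <= self.hu_mean <= 2000.0):
            raise PhantomSpecError(f"tissue {self.name!r}: hu_mean {self.hu_mean} outside [-1000, 2000]")
        if self.hu_sd < 0 or self.mri_sd < 0:
            raise PhantomSpecError(f"tissue {self.name!r}: standard deviations must be >= 0")
        if self.mri_mean < 0:
            raise PhantomSpecError(f"tissue {self.name!r}: mri_mean must be >= 0")


def default_tissue_classes() -> list[TissueClass]:
    """HU anchors air/soft/bone/tumor = -1000/30/1000/60; MRI anchors chosen so
    bone and air are both dark (non-monotonic MRI-to-HU map)."""
    return [
        TissueClass("air", -1000.0, 10.0, 30.0, 10.0),
        TissueClass("soft_tissue", 30.0, 20.0, 400.0, 30.0),
        TissueClass("bone", 1000.0, 50.0, 60.0, 20.0),
        TissueClass("tumor", 60.0, 20.0, 550.0, 40.0),
    ]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one head phantom.

    Lengths are mm; ``shape`` and ``spacing`` follow the package (z, y, x)
    convention.  The default is a single-slice 64x64 stack, matching the 2D
    per-slice synthesis model.
    """

    shape: tuple[int, int, int] = (1, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    head_radius: float = 80.0
    skull_thickness: float = 7.0
    n_air_cavities: int = 2
    tumor_radius: float = 10.0
    tumor_center: tuple[float, float, float] = (0.0, 8.0, 16.0)
    tissue_classes: list[TissueClass] = field(default_factory=default_tissue_classes)
    misalignment_max_shift: float = 6.0
    misalignment_max_rotation: float = 3.0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise PhantomSpecError(f"shape must be three positive voxel counts, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise PhantomSpecError(f"spacing must be positive on all axes, got {self.spacing}")
        if not (0 < self.skull_thickness < self.head_radius):
            raise PhantomSpecError(
                f"skull_thickness must satisfy 0 < {self.skull_thickness} < head_radius {self.head_radius}"
            )
        inner = self.head_radius - self.skull_thickness
        off = np.linalg.norm(self._tumor_offset_2d())
        if self.tumor_radius <= 0 or off + self.tumor_radius >= inner:
            raise PhantomSpecError(
                "tumor not fully inside the head interior: "
                f"|offset| {off:.1f} + radius {self.tumor_radius:.1f} >= inner radius {inner:.1f}"
            )
        if self.n_air_cavities < 0:
            raise PhantomSpecError("n_air_cavities must be >= 0")
        if self.misalignment_max_shift < 0 or self.misalignment_max_rotation < 0:
            raise PhantomSpecError("misalignment bounds must be >= 0")
        names = {t.name for t in self.tissue_classes}
        missing = {"air", "soft_tissue", "bone", "tumor"} - names
        if missing:
            raise PhantomSpecError(f"missing required tissue classes: {sorted(missing)}")
        for t in self.tissue_classes:
            t.validate()

    def _tumor_offset_2d(self) -> np.ndarray:
        return np.asarray(self.tumor_center[1:], dtype=float)

    def tissue(self, name: str) -> TissueClass:
        for t in self.tissue_classes:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "tissue_classes" in d:
            d["tissue_classes"] = [TissueClass(**t) for t in d["tissue_classes"]]
        for key in ("shape", "spacing", "tumor_center"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PairedSample:
    """One subject: MRI, CT, tissue labels and ROI masks on a shared grid."""

    mri: ImageVolume
    ct: ImageVolume
    labels: np.ndarray
    masks: dict[str, np.ndarray]
    subject_id: str
    misalignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shp = self.ct.shape
        if self.mri.shape != shp or self.labels.shape != shp:
            raise PhantomSpecError("mri, ct and labels must share one shape")
        for name, m in self.masks.items():
            if m.shape != shp:
                raise PhantomSpecError(f"mask {name!r} shape {m.shape} != volume shape {shp}")

    @property
    def body_mask(self) -> np.ndarray:
        """Ground-truth body region (everything that is not exterior air)."""
        return self.labels != LABEL_AIR


def _coordinate_grids(shape, spacing):
    """mm coordinates of voxel centres relative to the volume centre, (z, y, x)."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _build_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    zz, yy, xx = _coordinate_grids(spec.shape, spec.spacing)
    # head is a sphere in 3D, a disc for single-slice stacks (z distance 0 there)
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    labels = np.full(spec.shape, LABEL_AIR, dtype=np.int16)
    inner = spec.head_radius - spec.skull_thickness
    labels[r <= spec.head_radius] = LABEL_BONE
    labels[r <= inner] = LABEL_SOFT

    # air cavities: sinus-like pockets in the anterior (negative y) interior
    for _ in range(spec.n_air_cavities):
        cy = rng.uniform(-0.60, -0.30) * inner
        cx = rng.uniform(-0.35, 0.35) * inner
        cz = 0.0 if spec.shape[0] == 1 else rng.uniform(-0.2, 0.2) * inner
        rad = rng.uniform(5.0, 9.0)
        cav = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= rad
        labels[cav & (labels == LABEL_SOFT)] = LABEL_AIR

    tz, ty, tx = spec.tumor_center
    tum = np.sqrt((zz - tz) ** 2 + (yy - ty) ** 2 + (xx - tx) ** 2) <= spec.tumor_radius
    labels[tum & (labels == LABEL_SOFT)] = LABEL_TUMOR
    return labels


def _paint(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator, which: str) -> np.ndarray:
    """Fill each labelled region with draws from its class distribution."""
    out = np.zeros(labels.shape, dtype=np.float64)
    for t in spec.tissue_classes:
        m = labels == _LABEL_BY_NAME[t.name]
        if not m.any():
            continue
        if which == "hu":
            out[m] = rng.normal(t.hu_mean, t.hu_sd, size=int(m.sum())) if t.hu_sd > 0 else t.hu_mean
        else:
            out[m] = rng.normal(t.mri_mean, t.mri_sd, size=int(m.sum())) if t.mri_sd > 0 else t.mri_mean
    if which == "hu":
        np.clip(out, -1000.0, 2000.0, out=out)
    else:
        np.clip(out, 0.0, None, out=out)
    return out


def _rigid_misalign(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator, fill: float):
    """Apply a random in-plane rigid transform (rotation about z + shift).

    Returns the transformed image and the drawn parameters.  Linear
    interpolation; voxels pulled from outside the field are filled with the
    air intensity.
    """
    angle = float(rng.uniform(-spec.misalignment_max_rotation, spec.misalignment_max_rotation))
    shift_mm = rng.uniform(-spec.misalignment_max_shift, spec.misalignment_max_shift, size=3)
    if img.shape[0] == 1:
        shift_mm[0] = 0.0
    params = {"rotation_deg": angle, "shift_mm": [float(s) for s in shift_mm]}
    if angle == 0.0 and not np.any(shift_mm):
        return img.copy(), params

    theta = np.deg2rad(angle)
    c, s = np.cos(theta), np.sin(theta)
    # output voxel -> input voxel map: rotate about the volume centre in the
    # (y, x) plane, then translate by the shift (mm converted to voxels)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    centre = (np.asarray(img.shape) - 1) / 2.0
    shift_vox = shift_mm / np.asarray(spec.spacing)
    offset = centre - rot @ centre - rot @ shift_vox
    moved = ndimage.affine_transform(img, rot, offset=offset, order=1, mode="constant", cval=fill)
    return moved, params


def make_phantom(spec: PhantomSpec, seed: int) -> PairedSample:
    """Generate one paired MRI/CT head phantom.

    Deterministic for a fixed ``(spec, seed)``.  The CT carries HU, the MRI
    the non-monotonic tissue intensities, and the MRI is rigidly perturbed
    within the spec's misalignment bounds.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    labels = _build_labels(spec, rng)
    ct = _paint(labels, spec, rng, "hu")
    mri_aligned = _paint(labels, spec, rng, "mri")
    mri, params = _rigid_misalign(mri_aligned, spec, rng, fill=spec.tissue("air").mri_mean)

    masks = {
        "CTV": labels == LABEL_TUMOR,
        "brainstem": _brainstem_mask(spec),
    }
    return PairedSample(
        mri=ImageVolume(mri, spec.spacing),
        ct=ImageVolume(ct, spec.spacing),
        labels=labels,
        masks=masks,
        subject_id=f"subj-{seed}",
        misalignment=params,
    )


def _brainstem_mask(spec: PhantomSpec) -> np.ndarray:
    """A fixed posterior-medial organ-at-risk stand-in."""
    zz, yy, xx = _coordinate_grids(spec.shape, spec.spacing)
    inner = spec.head_radius - spec.skull_thickness
    cy, cx, rad = 0.35 * inner, -0.20 * inner, 7.0
    return np.sqrt(zz**2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= rad


def make_cohort(spec: PhantomSpec, n: int, seed: int) -> list[PairedSample]:
    """Generate ``n`` phantoms with jittered tumor geometry.

    Per-subject sub-seeds are derived deterministically from ``seed``; the
    tumor position and radius are jittered so subjects differ anatomically.
    """
    if n < 1:
        raise PhantomSpecError(f"cohort size must be >= 1, got {n}")
    spec.validate()
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for i in range(n):
        s = copy.deepcopy(spec)
        s.tumor_radius = float(spec.tumor_radius * rng.uniform(0.8, 1.2))
        jitter = rng.uniform(-5.0, 5.0, size=2)
        centre = np.array(spec.tumor_center, dtype=float)
        centre[1:] += jitter
        # keep the jittered tumor inside the head interior
        inner = spec.head_radius - spec.skull_thickness
        norm = np.linalg.norm(centre[1:])
        max_off = inner - s.tumor_radius - spec.spacing[1]
        if norm > max_off:
            centre[1:] *= max_off / norm
        s.tumor_center = tuple(centre)
        sample = make_phantom(s, int(subseeds[i]))
        sample.subject_id = f"subj-{i:03d}"
        cohort.append(sample)
    return cohort


def write_sample(sample: PairedSample, out_dir) -> None:
    """Write one sample as NIfTI volumes plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = sample.ct.spacing
    write_volume(sample.mri, out / "mri.nii.gz")
    write_volume(sample.ct, out / "ct.nii.gz")
    write_volume(ImageVolume(sample.labels.astype(np.float32), spacing), out / "labels.nii.gz")
    for name, mask in sample.masks.items():
        write_volume(ImageVolume(mask.astype(np.float32), spacing), out / f"mask_{name}.nii.gz")
    sidecar = {
        "subject_id": sample.subject_id,
        "spacing_mm": list(spacing),
        "misalignment": sample.misalignment,
    }
    (out / "sample.json").write_text(json.dumps(sidecar, indent=2))
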