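"""Mutual information between intensity images via joint histograms.

MI(X, Y) = H(X) + H(Y) - H(X, Y), estimated from a discretised joint
intensity distribution.  Two binning modes are provided:

* hard binning (``smoothing_bandwidth = 0``) — each voxel pair increments a
  single histogram cell; exact, used as the test oracle;
* smooth binning — each voxel spreads its mass linearly over the two
  neighbouring bins (triangular / partial-volume kernel), which makes the
  histogram, and therefore MI, differentiable with respect to the voxel
  intensities.  This is the form usable as a training loss.

Entropies are reported in bits.  MI is large when the two images are
deterministically related — under *any* intensity mapping, monotonic or not
— which is precisely why it tolerates the non-monotonic MRI-to-HU map and
residual misalignment between training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MIConfig",
    "JointHistogram",
    "joint_histogram",
    "entropy",
    "mutual_information",
    "mi_training_loss",
    "mi_loss_and_grad",
]

_LN2 = np.log(2.0)


@dataclass
class MIConfig:
    """Binning configuration for the joint histogram.

    ``smoothing_bandwidth`` is expressed as a fraction of the bin width;
    0 selects hard binning, 1.0 the triangular kernel spanning the two
    neighbouring bins.
    """

    n_bins: int = 64
    intensity_range: tuple[float, float] = (0.0, 1.0)
    smoothing_bandwidth: float = 1.0
    epsilon: float = 1e-10

    def validate(self) -> None:
        lo, hi = self.intensity_range
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not lo < hi:
            raise ValueError(f"intensity_range must satisfy lo < hi, got {self.intensity_range}")
        if self.smoothing_bandwidth < 0:
            raise ValueError("smoothing_bandwidth must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class JointHistogram:
    """Discretised joint distribution p(a, b) with its marginals."""

    table: np.ndarray
    bin_edges: np.ndarray
    marginal_a: np.ndarray
    marginal_b: np.ndarray

    def validate(self) -> None:
        if (self.table < -1e-12).any():
            raise ValueError("joint histogram has negative entries")
        if abs(self.table.sum() - 1.0) > 1e-9:
            raise ValueError(f"joint histogram sums to {self.table.sum()}, not 1")
        if not np.allclose(self.marginal_a, self.table.sum(axis=1), atol=1e-9):
            raise ValueError("marginal_a inconsistent with table row sums")
        if not np.allclose(self.marginal_b, self.table.sum(axis=0), atol=1e-9):
            raise ValueError("marginal_b inconsistent with table column sums")
        if (np.diff(self.bin_edges) <= 0).any():
            raise ValueError("bin_edges must be strictly increasing")


def _bin_coordinates(img: np.ndarray, cfg: MIConfig):
    """Map intensities to fractional bin coordinates; clamp to the range."""
    lo, hi = cfg.intensity_range
    v = np.clip(np.asarray(img, dtype=np.float64).ravel(), lo, hi)
    width = (hi - lo) / cfg.n_bins
    return v, width


def _soft_assign(img: np.ndarray, cfg: MIConfig):
    """Triangular-kernel bin assignment: indices (i, i+1) and weights (1-f, f)."""
    v, width = _bin_coordinates(img, cfg)
    lo, _ = cfg.intensity_range
    t = (v - lo) / width - 0.5  # bin-centre coordinate
    i0 = np.floor(t).astype(np.int64)
    f = t - i0
    i0c = np.clip(i0, 0, cfg.n_bins - 1)
    i1c = np.clip(i0 + 1, 0, cfg.n_bins - 1)
    return i0c, i1c, 1.0 - f, f


def _hard_assign(img: np.ndarray, cfg: MIConfig):
    v, width = _bin_coordinates(img, cfg)
    lo, _ = cfg.intensity_range
    idx = np.floor((v - lo) / width).astype(np.int64)
    return np.clip(idx, 0, cfg.n_bins - 1)


def joint_histogram(a: np.ndarray, b: np.ndarray, cfg: MIConfig | None = None) -> JointHistogram:
    """Normalised joint intensity histogram of two equally shaped images."""
    cfg = cfg or MIConfig()
    cfg.validate()
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    B = cfg.n_bins
    n = a.size
    if cfg.smoothing_bandwidth == 0:
        ia = _hard_assign(a, cfg)
        ib = _hard_assign(b, cfg)
        table = np.bincount(ia * B + ib, minlength=B * B).astype(np.float64)
    else:
        ia0, ia1, wa0, wa1 = _soft_assign(a, cfg)
        ib0, ib1, wb0, wb1 = _soft_assign(b, cfg)
        table = np.zeros(B * B)
        for ia, wa in ((ia0, wa0), (ia1, wa1)):
            for ib, wb in ((ib0, wb0), (ib1, wb1)):
                table += np.bincount(ia * B + ib, weights=wa * wb, minlength=B * B)
    table = table.reshape(B, B) / n
    lo, hi = cfg.intensity_range
    edges = np.linspace(lo, hi, B + 1)
    return JointHistogram(table, edges, table.sum(axis=1), table.sum(axis=0))


def entropy(p: np.ndarray, epsilon: float = 1e-10) -> float:
    """Shannon entropy in bits of a normalised probability vector or table."""
    p = np.asarray(p, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return float(-(p * np.log2(p + epsilon)).sum())


def mutual_information(a: np.ndarray, b: np.ndarray, cfg: MIConfig | None = None) -> float:
    """MI(a, b) = H(a) + H(b) - H(a, b) in bits, from one joint histogram."""
    cfg = cfg or MIConfig()
    h = joint_histogram(a, b, cfg)
    return mi_from_histogram(h, cfg.epsilon)


def mi_from_histogram(h: JointHistogram, epsilon: float = 1e-10) -> float:
    return entropy(h.marginal_a, epsilon) + entropy(h.marginal_b, epsilon) - entropy(h.table, epsilon)


def mi_double_sum(h: JointHistogram, epsilon: float = 1e-10) -> float:
    """The equivalent double-sum form sum p log2(p / (p_a p_b)); cross-check."""
    p = h.table
    outer = np.outer(h.marginal_a, h.marginal_b)
    mask = p > 0
    return float((p[mask] * np.log2((p[mask] + epsilon) / (outer[mask] + epsilon))).sum())


def mi_training_loss(a: np.ndarray, b: np.ndarray, cfg: MIConfig | None = None,
                     mode: str = "mi") -> float:
    """Differentiable synthesis loss.

    ``mode="mi"`` returns -MI(a, b) (lower is better); ``mode="joint_entropy"``
    returns H(a, b), the joint-entropy variant.  Both are minimised when b is
    a deterministic relabelling of a.  Requires smooth binning.
    """
    loss, _ = mi_loss_and_grad(a, b, cfg, mode=mode)
    return loss


def mi_loss_and_grad(a: np.ndarray, b: np.ndarray, cfg: MIConfig | None = None,
                     mode: str = "mi") -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to ``b``.

    The smooth histogram is piecewise linear in each voxel of ``b``, so the
    chain rule through p(i, j) is exact: moving a voxel of ``b`` transfers
    mass between its two neighbouring bins at rate 1/bin_width.
    """
    cfg = cfg or MIConfig()
    cfg.validate()
    if cfg.smoothing_bandwidth == 0:
        raise ValueError("training loss requires smooth binning (smoothing_bandwidth > 0); "
                         "hard binning is not differentiable")
    if mode not in ("mi", "joint_entropy"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")

    h = joint_histogram(a, b, cfg)
    eps = cfg.epsilon
    p, pa, pb = h.table, h.marginal_a, h.marginal_b

    if mode == "mi":
        loss = -mi_from_histogram(h, eps)
        # d(-MI)/dp_ij, dropping terms that depend on i only: perturbing a
        # voxel of b moves mass within one row of the table, so the marginal
        # over a is conserved and row-constant terms cancel.
        dpb = np.log2(pb + eps) + (pb / (pb + eps)) / _LN2
        dp = np.log2(p + eps) + (p / (p + eps)) / _LN2
        g = dpb[None, :] - dp
    else:
        loss = entropy(p, eps)
        g = -(np.log2(p + eps) + (p / (p + eps)) / _LN2)

    ia0, ia1, wa0, wa1 = _soft_assign(a, cfg)
    ib0, ib1, wb0, wb1 = _soft_assign(b, cfg)
    lo, hi = cfg.intensity_range
    width = (hi - lo) / cfg.n_bins
    n = b.size
    # dloss/db_k = (1/n) sum_i w_a,i(k) * [g(i, ib1) - g(i, ib0)] / width
    db = (wa0 * (g[ia0, ib1] - g[ia0, ib0]) + wa1 * (g[ia1, ib1] - g[ia1, ib0])) / (n * width)
    # clamped voxels (at the range boundary or in edge-clipped bins) get zero flow
    v = np.asarray(b, dtype=np.float64).ravel()
    db[(v <= lo) | (v >= hi) | (ib0 == ib1)] = 0.0
    return float(loss), db.reshape(b.shape)
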