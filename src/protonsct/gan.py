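"""Conditional GAN for MRI-to-synthetic-CT synthesis.

The generator is a 2D U-Net mapping a normalised MRI slice to a normalised
CT slice; the discriminator is a strided convolutional classifier that, in
its default conditional form, scores the (MRI, CT-candidate) pair as real or
synthetic.  The generator's synthesis loss is the (negated) mutual
information between the real CT and the generated slice — an
intensity-mapping-free similarity, which is what lets the model train on
MRI/CT pairs that are *not* rigidly aligned — combined with the adversarial
term, which pins the intensity scale the MI term leaves free.  Both networks
are optimised with Adam using separate learning rates (defaults 2e-4 for the
generator, 5e-5 for the discriminator, beta1 = 0.5 for both; see
:meth:`TrainConfig.phantom_scale` for the desk-scale settings).

Intensities are max-normalised per image before training; CT volumes are
first offset by +1000 HU so all values are nonnegative.  The training-set
maximum of the offset CT is stored in the fitted model as
``normalization_scale`` and used to restore HU at inference time (a paired
CT maximum does not exist in MRI-only deployment).

Usage follows the model/results pattern::

    model = MISynthesisGAN(cohort)
    res = model.fit(TrainConfig(epochs=30, seed=0))
    sct = res.predict_sct(sample.mri)
    print(res.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn.unet import UNet
from .mi import MIConfig, mi_loss_and_grad, mi_training_loss
from .phantom import PairedSample
from .volume import ImageVolume

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "TrainConfig",
    "normalize", "denormalize", "HU_OFFSET",
    "build_generator", "build_discriminator",
    "discriminator_loss", "generator_loss",
    "MISynthesisGAN", "SynthesisResults",
    "train", "crossval_split", "CVSplit", "crossvalidate", "CVResults",
    "predict_sct",
]

#: CT volumes are shifted by +1000 HU before max-normalisation so that the
#: per-image maximum division is well behaved for signed HU.
HU_OFFSET = 1000.0

_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# configs


@dataclass
class GeneratorConfig:
    input_size: int = 64
    depth: int = 3
    convs_per_block: int = 3
    kernel_size: int = 3
    base_filters: int = 8
    dropout_rate: float = 0.5
    final_activation: str = "sigmoid"

    def validate(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}")
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.final_activation != "sigmoid":
            raise ValueError("only sigmoid final activation is supported")


@dataclass
class DiscriminatorConfig:
    input_size: int = 64
    # 2 input channels = conditional discriminator scoring the (MRI, CT)
    # pair; 1 = unconditional image discriminator
    in_channels: int = 1
    conv_filter_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    kernel_size: int = 3
    stride: int = 2
    n_fc_layers: int = 5
    # light dropout: the fully connected head is only 64->32->16->8 units at
    # the 64x64 scale, where heavy dropout starves the classifier
    dropout_rate: float = 0.1
    # leaky activations keep the discriminator's gradient alive: with only
    # 2 filters in the first layer, plain ReLU frequently dies on smooth
    # generator outputs and the adversarial gradient vanishes exactly
    leaky_slope: float = 0.2
    output_activation: str = "sigmoid"

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if not self.conv_filter_sizes:
            raise ValueError("conv_filter_sizes must be nonempty")
        if self.input_size < 2 ** len(self.conv_filter_sizes):
            raise ValueError(
                f"input_size {self.input_size} smaller than 2^{len(self.conv_filter_sizes)} "
                "required by the strided convolutions")
        if self.n_fc_layers < 1:
            raise ValueError("need at least one fully connected layer")
        if self.output_activation != "sigmoid":
            raise ValueError("only sigmoid output activation is supported")


@dataclass
class TrainConfig:
    lr_generator: float = 2e-4
    beta1_generator: float = 0.5
    lr_discriminator: float = 5e-5
    beta1_discriminator: float = 0.5
    adversarial_weight: float = 1.0
    mi_weight: float = 1.0
    mi_mode: str = "mi"
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    @classmethod
    def phantom_scale(cls, **overrides) -> "TrainConfig":
        """Training configuration for desk-scale 64x64 phantom cohorts.

        The stock learning rates suit long GPU-scale trainings (tens of
        thousands of optimiser steps); a 30-epoch run on a small cohort
        takes only a few hundred steps, so the step sizes are scaled up
        and the batch reduced accordingly.
        """
        base = dict(lr_generator=1e-2, lr_discriminator=2e-3, batch_size=4, epochs=30)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be > 0")
        if not (0 < self.beta1_generator < 1 and 0 < self.beta1_discriminator < 1):
            raise ValueError("beta1 values must be in (0, 1)")
        if self.mi_weight <= 0:
            raise ValueError("mi_weight must be > 0")
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# normalisation


def normalize(image: ImageVolume | np.ndarray, offset: float = 0.0):
    """Max-normalise an image to [0, 1]; returns ``(unit_image, scale)``.

    ``offset`` is added before division (use :data:`HU_OFFSET` for CT so the
    signed HU range becomes nonnegative).  The scale is recorded such that
    :func:`denormalize` reproduces the input within float tolerance.
    """
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image)
    shifted = data.astype(np.float64) + offset
    scale = float(shifted.max())
    if scale <= 0 or shifted.min() == shifted.max():
        raise ValueError("image has zero dynamic range after offsetting; cannot max-normalise")
    return shifted / scale, scale


def denormalize(unit: np.ndarray, scale: float, offset: float = 0.0) -> np.ndarray:
    """Inverse of :func:`normalize`: restores physical units (HU for CT)."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return np.asarray(unit, dtype=np.float64) * scale - offset


# ---------------------------------------------------------------------------
# networks


def build_generator(cfg: GeneratorConfig | None = None,
                    rng: np.random.Generator | None = None) -> UNet:
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    return UNet(depth=cfg.depth, base_filters=cfg.base_filters,
                convs_per_block=cfg.convs_per_block, kernel_size=cfg.kernel_size,
                dropout_rate=cfg.dropout_rate, rng=rng or np.random.default_rng(0))


def build_discriminator(cfg: DiscriminatorConfig | None = None,
                        rng: np.random.Generator | None = None) -> nn.Sequential:
    cfg = cfg or DiscriminatorConfig()
    cfg.validate()
    rng = rng or np.random.default_rng(0)
    def act():
        return nn.LeakyReLU(cfg.leaky_slope) if cfg.leaky_slope > 0 else nn.ReLU()

    layers: list[nn.Layer] = []
    c_in = cfg.in_channels
    size = cfg.input_size
    for i, c_out in enumerate(cfg.conv_filter_sizes):
        layers.append(nn.Conv2d(c_in, c_out, k=cfg.kernel_size, stride=cfg.stride, pad=1, rng=rng))
        if i > 0:
            layers.append(nn.BatchNorm2d(c_out))
        layers.append(act())
        size = (size + 2 - cfg.kernel_size) // cfg.stride + 1
        c_in = c_out
    layers.append(nn.Flatten())
    flat = c_in * size * size
    hidden = [64, 32, 16, 8, 4, 2][: cfg.n_fc_layers - 1]
    dims = [flat] + hidden + [1]
    for i in range(len(dims) - 1):
        layers.append(nn.Dense(dims[i], dims[i + 1], rng=rng))
        if i < len(dims) - 2:
            layers.append(act())
            layers.append(nn.Dropout(cfg.dropout_rate,
                                     rng=np.random.default_rng(rng.integers(2**31 - 1))))
    layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


# ---------------------------------------------------------------------------
# losses


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Batch-mean of -log D(real) - log(1 - D(fake)) (natural log)."""
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    return float(np.mean(-np.log(dr)) + np.mean(-np.log(1.0 - df)))


def generator_loss(real_ct: np.ndarray, fake_ct: np.ndarray, d_fake: np.ndarray,
                   train_cfg: TrainConfig, mi_cfg: MIConfig | None = None) -> float:
    """mi_weight * MI-loss(real, fake) + adversarial_weight * (-log D(fake)).

    With ``adversarial_weight = 0`` this reduces to the pure mutual-
    information objective.  Images are expected in normalised [0, 1] units;
    slices along the leading axis are averaged.
    """
    mi_cfg = mi_cfg or MIConfig()
    real = np.atleast_3d(np.asarray(real_ct))
    fake = np.atleast_3d(np.asarray(fake_ct))
    mi_term = float(np.mean([
        mi_training_loss(r, f, mi_cfg, mode=train_cfg.mi_mode) for r, f in zip(real, fake)
    ]))
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    adv_term = float(np.mean(-np.log(df)))
    return train_cfg.mi_weight * mi_term + train_cfg.adversarial_weight * adv_term


# ---------------------------------------------------------------------------
# numerically stable adversarial updates
#
# The discriminator ends in a sigmoid; its losses are differentiated at the
# logit level (standard binary cross-entropy with logits), where the
# gradients (d - target) are bounded.  Differentiating the clamped
# probabilities instead either underflows (saturated sigmoid) or explodes
# (1/d factors), both of which destabilise the generator update.


def _disc_forward_logits(disc: nn.Sequential, x: np.ndarray, training: bool) -> np.ndarray:
    for layer in disc.layers[:-1]:
        x = layer.forward(x, training=training)
    return x


def _disc_backward_logits(disc: nn.Sequential, dlogit: np.ndarray) -> np.ndarray:
    dy = dlogit
    for layer in reversed(disc.layers[:-1]):
        dy = layer.backward(dy)
    return dy


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


# ---------------------------------------------------------------------------
# data plumbing


def _cohort_slices(cohort: list[PairedSample]):
    """Per-image max-normalised 2D slices; returns (mri, ct) arrays (N,1,H,W)
    plus the training-set maximum of the offset CT."""
    mri, ct = [], []
    ct_max = 0.0
    for s in cohort:
        m_unit, _ = normalize(s.mri)
        c_unit, c_scale = normalize(s.ct, offset=HU_OFFSET)
        ct_max = max(ct_max, c_scale)
        for z in range(s.ct.shape[0]):
            mri.append(m_unit[z])
            ct.append(c_unit[z])
    return (np.asarray(mri)[:, None], np.asarray(ct)[:, None], ct_max)


# ---------------------------------------------------------------------------
# model / results


class MISynthesisGAN:
    """MRI-to-sCT synthesis model over a cohort of paired samples.

    Parameters
    ----------
    cohort : list of PairedSample
        Training subjects (MRI/CT pairs; pairs may be misaligned).
    gen_cfg, disc_cfg, mi_cfg : optional
        Network and MI-loss configuration; defaults match the phantom scale.
    """

    def __init__(self, cohort: list[PairedSample],
                 gen_cfg: GeneratorConfig | None = None,
                 disc_cfg: DiscriminatorConfig | None = None,
                 mi_cfg: MIConfig | None = None):
        if not cohort:
            raise ValueError("cohort must be nonempty")
        self.cohort = list(cohort)
        self.gen_cfg = gen_cfg or GeneratorConfig()
        # conditional discriminator by default: it scores the (MRI, CT) pair,
        # which is what breaks the intensity-relabelling symmetry the MI term
        # cannot resolve on its own
        self.disc_cfg = disc_cfg or DiscriminatorConfig(input_size=self.gen_cfg.input_size,
                                                        in_channels=2)
        self.mi_cfg = mi_cfg or MIConfig()
        self.gen_cfg.validate()
        self.disc_cfg.validate()

    def _pair(self, mri_batch: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        if self.disc_cfg.in_channels == 2:
            return np.concatenate([mri_batch, candidate], axis=1)
        return candidate

    def fit(self, train_cfg: TrainConfig | None = None,
            validation: list[PairedSample] | None = None) -> "SynthesisResults":
        """Alternating discriminator/generator Adam updates.

        Deterministic for a fixed seed.  Raises on non-finite losses.
        """
        cfg = train_cfg or TrainConfig()
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        gen = build_generator(self.gen_cfg, rng=np.random.default_rng(rng.integers(2**31 - 1)))
        disc = build_discriminator(self.disc_cfg, rng=np.random.default_rng(rng.integers(2**31 - 1)))
        opt_g = nn.Adam(gen.params(), lr=cfg.lr_generator, beta1=cfg.beta1_generator)
        opt_d = nn.Adam(disc.params(), lr=cfg.lr_discriminator, beta1=cfg.beta1_discriminator)

        mri, ct, scale = _cohort_slices(self.cohort)
        n = mri.shape[0]
        history = {"d_loss": [], "g_loss": [], "g_mi": [], "g_adv": [], "val_mi": []}

        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            d_losses, g_losses, mi_losses, adv_losses = [], [], [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                m_b, c_b = mri[idx], ct[idx]
                nb = len(idx)

                # --- discriminator update: real and fake are scored in one
                # concatenated batch so batch-norm statistics are shared
                # (separate batches would normalise away the global intensity
                # differences the discriminator must detect)
                fake = gen.forward(m_b, training=True)
                opt_d.zero_grad()
                z_all = _disc_forward_logits(
                    disc,
                    np.concatenate([self._pair(m_b, c_b), self._pair(m_b, fake)]),
                    training=True)
                d_all = _sigmoid(z_all)
                dr, df = d_all[:nb], d_all[nb:]
                # d(-log D(real))/dz = d - 1 ; d(-log(1 - D(fake)))/dz = d
                _disc_backward_logits(disc, np.concatenate([(dr - 1.0) / nb, df / nb]))
                drc = np.clip(dr, _CLAMP, 1 - _CLAMP)
                dfc = np.clip(df, _CLAMP, 1 - _CLAMP)
                d_losses.append(float(np.mean(-np.log(drc)) + np.mean(-np.log(1 - dfc))))
                opt_d.step()

                # --- generator update
                opt_g.zero_grad()
                fake = gen.forward(m_b, training=True)
                dfake = np.zeros_like(fake)
                mi_val = 0.0
                for i in range(nb):
                    li, gi = mi_loss_and_grad(c_b[i, 0], fake[i, 0], self.mi_cfg, mode=cfg.mi_mode)
                    mi_val += li / nb
                    dfake[i, 0] += cfg.mi_weight * gi / nb
                adv_val = 0.0
                if cfg.adversarial_weight > 0:
                    opt_d.zero_grad()  # discard D grads from the G pass
                    # eval-mode discriminator (running batch-norm statistics)
                    # so the generator gradient sees absolute intensity levels
                    z_fake = _disc_forward_logits(disc, self._pair(m_b, fake), training=False)
                    df = _sigmoid(z_fake)
                    adv_val = float(np.mean(-np.log(np.clip(df, _CLAMP, 1 - _CLAMP))))
                    # d(-log D(fake))/dz = d - 1, bounded in [-1, 0]
                    dpair = _disc_backward_logits(disc, (df - 1.0) / nb)
                    # gradient w.r.t. the candidate channel only (the MRI
                    # condition is an input, not an optimisation variable)
                    dadv = dpair[:, -1:] if self.disc_cfg.in_channels == 2 else dpair
                    dfake += cfg.adversarial_weight * dadv
                    opt_d.zero_grad()
                gen.backward(dfake)
                opt_g.step()
                g_total = cfg.mi_weight * mi_val + cfg.adversarial_weight * adv_val
                if not (math.isfinite(g_total) and math.isfinite(d_losses[-1])):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"g_loss={g_total}, d_loss={d_losses[-1]}")
                g_losses.append(g_total)
                mi_losses.append(mi_val)
                adv_losses.append(adv_val)

            history["d_loss"].append(float(np.mean(d_losses)))
            history["g_loss"].append(float(np.mean(g_losses)))
            history["g_mi"].append(float(np.mean(mi_losses)))
            history["g_adv"].append(float(np.mean(adv_losses)))
            if validation:
                history["val_mi"].append(self._validation_mi(gen, validation, cfg))

        return SynthesisResults(generator=gen, gen_cfg=self.gen_cfg, disc_cfg=self.disc_cfg,
                                mi_cfg=self.mi_cfg, train_cfg=cfg,
                                normalization_scale=scale, loss_history=history)

    def _validation_mi(self, gen: UNet, validation: list[PairedSample], cfg: TrainConfig) -> float:
        mri, ct, _ = _cohort_slices(validation)
        fake = gen.forward(mri, training=False)
        return float(np.mean([
            mi_training_loss(ct[i, 0], fake[i, 0], self.mi_cfg, mode=cfg.mi_mode)
            for i in range(len(mri))
        ]))


@dataclass
class SynthesisResults:
    """A fitted synthesis model: generator weights, configs and history."""

    generator: UNet
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    mi_cfg: MIConfig
    train_cfg: TrainConfig
    normalization_scale: float
    loss_history: dict[str, list[float]]

    def predict_sct(self, mri: ImageVolume) -> ImageVolume:
        """Synthesise a CT in HU from an MRI volume (per-slice inference)."""
        unit, _ = normalize(mri)
        x = np.asarray(unit, dtype=np.float64)[:, None]
        if x.shape[-2] % (2**self.gen_cfg.depth) or x.shape[-1] % (2**self.gen_cfg.depth):
            raise ValueError(
                f"slice shape {x.shape[-2:]} incompatible with U-Net depth {self.gen_cfg.depth}")
        out = self.generator.forward(x, training=False)[:, 0]
        hu = denormalize(out, self.normalization_scale, offset=HU_OFFSET)
        return ImageVolume(hu, mri.spacing)

    @property
    def final_losses(self) -> dict[str, float]:
        return {k: v[-1] for k, v in self.loss_history.items() if v}

    def summary(self) -> str:
        lines = [
            "MI-GAN synthesis results",
            "========================",
            f"epochs trained        : {len(self.loss_history['g_loss'])}",
            f"generator             : U-Net depth {self.gen_cfg.depth}, "
            f"base filters {self.gen_cfg.base_filters}, input {self.gen_cfg.input_size}",
            f"discriminator filters : {self.disc_cfg.conv_filter_sizes}",
            f"loss weights          : mi={self.train_cfg.mi_weight}, "
            f"adv={self.train_cfg.adversarial_weight} (mode={self.train_cfg.mi_mode})",
            f"normalization scale   : {self.normalization_scale:.1f} "
            f"(offset {HU_OFFSET:.0f} HU)",
        ]
        for k, v in self.final_losses.items():
            lines.append(f"final {k:<16}: {v:.4f}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Serialise weights (npz) plus a JSON sidecar with the configs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.v for i, p in enumerate(self.generator.params())}
        for i, bn in enumerate(self.generator.batchnorms()):
            arrays[f"bn{i}_mean"] = bn.running_mean
            arrays[f"bn{i}_var"] = bn.running_var
        np.savez(out / "generator.npz", **arrays)
        sidecar = {
            "gen_cfg": asdict(self.gen_cfg),
            "disc_cfg": asdict(self.disc_cfg),
            "mi_cfg": asdict(self.mi_cfg),
            "train_cfg": asdict(self.train_cfg),
            "normalization_scale": self.normalization_scale,
            "loss_history": self.loss_history,
        }
        (out / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, in_dir) -> "SynthesisResults":
        src = Path(in_dir)
        meta = json.loads((src / "model.json").read_text())
        gen_cfg = GeneratorConfig(**{**meta["gen_cfg"]})
        disc_cfg = DiscriminatorConfig(**{**meta["disc_cfg"],
                                          "conv_filter_sizes": tuple(meta["disc_cfg"]["conv_filter_sizes"])})
        mi_cfg = MIConfig(**{**meta["mi_cfg"],
                             "intensity_range": tuple(meta["mi_cfg"]["intensity_range"])})
        train_cfg = TrainConfig(**meta["train_cfg"])
        gen = build_generator(gen_cfg)
        weights = np.load(src / "generator.npz")
        for i, p in enumerate(gen.params()):
            p.v[...] = weights[f"p{i}"]
        for i, bn in enumerate(gen.batchnorms()):
            bn.running_mean = weights[f"bn{i}_mean"]
            bn.running_var = weights[f"bn{i}_var"]
        return cls(generator=gen, gen_cfg=gen_cfg, disc_cfg=disc_cfg, mi_cfg=mi_cfg,
                   train_cfg=train_cfg, normalization_scale=meta["normalization_scale"],
                   loss_history=meta["loss_history"])


def train(cohort: list[PairedSample], gen_cfg=None, disc_cfg=None,
          train_cfg: TrainConfig | None = None, mi_cfg=None,
          validation=None) -> SynthesisResults:
    """Functional wrapper: build the model and fit it."""
    return MISynthesisGAN(cohort, gen_cfg, disc_cfg, mi_cfg).fit(train_cfg, validation=validation)


def predict_sct(results: SynthesisResults, mri: ImageVolume) -> ImageVolume:
    """Functional wrapper around :meth:`SynthesisResults.predict_sct`."""
    return results.predict_sct(mri)


# ---------------------------------------------------------------------------
# cross-validation protocol


@dataclass
class CVSplit:
    """Index sets of a k-fold protocol with an isolated holdout set.

    The holdout (test) subjects are removed first; the remaining development
    subjects are split per fold into disjoint validation chunks with the
    rest used for training.
    """

    holdout: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) per fold

    @property
    def n_development(self) -> int:
        return len(self.folds[0][0]) + len(self.folds[0][1])


def crossval_split(n_subjects: int, k: int = 5, holdout_fraction: float = 0.15,
                   train_fraction: float = 0.70, seed: int = 0) -> CVSplit:
    """Seeded subject-level split: holdout first, then k train/validation folds.

    With the defaults and 77 subjects this gives 66 development + 11 holdout
    subjects and per-fold splits of 54 training / 12 validation.  Validation
    chunks are disjoint across folds.
    """
    n_holdout = int(np.floor(n_subjects * holdout_fraction))
    n_train = int(round(n_subjects * train_fraction))
    n_dev = n_subjects - n_holdout
    n_val = n_dev - n_train
    if n_val < 1 or n_train < 1:
        raise ValueError(
            f"cohort of {n_subjects} too small for holdout_fraction={holdout_fraction}, "
            f"train_fraction={train_fraction}")
    if k * n_val > n_dev:
        raise ValueError(
            f"cohort too small: {k} disjoint validation chunks of {n_val} subjects "
            f"need >= {k * n_val} development subjects, have {n_dev}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    holdout = np.sort(perm[:n_holdout])
    dev = perm[n_holdout:]
    folds = []
    for f in range(k):
        val = np.sort(dev[f * n_val:(f + 1) * n_val])
        trn = np.sort(np.setdiff1d(dev, val))
        folds.append((trn, val))
    return CVSplit(holdout=holdout, folds=folds)


@dataclass
class CVResults:
    split: CVSplit
    fold_results: list[SynthesisResults]
    fold_val_losses: list[float]
    selected_fold: int

    @property
    def selected(self) -> SynthesisResults:
        return self.fold_results[self.selected_fold]

    def summary(self) -> str:
        lines = ["Cross-validation summary", "========================"]
        for i, v in enumerate(self.fold_val_losses):
            star = " *" if i == self.selected_fold else ""
            lines.append(f"fold {i}: validation loss {v:.4f}{star}")
        lines.append(f"selected fold: {self.selected_fold} (lowest validation loss)")
        lines.append(f"holdout subjects: {len(self.split.holdout)}")
        return "\n".join(lines)


def crossvalidate(cohort: list[PairedSample], k: int = 5, holdout_fraction: float = 0.15,
                  train_fraction: float = 0.70, gen_cfg=None, disc_cfg=None,
                  train_cfg: TrainConfig | None = None, mi_cfg=None) -> CVResults:
    """k-fold training with holdout isolation; selects the fold model with the
    lowest validation loss."""
    cfg = train_cfg or TrainConfig()
    split = crossval_split(len(cohort), k, holdout_fraction, train_fraction, seed=cfg.seed)
    fold_results, fold_losses = [], []
    for f, (trn, val) in enumerate(split.folds):
        train_set = [cohort[i] for i in trn]
        val_set = [cohort[i] for i in val]
        res = MISynthesisGAN(train_set, gen_cfg, disc_cfg, mi_cfg).fit(cfg, validation=val_set)
        fold_results.append(res)
        fold_losses.append(res.loss_history["val_mi"][-1])
    selected = int(np.argmin(fold_losses))
    return CVResults(split=split, fold_results=fold_results,
                     fold_val_losses=fold_losses, selected_fold=selected)
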