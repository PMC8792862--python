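"""Manifest-level training: the published schedule around :class:`UShapedGAN`.

``train`` reads images per a dataset manifest, fits the estimator in the
requested mode, and writes ``losses.csv`` plus periodic checkpoints to the
output directory.  The full-scale protocol (500 epochs at 1,024² with a
ResNet-50 encoder, Adam at 0.001/0.0001 decayed x0.1 after epoch 200) is the
``full_scale`` preset; the desk preset trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as uio
from .model import UShapedGAN
from .types import DatasetManifest

__all__ = ["TrainConfig", "TrainState", "train", "load_pools"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the desk-scale preset; ``TrainConfig.full_scale()`` restores
    the published schedule (500 epochs, decay at 200, 1,024², ResNet-50
    encoder).
    """

    mode: str = "semi_supervised"
    epochs: int = 20
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_epoch: int | None = None
    batch_size: int = 8
    seed: int = 0
    resolution: int = 32
    encoder: str = "small-cnn"
    encoder_channels: tuple = (8, 16, 24, 32)
    decoder_channels: tuple = (32, 24, 16, 8)
    generator_channels: tuple | None = None
    skip_connections: bool = True
    pointwise_reduction: bool = True
    non_saturating: bool = False
    generator_enabled: bool = True
    checkpoint_every: int = 0

    def __post_init__(self):
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be > 0")
        if self.lr_decay_epoch is not None and self.lr_decay_epoch >= self.epochs:
            raise ValueError("lr_decay_epoch must be < epochs")

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        base = dict(epochs=500, lr_decay_epoch=200, resolution=1024,
                    encoder="resnet50-random", batch_size=16,
                    encoder_channels=(), decoder_channels=(256, 128, 64, 32, 16))
        base.update(overrides)
        return cls(**base)

    def estimator(self) -> UShapedGAN:
        return UShapedGAN(
            mode=self.mode, resolution=self.resolution, epochs=self.epochs,
            batch_size=self.batch_size, lr_generator=self.lr_generator,
            lr_discriminator=self.lr_discriminator,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_epoch=self.lr_decay_epoch, encoder=self.encoder,
            encoder_channels=tuple(self.encoder_channels),
            decoder_channels=tuple(self.decoder_channels),
            generator_channels=self.generator_channels,
            skip_connections=self.skip_connections,
            pointwise_reduction=self.pointwise_reduction,
            non_saturating=self.non_saturating,
            generator_enabled=self.generator_enabled,
            checkpoint_every=self.checkpoint_every,
            random_state=self.seed)


@dataclass
class TrainState:
    """What a finished (or checkpointed) run consists of."""

    estimator: UShapedGAN
    epoch: int
    loss_history: "object"  # pandas DataFrame
    out_dir: Path | None = None


def load_pools(manifest: DatasetManifest, mode: str):
    """Materialize (X, y) from a manifest for the given mode; unannotated
    and target-domain images get all ``-1`` label planes."""
    res = manifest.resolution
    if mode in ("supervised",):
        pools = {"labeled": manifest.pool("annotated", "source")}
    elif mode in ("semi_supervised", "original_gan"):
        pools = {"labeled": manifest.pool("annotated"),
                 "unlabeled": manifest.pool("unannotated")}
    elif mode == "uda":
        train_only = [e for e in manifest.entries if e.split in (None, "train")]
        pools = {"labeled": [e for e in train_only if e.pool == "source"],
                 "unlabeled": [e for e in train_only if e.pool == "target"]}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not pools.get("labeled"):
        raise ValueError(f"mode {mode!r} requires a nonempty annotated/source pool")
    X, y = [], []
    for e in pools["labeled"]:
        im = uio.load_radiograph(e.image, res)
        X.append(im.pixels)
        y.append(uio.load_mask(e.mask, res).astype(np.int64))
    for e in pools.get("unlabeled", []):
        im = uio.load_radiograph(e.image, res)
        X.append(im.pixels)
        y.append(-np.ones((res, res), dtype=np.int64))
    return np.stack(X), np.stack(y)


def train(config: TrainConfig, data: DatasetManifest,
          out_dir=None, resume_from=None) -> TrainState:
    """Run the alternating adversarial optimization on a manifest.

    Writes ``losses.csv`` (one row per epoch: losses and learning rates)
    and, if ``config.checkpoint_every`` is set, periodic self-describing
    checkpoints under ``out_dir``.
    """
    X, y = load_pools(data, config.mode)
    if resume_from is not None:
        est = UShapedGAN.load_checkpoint(resume_from)
    else:
        est = config.estimator()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        est.checkpoint_dir = str(out_dir)
    est.fit(X, y)
    if out_dir is not None:
        est.loss_history_.to_csv(out_dir / "losses.csv", index=False)
        est.save_checkpoint(out_dir / "final.npz", epoch=est.n_iter_)
    return TrainState(estimator=est, epoch=est.n_iter_,
                      loss_history=est.loss_history_, out_dir=out_dir)
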