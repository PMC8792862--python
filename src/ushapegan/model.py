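"""The U-shaped GAN segmenter as a scikit-learn style estimator.

``UShapedGAN`` holds a generator (noise → fake radiograph) and a U-shaped
discriminator (image → per-pixel lung/background/fake probabilities) and
trains them by alternating Adam steps: one discriminator update on the sum
of the supervised, unsupervised-real and fake losses, then one generator
update, per iteration.

The same machinery serves four modes:

* ``supervised``       — annotated images only; generator disabled.
* ``semi_supervised``  — annotated + unannotated images; full loss.
* ``uda``              — source images play the annotated role and target
  images the unannotated role; identical loss and schedule.
* ``original_gan``     — ablation arm: the decoder does plain 2-class
  segmentation and a whole-image classification head carries the classic
  real-vs-fake GAN objective.

``fit(X, y)`` follows the scikit-learn semi-supervised convention: ``X`` is
``(n, H, W)`` in [0, 1]; ``y`` is ``(n, H, W)`` with 0/1 masks, and an image
whose mask plane is all ``-1`` is unannotated (target-domain).  Fitted
attributes carry trailing underscores; the estimator round-trips through
``get_params``/``set_params`` and composes with scikit-learn model
selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import losses, nn
from .networks import (Discriminator, DiscriminatorSpec, Generator,
                       GeneratorSpec)

__all__ = ["UShapedGAN"]

MODES = ("supervised", "semi_supervised", "original_gan", "uda")


def _generator_spec(resolution: int, channels, noise_dim: int,
                    pointwise_reduction: bool) -> GeneratorSpec:
    if channels is not None:
        n_blocks = len(channels) - 1
        base = resolution // 4 ** n_blocks
    else:
        base, n_blocks = resolution, 0
        while base % 4 == 0 and base // 4 >= 2:
            base //= 4
            n_blocks += 1
        channels = tuple(min(64, 16 * 2 ** (n_blocks - i)) for i in range(n_blocks + 1))
    if base * 4 ** n_blocks != resolution or base < 1:
        raise ValueError(f"resolution {resolution} is not base * 4^k")
    return GeneratorSpec(noise_dim=noise_dim, base_resolution=base,
                         output_resolution=resolution,
                         channel_schedule=tuple(channels),
                         pointwise_reduction=pointwise_reduction)


class UShapedGAN(BaseEstimator):
    """Adversarial semi-supervised / domain-adaptive lung-field segmenter.

    Parameters mirror the published training protocol: Adam, generator and
    discriminator learning rates 0.001 and 0.0001, both multiplied by
    ``lr_decay_factor`` after ``lr_decay_epoch`` epochs (defaulting to 40%
    of the schedule, the published 200-of-500 proportion).
    """

    def __init__(self, mode="semi_supervised", resolution=32, epochs=12,
                 batch_size=8, lr_generator=1e-3, lr_discriminator=1e-4,
                 lr_decay_factor=0.1, lr_decay_epoch=None, noise_dim=100,
                 encoder="small-cnn", encoder_channels=(8, 16, 24, 32),
                 decoder_channels=(32, 24, 16, 8), generator_channels=None,
                 skip_connections=True, pointwise_reduction=True,
                 non_saturating=False, generator_enabled=True,
                 checkpoint_every=0, checkpoint_dir=None, random_state=0):
        self.mode = mode
        self.resolution = resolution
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_generator = lr_generator
        self.lr_discriminator = lr_discriminator
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_epoch = lr_decay_epoch
        self.noise_dim = noise_dim
        self.encoder = encoder
        self.encoder_channels = encoder_channels
        self.decoder_channels = decoder_channels
        self.generator_channels = generator_channels
        self.skip_connections = skip_connections
        self.pointwise_reduction = pointwise_reduction
        self.non_saturating = non_saturating
        self.generator_enabled = generator_enabled
        self.checkpoint_every = checkpoint_every
        self.checkpoint_dir = checkpoint_dir
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_config(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        decay = self.lr_decay_epoch
        if decay is None:
            decay = max(1, int(round(0.4 * self.epochs)))
        if decay >= self.epochs and self.epochs > 1:
            raise ValueError("lr_decay_epoch must be < epochs")
        return decay

    def _uses_generator(self) -> bool:
        return self.mode != "supervised" and self.generator_enabled

    def _build(self):
        dspec = DiscriminatorSpec(
            encoder=self.encoder,
            encoder_channels=tuple(self.encoder_channels),
            decoder_channel_schedule=tuple(self.decoder_channels),
            n_classes=2 if self.mode == "original_gan" else 3,
            skip_connections=self.skip_connections,
            image_head=(self.mode == "original_gan"),
        )
        self.discriminator_ = Discriminator(dspec, seed=self.random_state)
        self.generator_ = None
        if self._uses_generator():
            gspec = _generator_spec(self.resolution, self.generator_channels,
                                    self.noise_dim, self.pointwise_reduction)
            self.generator_ = Generator(gspec, seed=self.random_state + 1)

    # ------------------------------------------------------------------
    @staticmethod
    def _split_pools(X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_images, H, W)")
        if y is None:
            y = -np.ones(X.shape, dtype=np.int64)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must align with X (use all -1 planes for "
                             "unannotated images)")
        labeled = np.array([(plane >= 0).all() for plane in y])
        partially = np.array([((plane >= 0).any() and not (plane >= 0).all())
                              for plane in y])
        if partially.any():
            raise ValueError("an image must be fully annotated or fully "
                             "unannotated (-1 plane)")
        return X, y, np.flatnonzero(labeled), np.flatnonzero(~labeled)

    def fit(self, X, y=None):
        """Train on images ``X`` with per-pixel labels ``y`` (-1 planes mark
        unannotated images).  Returns self."""
        decay_epoch = self._validate_config()
        X, y, lab, unlab = self._split_pools(X, y)
        if len(lab) == 0:
            raise ValueError("at least one annotated image is required")
        if self.mode == "supervised" and len(unlab):
            unlab = np.array([], dtype=int)  # supervised mode ignores the pool
        resuming = getattr(self, "_resume_state", None)
        if resuming is None:
            self._build()
            self._rng = np.random.default_rng(self.random_state)
            self._history: list[dict] = []
            self._opt_d = nn.Adam(self.discriminator_.params(), self.lr_discriminator)
            self._opt_g = (nn.Adam(self.generator_.params(), self.lr_generator)
                           if self.generator_ is not None else None)
            start_epoch = 0
        else:
            start_epoch = resuming
            self._resume_state = None

        bs = min(self.batch_size, max(len(lab), len(unlab)))
        use_unlab = len(unlab) > 0 and self.mode != "supervised"
        driver = lab if len(lab) >= len(unlab) or not use_unlab else unlab
        n_iter = int(np.ceil(len(driver) / bs))

        for epoch in range(start_epoch, self.epochs):
            lr_scale = self.lr_decay_factor if (epoch + 1) > decay_epoch else 1.0
            self._opt_d.lr = self.lr_discriminator * lr_scale
            if self._opt_g is not None:
                self._opt_g.lr = self.lr_generator * lr_scale
            order = self._rng.permutation(len(driver))
            sums = {"L_l": 0.0, "L_u": 0.0, "L_g": 0.0, "L_D": 0.0, "L_G": 0.0}
            for it in range(n_iter):
                chunk = driver[order[it * bs:(it + 1) * bs]]
                nb = len(chunk)
                if driver is lab:
                    a_idx = chunk
                    u_idx = self._rng.choice(unlab, nb) if use_unlab else None
                else:
                    u_idx = chunk
                    a_idx = self._rng.choice(lab, nb)
                bundle = self._step(X, y, a_idx, u_idx)
                for k in sums:
                    sums[k] += getattr(bundle, k)
            row = {k: v / n_iter for k, v in sums.items()}
            row.update(epoch=epoch + 1, lr_discriminator=self._opt_d.lr,
                       lr_generator=self._opt_g.lr if self._opt_g else 0.0)
            self._history.append(row)
            if not np.isfinite(row["L_D"]):
                raise FloatingPointError(
                    f"non-finite discriminator loss at epoch {epoch + 1}: {row}")
            if (self.checkpoint_every and self.checkpoint_dir
                    and (epoch + 1) % self.checkpoint_every == 0):
                self.save_checkpoint(
                    Path(self.checkpoint_dir) / f"checkpoint_epoch{epoch + 1:04d}.npz",
                    epoch=epoch + 1)
        self.loss_history_ = pd.DataFrame(
            self._history,
            columns=["epoch", "L_l", "L_u", "L_g", "L_D", "L_G",
                     "lr_discriminator", "lr_generator"])
        self.n_iter_ = len(self._history)
        return self

    # ------------------------------------------------------------------
    def _step(self, X, y, a_idx, u_idx) -> losses.LossBundle:
        if self.mode == "original_gan":
            return self._step_original(X, y, a_idx, u_idx)
        D, G = self.discriminator_, self.generator_
        x_a, y_a = X[a_idx], y[a_idx]
        nb = len(a_idx)

        # --- discriminator update on L_D = L_l + L_u + L_g
        probs = D.forward(x_a)
        L_l, dprobs = losses.supervised_loss(probs, y_a, return_grad=True)
        D.backward(dprobs)
        L_u = 0.0
        if u_idx is not None and len(u_idx):
            probs = D.forward(X[u_idx])
            L_u, dprobs = losses.unsupervised_real_loss(probs, return_grad=True)
            D.backward(dprobs)
        L_g = 0.0
        x_f = None
        if G is not None:
            z = self._rng.standard_normal((nb, self.noise_dim))
            x_f = G.forward(z, train=False)
            probs = D.forward(x_f)
            L_g, dprobs = losses.fake_loss(probs, return_grad=True)
            D.backward(dprobs)
        self._opt_d.step()
        self._opt_d.zero_grad()

        # --- generator update on L_G
        L_G = 0.0
        if G is not None:
            z = self._rng.standard_normal((nb, self.noise_dim))
            x_f = G.forward(z)
            probs = D.forward(x_f)
            L_G, dprobs = losses.generator_loss(probs, return_grad=True,
                                                non_saturating=self.non_saturating)
            dx = D.backward(dprobs)
            G.backward(dx)
            self._opt_g.step()
            self._opt_g.zero_grad()
            self._opt_d.zero_grad()  # discard grads from the generator pass
        return losses.LossBundle(L_l=L_l, L_u=L_u, L_g=L_g, L_D=L_l + L_u + L_g,
                                 L_G=L_G,
                                 pixel_counts=(x_a.size,
                                               0 if u_idx is None else int(np.size(X[u_idx])),
                                               0 if x_f is None else x_f.size))

    def _step_original(self, X, y, a_idx, u_idx) -> losses.LossBundle:
        """Classic-GAN ablation: 2-class decoder + whole-image real/fake head."""
        D, G = self.discriminator_, self.generator_
        x_a, y_a = X[a_idx], y[a_idx]
        nb = len(a_idx)

        probs = D.forward(x_a)
        L_l, dprobs = losses.supervised_loss(probs, y_a, return_grad=True)
        L_real, dimg = losses.original_gan_loss(
            D.last_image_prob_, np.ones(nb), return_grad=True)
        D.backward(dprobs, dimage_prob=dimg)
        L_u = 0.0
        if u_idx is not None and len(u_idx):
            probs = D.forward(X[u_idx])
            L_u, dimg = losses.original_gan_loss(
                D.last_image_prob_, np.ones(len(u_idx)), return_grad=True)
            D.backward(np.zeros_like(probs), dimage_prob=dimg)
        L_fake = 0.0
        if G is not None:
            z = self._rng.standard_normal((nb, self.noise_dim))
            x_f = G.forward(z, train=False)
            probs = D.forward(x_f)
            L_fake, dimg = losses.original_gan_loss(
                D.last_image_prob_, np.zeros(nb), return_grad=True)
            D.backward(np.zeros_like(probs), dimage_prob=dimg)
        self._opt_d.step()
        self._opt_d.zero_grad()

        L_G = 0.0
        if G is not None:
            z = self._rng.standard_normal((nb, self.noise_dim))
            x_f = G.forward(z)
            probs = D.forward(x_f)
            # saturating classic-GAN form: G minimizes mean log(1 - D_real(G(z)))
            p = D.last_image_prob_
            L_G = float(np.log(np.maximum(1.0 - p, losses.SAFE_LOG_EPS)).mean())
            dimg = np.where(1.0 - p > losses.SAFE_LOG_EPS,
                            -1.0 / np.maximum(1.0 - p, losses.SAFE_LOG_EPS), 0.0) / p.size
            dx = D.backward(np.zeros_like(probs), dimage_prob=dimg)
            G.backward(dx)
            self._opt_g.step()
            self._opt_g.zero_grad()
            self._opt_d.zero_grad()
        L_adv = L_real + L_u + L_fake
        return losses.LossBundle(L_l=L_l, L_u=L_u + L_real, L_g=L_fake,
                                 L_D=L_l + L_adv, L_G=L_G,
                                 pixel_counts=(x_a.size, 0, 0))

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probability maps, (n, n_classes, H, W)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_images, H, W)")
        if X.shape[1] != self.resolution:
            raise ValueError(f"images are {X.shape[1]}px but the model was "
                             f"configured for {self.resolution}px")
        out = []
        bs = max(1, self.batch_size)
        for i in range(0, len(X), bs):
            out.append(self.discriminator_.forward(X[i:i + bs], train=False))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary lung masks: argmax over the two real classes, ignoring the
        fake channel; ties toward background."""
        probs = self.predict_proba(X)
        return (probs[:, losses.LUNG] > probs[:, losses.BACKGROUND]).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice against ground-truth masks."""
        from .evaluation import dice
        preds = self.predict(X)
        return float(np.mean([dice(p, t) for p, t in zip(preds, np.asarray(y))]))

    # ------------------------------------------------------------------
    def save_checkpoint(self, path, epoch: int | None = None) -> None:
        """Self-describing checkpoint: weights, Adam moments, RNG state,
        loss history and the full estimator configuration."""
        arrays = {}
        for i, p in enumerate(self.discriminator_.params()):
            arrays[f"d_{i}"] = p.value
        for i, (m, v) in enumerate(zip(self._opt_d.m, self._opt_d.v)):
            arrays[f"dm_{i}"], arrays[f"dv_{i}"] = m, v
        if self.generator_ is not None:
            for i, p in enumerate(self.generator_.params()):
                arrays[f"g_{i}"] = p.value
            for i, (m, v) in enumerate(zip(self._opt_g.m, self._opt_g.v)):
                arrays[f"gm_{i}"], arrays[f"gv_{i}"] = m, v
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "epoch": epoch if epoch is not None else len(self._history),
            "rng_state": self._rng.bit_generator.state,
            "opt_d": {"t": self._opt_d.t, "lr": self._opt_d.lr},
            "opt_g": ({"t": self._opt_g.t, "lr": self._opt_g.lr}
                      if self.generator_ is not None else None),
            "history": self._history,
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path) -> "UShapedGAN":
        """Rebuild an estimator mid-training; a subsequent ``fit`` resumes
        the remaining epochs and reproduces the uninterrupted trajectory."""
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in meta["params"].items()}
        est = cls(**params)
        est._build()
        for i, p in enumerate(est.discriminator_.params()):
            p.value[...] = data[f"d_{i}"]
        est._opt_d = nn.Adam(est.discriminator_.params(), meta["opt_d"]["lr"])
        est._opt_d.t = int(meta["opt_d"]["t"])
        est._opt_d.m = [np.array(data[f"dm_{i}"]) for i in range(len(est._opt_d.m))]
        est._opt_d.v = [np.array(data[f"dv_{i}"]) for i in range(len(est._opt_d.v))]
        est._opt_g = None
        if est.generator_ is not None:
            for i, p in enumerate(est.generator_.params()):
                p.value[...] = data[f"g_{i}"]
            est._opt_g = nn.Adam(est.generator_.params(), meta["opt_g"]["lr"])
            est._opt_g.t = int(meta["opt_g"]["t"])
            est._opt_g.m = [np.array(data[f"gm_{i}"]) for i in range(len(est._opt_g.m))]
            est._opt_g.v = [np.array(data[f"gv_{i}"]) for i in range(len(est._opt_g.v))]
        est._rng = np.random.default_rng()
        est._rng.bit_generator.state = meta["rng_state"]
        est._history = list(meta["history"])
        est._resume_state = int(meta["epoch"])
        return est
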