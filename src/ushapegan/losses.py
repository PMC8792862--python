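"""Pixel-level adversarial losses.

Probability maps are (n, 3, H, W) arrays over the channel order
(lung, background, fake); every pixel's three probabilities sum to 1.
There is no explicit "real" output: real-ness of a pixel is
``1 - P(fake)``, i.e. the probability mass on the two semantic classes.

The discriminator loss is the unweighted sum of three terms:

* ``L_l``  — annotated pixels: cross-entropy against the true semantic
  class, mean of ``-log D(y|x)``;
* ``L_u``  — unannotated (or target-domain) pixels: ``-log(1 - D(x)_fake)``;
* ``L_g``  — generated pixels: ``-log D(G(z))_fake``.

The generator minimizes ``L_G = +log D(G(z))_fake`` (the literal, saturating
form; a non-saturating ``-log(1 - D_fake)`` variant is available behind a
flag).  All expectations are flat arithmetic means over every pixel of the
batch.  Logarithms are clamped at ``SAFE_LOG_EPS`` so one-hot maps produced
by a hard-trained network never yield NaN or Inf.

Each loss optionally returns its exact gradient with respect to the
probability map, which the training loop feeds back through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SAFE_LOG_EPS = 1e-8

LUNG, BACKGROUND, FAKE = 0, 1, 2

__all__ = [
    "SAFE_LOG_EPS",
    "LUNG",
    "BACKGROUND",
    "FAKE",
    "LossBundle",
    "supervised_loss",
    "unsupervised_real_loss",
    "fake_loss",
    "generator_loss",
    "discriminator_loss",
    "original_gan_loss",
]


def _safe_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, SAFE_LOG_EPS))


def _inv_where_safe(p: np.ndarray) -> np.ndarray:
    """d/dp of safe_log: 1/p where p > eps, else 0 (the clamp is flat)."""
    return np.where(p > SAFE_LOG_EPS, 1.0 / np.maximum(p, SAFE_LOG_EPS), 0.0)


def _check_probs(probs: np.ndarray, channels=(3,)) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 4 or probs.shape[1] not in channels:
        raise ValueError(
            f"probability map must be (n, c, H, W) with c in {channels},"
            f" got {probs.shape}")
    return probs


@dataclass
class LossBundle:
    """Scalar losses for one batch, plus how many pixels fed each term."""

    L_l: float
    L_u: float
    L_g: float
    L_D: float
    L_G: float
    pixel_counts: tuple[int, int, int]  # annotated, unannotated, generated


def supervised_loss(probs: np.ndarray, masks: np.ndarray, return_grad: bool = False):
    """Mean ``-log D(y|x)`` over annotated pixels; y = lung where mask is 1,
    background where mask is 0.  Accepts 3-channel maps or the 2-channel
    (no fake output) maps of the classic-GAN ablation arm."""
    probs = _check_probs(probs, channels=(2, 3))
    masks = np.asarray(masks)
    if masks.shape != (probs.shape[0],) + probs.shape[2:]:
        raise ValueError(f"masks {masks.shape} do not align with probs {probs.shape}")
    if not np.isin(masks, (0, 1)).all():
        raise ValueError("masks must contain only 0 and 1")
    sel = np.where(masks.astype(bool), probs[:, LUNG], probs[:, BACKGROUND])
    value = float(-_safe_log(sel).mean())
    if not return_grad:
        return value
    n_pix = sel.size
    g = -_inv_where_safe(sel) / n_pix
    grad = np.zeros_like(probs)
    lung_sel = masks.astype(bool)
    grad[:, LUNG][lung_sel] = g[lung_sel]
    grad[:, BACKGROUND][~lung_sel] = g[~lung_sel]
    return value, grad


def unsupervised_real_loss(probs: np.ndarray, return_grad: bool = False):
    """Mean ``-log(1 - D(x)_fake)`` over unannotated real pixels."""
    probs = _check_probs(probs)
    p_real = 1.0 - probs[:, FAKE]
    value = float(-_safe_log(p_real).mean())
    if not return_grad:
        return value
    grad = np.zeros_like(probs)
    grad[:, FAKE] = _inv_where_safe(p_real) / p_real.size
    return value, grad


def fake_loss(probs: np.ndarray, return_grad: bool = False):
    """Mean ``-log D(G(z))_fake`` over generated pixels."""
    probs = _check_probs(probs)
    p_fake = probs[:, FAKE]
    value = float(-_safe_log(p_fake).mean())
    if not return_grad:
        return value
    grad = np.zeros_like(probs)
    grad[:, FAKE] = -_inv_where_safe(p_fake) / p_fake.size
    return value, grad


def generator_loss(probs: np.ndarray, return_grad: bool = False,
                   non_saturating: bool = False):
    """Generator objective on the discriminator's view of generated pixels.

    Default (literal, saturating) form: mean ``+log D_fake``, so minimizing
    drives the fake probability of generated pixels down.  With
    ``non_saturating=True`` the common ``-log(1 - D_fake)`` alternative is
    used (same fixed points, stronger early gradients).
    """
    probs = _check_probs(probs)
    p_fake = probs[:, FAKE]
    if non_saturating:
        p_real = 1.0 - p_fake
        value = float(-_safe_log(p_real).mean())
        if not return_grad:
            return value
        grad = np.zeros_like(probs)
        grad[:, FAKE] = _inv_where_safe(p_real) / p_real.size
        return value, grad
    value = float(_safe_log(p_fake).mean())
    if not return_grad:
        return value
    grad = np.zeros_like(probs)
    grad[:, FAKE] = _inv_where_safe(p_fake) / p_fake.size
    return value, grad


def discriminator_loss(annotated=None, unannotated=None, generated=None) -> LossBundle:
    """Total discriminator loss ``L_D = L_l + L_u + L_g``.

    Parameters are the three data streams; any may be ``None`` (contributing
    0), enabling pure-supervised and pure-UDA configurations, but not all
    three at once.

    annotated : (probs, masks) tuple | None
    unannotated : probs | None
    generated : probs | None
    """
    if annotated is None and unannotated is None and generated is None:
        raise ValueError("at least one of annotated/unannotated/generated is required")
    n_a = n_u = n_g = 0
    L_l = L_u = L_g = 0.0
    L_G = 0.0
    if annotated is not None:
        probs_a, masks_a = annotated
        L_l = supervised_loss(probs_a, masks_a)
        n_a = int(np.prod(np.asarray(probs_a).shape) // 3)
    if unannotated is not None:
        L_u = unsupervised_real_loss(unannotated)
        n_u = int(np.prod(np.asarray(unannotated).shape) // 3)
    if generated is not None:
        L_g = fake_loss(generated)
        L_G = generator_loss(generated)
        n_g = int(np.prod(np.asarray(generated).shape) // 3)
    return LossBundle(L_l=L_l, L_u=L_u, L_g=L_g, L_D=L_l + L_u + L_g,
                      L_G=L_G, pixel_counts=(n_a, n_u, n_g))


def original_gan_loss(image_level_real_prob: np.ndarray, is_real: np.ndarray,
                      return_grad: bool = False):
    """Image-level binary cross-entropy for the classic-GAN ablation arm,
    where a classification head discriminates whole real vs fake images."""
    p = np.asarray(image_level_real_prob, dtype=np.float64)
    t = np.asarray(is_real, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("probabilities and flags must align")
    value = float(-(t * _safe_log(p) + (1.0 - t) * _safe_log(1.0 - p)).mean())
    if not return_grad:
        return value
    grad = (-t * _inv_where_safe(p) + (1.0 - t) * _inv_where_safe(1.0 - p)) / p.size
    return value, grad
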