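"""Mask prediction and overlap metrics.

At inference the fake channel is a training device, not a semantic class,
so prediction is an argmax over the two real classes only (lung vs
background), with ties broken toward background.

Jaccard J = |A∩B| / |A∪B| and Dice D = 2|A∩B| / (|A|+|B|) over foreground
pixel sets; when both masks are empty the sets agree perfectly and both
metrics are 1.  The two are algebraically locked: D = 2J / (1 + J).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses import BACKGROUND, LUNG
from .types import Radiograph, validate_mask

__all__ = ["SegmentationResult", "predict_mask", "jaccard", "dice",
           "evaluate_images", "evaluate_manifest", "summarize"]


@dataclass
class SegmentationResult:
    image_id: str
    predicted: np.ndarray
    dice: float
    jaccard: float


def predict_mask(discriminator, image) -> np.ndarray:
    """Per-pixel argmax over the lung and background channels, ignoring the
    fake channel; ties go to background."""
    if isinstance(image, Radiograph):
        px = image.pixels
    else:
        px = np.asarray(image, dtype=np.float64)
    probs = discriminator(px[None], train=False)[0]
    return (probs[LUNG] > probs[BACKGROUND]).astype(np.uint8)


def _counts(pred, truth):
    pred = validate_mask(pred).astype(bool)
    truth = validate_mask(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = int((pred & truth).sum())
    return inter, int(pred.sum()), int(truth.sum())


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    inter, a, b = _counts(pred, truth)
    union = a + b - inter
    return 1.0 if union == 0 else inter / union


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter, a, b = _counts(pred, truth)
    return 1.0 if a + b == 0 else 2.0 * inter / (a + b)


def evaluate_images(discriminator, images: list[Radiograph]) -> pd.DataFrame:
    """Per-image Dice/Jaccard for radiographs that carry ground-truth masks.

    Images without a mask are listed with NaN metrics and a warning column
    rather than silently dropped.
    """
    rows = []
    for im in images:
        pred = predict_mask(discriminator, im)
        if im.mask is None:
            rows.append({"image_id": im.image_id, "dice": np.nan,
                         "jaccard": np.nan, "note": "missing mask; skipped"})
            continue
        rows.append({"image_id": im.image_id,
                     "dice": dice(pred, im.mask),
                     "jaccard": jaccard(pred, im.mask), "note": ""})
    return pd.DataFrame(rows, columns=["image_id", "dice", "jaccard", "note"])


def evaluate_manifest(discriminator, manifest, out_csv=None) -> pd.DataFrame:
    """Evaluate every manifest entry with a mask; metrics are computed per
    image and then averaged (mean ± sd rows appended)."""
    from . import io as iio_mod

    images = []
    for e in manifest.entries:
        im = iio_mod.load_radiograph(e.image, manifest.resolution)
        if e.mask:
            im.mask = iio_mod.load_mask(e.mask, manifest.resolution)
        images.append(im)
    df = evaluate_images(discriminator, images)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def summarize(df: pd.DataFrame) -> dict:
    d = df["dice"].dropna()
    j = df["jaccard"].dropna()
    return {"dice_mean": float(d.mean()), "dice_sd": float(d.std(ddof=0)),
            "jaccard_mean": float(j.mean()), "jaccard_sd": float(j.std(ddof=0)),
            "n": int(len(d))}
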