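"""Image, mask and manifest I/O, plus the split protocols.

Images are PNG/TIFF, 8- or 16-bit grayscale, normalized by the dtype
maximum to [0, 1] and resized (bilinear by default) to the square working
resolution.  Masks are 8-bit PNGs with 0 = background and 255 = lung; they
are thresholded at half the source maximum and resized nearest-neighbour so
no interpolated values ever appear.  A dataset manifest is a CSV with header
``image,mask,pool,fold`` (an empty mask field means unannotated; an optional
``split`` column carries train/val/test assignments) or an equivalent JSON
document.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .types import DatasetManifest, ManifestEntry, Radiograph, validate_mask

__all__ = [
    "load_radiograph", "load_mask", "save_image", "save_mask",
    "read_manifest", "write_manifest",
    "make_semisup_splits", "make_uda_splits",
]

_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def _read_gray(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = arr[..., 0] if arr.shape[2] == 1 else arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    return arr


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0  # float images are taken to be unit-interval already


def load_radiograph(path, target_resolution: int,
                    interpolation: str = "bilinear") -> Radiograph:
    """Read a grayscale image, normalize to [0, 1] by the dtype maximum and
    resize to ``target_resolution`` squared."""
    arr = _read_gray(path)
    px = arr.astype(np.float64) / _dtype_max(arr)
    px = np.clip(px, 0.0, 1.0)
    if px.shape != (target_resolution, target_resolution):
        px = resize(px, (target_resolution, target_resolution),
                    order=_INTERP_ORDER[interpolation], anti_aliasing=False,
                    preserve_range=True)
        px = np.clip(px, 0.0, 1.0)
    return Radiograph(image_id=Path(path).stem, pixels=px)


def load_mask(path, target_resolution: int) -> np.ndarray:
    """Read a binary mask: threshold at half the source maximum, then
    nearest-neighbour resize so values stay exactly {0, 1}."""
    arr = _read_gray(path)
    peak = arr.max()
    labels = (arr > peak / 2.0).astype(np.uint8) if peak > 0 else np.zeros_like(arr, np.uint8)
    if labels.shape != (target_resolution, target_resolution):
        labels = resize(labels, (target_resolution, target_resolution), order=0,
                        anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return validate_mask(labels)


def save_image(path, pixels: np.ndarray) -> None:
    """Write a unit-interval image as 8-bit grayscale PNG/TIFF."""
    px = np.asarray(pixels, dtype=np.float64)
    iio.imwrite(path, np.round(np.clip(px, 0, 1) * 255).astype(np.uint8))


def save_mask(path, labels: np.ndarray) -> None:
    """Write a {0,1} mask as 8-bit PNG with 0/255; round-trips losslessly."""
    labels = validate_mask(labels)
    iio.imwrite(path, (labels * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# manifests


def write_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    rows = [{"image": e.image, "mask": e.mask or "", "pool": e.pool,
             "fold": "" if e.fold is None else e.fold,
             "split": e.split or ""} for e in manifest.entries]
    if path.suffix == ".json":
        payload = {"resolution": manifest.resolution, "seed": manifest.seed,
                   "entries": rows}
        path.write_text(json.dumps(payload, indent=1))
        return
    df = pd.DataFrame(rows, columns=["image", "mask", "pool", "fold", "split"])
    if (df["split"] == "").all():
        df = df.drop(columns=["split"])
    df.to_csv(path, index=False)


def read_manifest(path, resolution: int | None = None, seed: int = 0) -> DatasetManifest:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        rows = payload["entries"]
        resolution = resolution or int(payload.get("resolution", 64))
        seed = int(payload.get("seed", seed))
    else:
        df = pd.read_csv(path, dtype={"image": str, "mask": str, "pool": str},
                         keep_default_na=False)
        rows = df.to_dict("records")
        resolution = resolution or 64
    entries = []
    for r in rows:
        fold = r.get("fold", "")
        fold = None if fold in ("", None) else int(float(fold))
        entries.append(ManifestEntry(
            image=r["image"], mask=(r.get("mask") or None), pool=r["pool"],
            fold=fold, split=(r.get("split") or None)))
    return DatasetManifest(entries, resolution=resolution, seed=seed)


# ---------------------------------------------------------------------------
# split protocols


def _apportion(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    quotas = [total * w / sum(weights) for w in weights]
    counts = [math.floor(q) for q in quotas]
    rem = total - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: quotas[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def make_semisup_splits(manifest: DatasetManifest, annotated_fraction: float,
                        k_folds: int, seed: int) -> DatasetManifest:
    """Assign cross-validation folds and annotated/unannotated pools.

    Every entry must carry a mask.  Folds are assigned uniformly at random
    under ``seed``.  The total annotated count is ``ceil(fraction * n)``,
    apportioned across folds in proportion to fold size, so each training
    portion (all folds but one) holds the expected share of annotated images
    — exactly ``ceil(fraction * n_train)`` whenever the per-fold share is
    integral.
    """
    n = len(manifest)
    if not (0.0 < annotated_fraction <= 1.0):
        raise ValueError("annotated_fraction must be in (0, 1]")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < k_folds:
        raise ValueError(f"{n} entries cannot fill {k_folds} folds")
    for e in manifest.entries:
        if not e.mask:
            raise ValueError(f"entry {e.image!r} has no mask; all entries must "
                             "be maskable to form the annotated subset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % k_folds
    fold_sizes = [int((fold_of == j).sum()) for j in range(k_folds)]
    total_annotated = math.ceil(annotated_fraction * n - 1e-12)
    per_fold = _apportion(total_annotated, [float(m) for m in fold_sizes])
    annotated = np.zeros(n, dtype=bool)
    for j in range(k_folds):
        members = np.flatnonzero(fold_of == j)
        chosen = rng.choice(members, size=per_fold[j], replace=False)
        annotated[chosen] = True
    entries = []
    for i, e in enumerate(manifest.entries):
        pool = "annotated" if annotated[i] else "unannotated"
        # mask paths stay on unannotated entries for evaluation; training
        # never consumes them
        entries.append(ManifestEntry(image=e.image, mask=e.mask, pool=pool,
                                     fold=int(fold_of[i])))
    return DatasetManifest(entries, resolution=manifest.resolution, seed=seed)


def make_uda_splits(source: DatasetManifest, target: DatasetManifest,
                    ratios: tuple = (0.7, 0.1, 0.2), seed: int = 0) -> DatasetManifest:
    """Split each domain into train/val/test by ``ratios`` (default 7:1:2).

    The training pool is source (annotated) plus target (unannotated);
    target mask paths stay in the manifest for evaluation only.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both domains must be nonempty")
    if min(ratios) <= 0:
        raise ValueError("all split ratios must be > 0")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    for e in source.entries:
        if not e.mask:
            raise ValueError(f"source entry {e.image!r} has no mask")
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    for dom, pool in ((source, "source"), (target, "target")):
        n = len(dom)
        counts = _apportion(n, list(ratios))
        labels = np.repeat(["train", "val", "test"], counts)
        labels = labels[rng.permutation(n)]
        for e, sp in zip(dom.entries, labels):
            entries.append(ManifestEntry(image=e.image, mask=e.mask, pool=pool,
                                         split=str(sp)))
    return DatasetManifest(entries, resolution=source.resolution, seed=seed)
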