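"""Core value types: radiographs, pixel masks, dataset manifests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Radiograph", "validate_mask", "ManifestEntry", "DatasetManifest",
           "POOLS"]

POOLS = ("annotated", "unannotated", "source", "target")


def validate_mask(labels: np.ndarray) -> np.ndarray:
    """A pixel mask is a 2-D array over {0 = background, 1 = lung}."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {labels.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return labels.astype(np.uint8)


@dataclass
class Radiograph:
    """One grayscale image with unit-interval intensities and an optional
    ground-truth lung mask of identical shape."""

    image_id: str
    pixels: np.ndarray
    mask: np.ndarray | None = None
    domain_tag: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("zero-sized image")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.mask is not None:
            self.mask = validate_mask(self.mask)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}")

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ManifestEntry:
    image: str
    mask: str | None = None
    pool: str = "annotated"
    fold: int | None = None
    split: str | None = None  # train / val / test (domain-adaptation runs)

    def __post_init__(self):
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}, got {self.pool!r}")
        if self.pool in ("annotated", "source") and not self.mask:
            raise ValueError(f"{self.pool!r} entry {self.image!r} needs a mask path")


@dataclass
class DatasetManifest:
    """Partition of images into annotated/unannotated (or source/target)
    pools, with optional cross-validation folds or train/val/test splits."""

    entries: list[ManifestEntry] = field(default_factory=list)
    resolution: int = 64
    seed: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def pool(self, *pools: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.pool in pools]

    def subset(self, predicate) -> "DatasetManifest":
        return DatasetManifest([e for e in self.entries if predicate(e)],
                               resolution=self.resolution, seed=self.seed)

    def folds(self) -> list[int]:
        return sorted({e.fold for e in self.entries if e.fold is not None})
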