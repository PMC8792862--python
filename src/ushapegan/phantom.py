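"""Synthetic chest-radiograph-like phantoms with exact ground-truth masks.

A phantom is a square grayscale image containing two non-overlapping dark
elliptical "lung fields" (lungs are radiolucent, so darker than the
surrounding tissue) on a brighter background crossed by a horizontal
sinusoidal "rib" texture, plus i.i.d. Gaussian noise, clipped to [0, 1].
The mask is exact: 1 precisely inside the two rasterized ellipses.

A second, intensity-shifted domain for domain-adaptation experiments is
produced by :func:`apply_domain_shift`: gamma curve, contrast scale, a
smooth random bias field, and extra noise.  The shift is intensity-only so
the ground-truth mask carries over unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .types import Radiograph

__all__ = ["PhantomConfig", "DomainShift", "generate_phantoms", "apply_domain_shift"]


@dataclass
class PhantomConfig:
    """Study conditions for the phantom generator.

    lung_area_fraction_range bounds the *total* (both lungs) mask area as a
    fraction of the image; lung_eccentricity_range bounds the ratio of the
    vertical to the horizontal semi-axis of each ellipse (real lung fields
    are taller than wide); rib_frequency is in cycles per image height and
    rib_amplitude in intensity units.
    """

    resolution: int = 64
    n_images: int = 200
    lung_eccentricity_range: tuple = (1.4, 2.2)
    lung_area_fraction_range: tuple = (0.15, 0.30)
    rib_frequency: float = 6.0
    rib_amplitude: float = 0.08
    noise_sd: float = 0.08
    background_level: float = 0.65
    lung_level: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 32:
            raise ValueError("resolution must be >= 32")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not self.lung_level < self.background_level:
            raise ValueError("lung_level must be below background_level "
                             "(lung fields are radiolucent)")
        if not (0.0 <= self.rib_amplitude < 1.0):
            raise ValueError("rib_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DomainShift:
    """Intensity-only appearance shift between acquisition sites.

    The identity shift (gamma=1, contrast_scale=1, bias_field_amplitude=0,
    noise_sd_delta=0) maps any image to itself exactly.
    bias_field_smoothness is the Gaussian correlation length of the bias
    field as a fraction of the image side.
    """

    gamma: float = 1.0
    contrast_scale: float = 1.0
    bias_field_amplitude: float = 0.0
    bias_field_smoothness: float = 0.25
    noise_sd_delta: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0 or self.contrast_scale <= 0:
            raise ValueError("gamma and contrast_scale must be > 0")
        if not (0.0 <= self.bias_field_amplitude < 1.0):
            raise ValueError("bias_field_amplitude must be in [0, 1)")
        if self.bias_field_smoothness <= 0:
            raise ValueError("bias_field_smoothness must be > 0")

    @property
    def is_identity(self) -> bool:
        return (self.gamma == 1.0 and self.contrast_scale == 1.0
                and self.bias_field_amplitude == 0.0 and self.noise_sd_delta == 0.0)


class PhantomGenerationError(RuntimeError):
    pass


def _ellipse_mask(res: int, cy: float, cx: float, a: float, b: float) -> np.ndarray:
    """Pixels whose centers fall inside the ellipse ((y-cy)/a)^2+((x-cx)/b)^2 < 1."""
    yy, xx = np.mgrid[0:res, 0:res]
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 < 1.0


def _sample_lungs(rng: np.random.Generator, cfg: PhantomConfig):
    """Two non-overlapping ellipses; rejection-sample geometry, 100 tries."""
    res = cfg.resolution
    for _ in range(100):
        frac = rng.uniform(*cfg.lung_area_fraction_range)
        masks = []
        ok = True
        for side, x_center in ((0, 0.30), (1, 0.70)):
            ecc = rng.uniform(*cfg.lung_eccentricity_range)
            area = frac / 2.0 * res * res  # pixels per lung: pi*a*b
            b = np.sqrt(area / (np.pi * ecc))
            a = ecc * b
            cy = res * (0.5 + rng.uniform(-0.06, 0.06))
            cx = res * (x_center + rng.uniform(-0.04, 0.04))
            if cy - a < 1 or cy + a > res - 1 or cx - b < 1 or cx + b > res - 1:
                ok = False
                break
            masks.append(_ellipse_mask(res, cy, cx, a, b))
        if ok and not (masks[0] & masks[1]).any():
            return masks[0] | masks[1]
    raise PhantomGenerationError(f"could not place two non-overlapping lungs: {cfg}")


def generate_phantoms(config: PhantomConfig) -> list[Radiograph]:
    """Generate ``config.n_images`` phantoms, bitwise reproducible from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    res = config.resolution
    out = []
    for i in range(config.n_images):
        mask = _sample_lungs(rng, config)
        img = np.full((res, res), config.background_level)
        if config.rib_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            y = np.arange(res) / res
            ribs = config.rib_amplitude * np.sin(
                2 * np.pi * config.rib_frequency * y + phase)
            img += ribs[:, None]
        img[mask] = config.lung_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        out.append(Radiograph(image_id=f"phantom_{config.seed}_{i:04d}",
                              pixels=img, mask=mask.astype(np.uint8)))
    return out


def _bias_field(rng: np.random.Generator, res: int, smoothness: float,
                amplitude: float) -> np.ndarray:
    """Smooth random surface, normalized to max |.| = amplitude."""
    field = rng.normal(size=(res, res))
    field = ndimage.gaussian_filter(field, sigma=smoothness * res, mode="reflect")
    peak = np.abs(field).max()
    if peak == 0:
        return np.zeros((res, res))
    return amplitude * field / peak


def apply_domain_shift(image: Radiograph, shift: DomainShift, seed: int = 0) -> Radiograph:
    """clip(contrast_scale * image**gamma + bias_field + noise, 0, 1); the
    mask is domain-invariant and carried over unchanged."""
    px = image.pixels
    if px.min() < 0 or px.max() > 1:
        raise ValueError("image intensities must be in [0, 1]")
    if shift.is_identity:
        return replace(image, domain_tag="target")
    rng = np.random.default_rng(seed)
    out = px if shift.gamma == 1.0 else np.power(px, shift.gamma)
    if shift.contrast_scale != 1.0:
        out = shift.contrast_scale * out
    if shift.bias_field_amplitude > 0:
        out = out + _bias_field(rng, px.shape[0], shift.bias_field_smoothness,
                                shift.bias_field_amplitude)
    if shift.noise_sd_delta != 0:
        out = out + rng.normal(0.0, abs(shift.noise_sd_delta), size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    return replace(image, pixels=out, domain_tag="target")
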