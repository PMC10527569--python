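"""Hybrid contrast enhancement for low-contrast dermoscopy images.

The enhancement runs in two stages.  First a dark-channel-prior dehazing
step removes the global veiling glare that makes lesions look washed out:
the observed image is modelled as ``I = J*T + A*(1 - T)`` where ``J`` is the
scene radiance, ``A`` the atmospheric (veiling) light and ``T`` the
per-pixel transmission.  Second, per-channel top-hat and bottom-hat
morphological transforms sharpen small-scale bright and dark structure:
``F = clip(J + tophat(J) - bothat(J))``.

All images are ``H x W x 3`` float arrays with intensities in ``[0, 1]``;
8-bit conversion happens only at file boundaries (:func:`read_image` /
:func:`write_image`).
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk


__all__ = [
    "HazeParams",
    "MorphParams",
    "validate_image",
    "read_image",
    "write_image",
    "dark_channel",
    "estimate_atmospheric_light",
    "estimate_transmission",
    "recover_radiance",
    "top_hat",
    "bottom_hat",
    "enhance_image",
]


@dataclass(frozen=True)
class HazeParams:
    """Parameters of the dark-channel dehazing stage.

    patch_size
        Odd side length (pixels) of the minimum-filter window used for the
        dark channel.
    omega
        Haze retention weight in ``(0, 1]``; 1 removes all estimated haze.
    t0
        Transmission floor in ``(0, 1)`` guarding the division in the
        radiance recovery.
    light_fraction
        Fraction of the brightest dark-channel pixels averaged to estimate
        the atmospheric light.
    """

    patch_size: int = 15
    omega: float = 0.95
    t0: float = 0.1
    light_fraction: float = 0.001

    def __post_init__(self) -> None:
        _check_patch_size(self.patch_size)
        if not 0.0 < self.omega <= 1.0:
            raise ValueError(f"omega must be in (0, 1], got {self.omega}")
        if not 0.0 < self.t0 < 1.0:
            raise ValueError(f"t0 must be in (0, 1), got {self.t0}")


@dataclass(frozen=True)
class MorphParams:
    """Structuring element of the top-hat / bottom-hat stage."""

    se_shape: str = "disk"
    se_radius: int = 9

    def __post_init__(self) -> None:
        if self.se_shape not in ("disk", "square"):
            raise ValueError(f"se_shape must be 'disk' or 'square', got {self.se_shape!r}")
        if self.se_radius < 1:
            raise ValueError(f"se_radius must be >= 1, got {self.se_radius}")

    def footprint(self) -> np.ndarray:
        if self.se_shape == "disk":
            return disk(self.se_radius)
        side = 2 * self.se_radius + 1
        return np.ones((side, side), dtype=bool)


def _check_patch_size(patch_size: int) -> None:
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd and >= 1, got {patch_size}")


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid float RGB image in [0, 1] and return it."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG file into a float RGB image in [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[..., :3]
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    return validate_image(raw)


def write_image(path, img: np.ndarray) -> None:
    """Write a float RGB image in [0, 1] to an 8-bit PNG/JPEG file."""
    img = validate_image(img)
    iio.imwrite(path, (np.clip(img, 0, 1) * 255.0 + 0.5).astype(np.uint8))


def dark_channel(img: np.ndarray, patch_size: int = 15) -> np.ndarray:
    """Dark channel: local minimum over channels and a square neighborhood.

    Edge pixels use replicate padding.  On a haze-free image with colorful
    or shadowed content the dark channel is near zero; haze lifts it toward
    the atmospheric light.
    """
    _check_patch_size(patch_size)
    img = validate_image(img)
    per_pixel_min = img.min(axis=2)
    return ndi.minimum_filter(per_pixel_min, size=patch_size, mode="nearest")


def estimate_atmospheric_light(
    img: np.ndarray,
    dark: np.ndarray,
    light_fraction: float = 0.001,
    floor: float = 1e-3,
) -> np.ndarray:
    """Estimate the veiling light A from the haziest (brightest-dark-channel) pixels.

    A is the per-channel mean of the image pixels whose dark-channel value
    falls in the top ``light_fraction`` quantile, floored at ``floor`` to
    keep later divisions safe.  An empty selection falls back to the global
    per-channel maximum.
    """
    img = validate_image(img)
    flat_dark = np.asarray(dark, dtype=np.float64).ravel()
    n_pixels = flat_dark.size
    n_top = int(np.ceil(light_fraction * n_pixels))
    if n_top < 1:
        a = img.reshape(-1, 3).max(axis=0)
    else:
        idx = np.argpartition(flat_dark, n_pixels - n_top)[n_pixels - n_top:]
        a = img.reshape(-1, 3)[idx].mean(axis=0)
    return np.clip(a, floor, 1.0)


def estimate_transmission(
    img: np.ndarray, a: np.ndarray, params: HazeParams = HazeParams()
) -> np.ndarray:
    """Transmission map ``T = 1 - omega * dark_channel(I / A)``, clipped to [t0, 1]."""
    img = validate_image(img)
    a = np.asarray(a, dtype=np.float64)
    if np.any(a <= 0):
        raise ValueError("atmospheric light must be strictly positive")
    ratio_min = (img / a[None, None, :]).min(axis=2)
    dark = ndi.minimum_filter(ratio_min, size=params.patch_size, mode="nearest")
    t = 1.0 - params.omega * dark
    return np.clip(t, params.t0, 1.0)


def recover_radiance(
    img: np.ndarray,
    a: np.ndarray,
    t: np.ndarray,
    t0: float = 0.1,
    clip: bool = True,
) -> np.ndarray:
    """Invert the haze model: ``J = (I - A) / max(T, t0) + A``.

    With the true A and T this is the exact algebraic inverse of
    ``I = J*T + A*(1-T)`` wherever ``T >= t0``.  Set ``clip=False`` to skip
    the final [0, 1] clamp (useful when checking the inverse identity).
    """
    img = validate_image(img)
    a = np.asarray(a, dtype=np.float64)
    divisor = np.maximum(np.asarray(t, dtype=np.float64), t0)
    j = (img - a[None, None, :]) / divisor[..., None] + a[None, None, :]
    return np.clip(j, 0.0, 1.0) if clip else j


def top_hat(img: np.ndarray, morph: MorphParams = MorphParams()) -> np.ndarray:
    """White top-hat per channel: image minus its grayscale opening (>= 0)."""
    img = validate_image(img)
    fp = morph.footprint()
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = img[..., c] - ndi.grey_opening(img[..., c], footprint=fp, mode="nearest")
    return out


def bottom_hat(img: np.ndarray, morph: MorphParams = MorphParams()) -> np.ndarray:
    """Black bottom-hat per channel: grayscale closing minus the image (>= 0)."""
    img = validate_image(img)
    fp = morph.footprint()
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndi.grey_closing(img[..., c], footprint=fp, mode="nearest") - img[..., c]
    return out


def default_morph_params(shape: tuple[int, ...]) -> MorphParams:
    """Disk radius 9 at 256 px, scaled proportionally to the short image side."""
    radius = max(1, round(9 * min(shape[0], shape[1]) / 256))
    return MorphParams(se_shape="disk", se_radius=radius)


def enhance_image(
    img: np.ndarray,
    haze: HazeParams = HazeParams(),
    morph: MorphParams | None = None,
) -> np.ndarray:
    """Full hybrid enhancement: dehaze, then add top-hat and subtract bottom-hat.

    Haze reduction runs first (it restores the global dynamic range), then
    the morphological stage boosts local contrast.  Output is clipped to
    [0, 1] and has the input's shape.  The whole chain is deterministic.
    """
    img = validate_image(img)
    if morph is None:
        morph = default_morph_params(img.shape)
    dark = dark_channel(img, haze.patch_size)
    a = estimate_atmospheric_light(img, dark, haze.light_fraction)
    t = estimate_transmission(img, a, haze)
    j = recover_radiance(img, a, t, haze.t0)
    f = j + top_hat(j, morph) - bottom_hat(j, morph)
    return np.clip(f, 0.0, 1.0)
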