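"""Slice preprocessing and training-time augmentation.

Preprocessing clips intensities to a configurable window (the CT analogue
of contrast windowing), standardizes to zero mean / unit variance, then
affinely rescales so the slice occupies exactly [0, 1].  Augmentation
produces the right-angle rotations of an (image, mask) pair; it is applied
to training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["PreprocessConfig", "normalize_slice", "augment", "crop_body"]

_ALLOWED_ROTATIONS = {90, 180, 270}


@dataclass(frozen=True)
class PreprocessConfig:
    """window_low/window_high clip intensities before normalization;
    rotations are right-angle training augmentations."""

    window_low: float = -np.inf
    window_high: float = np.inf
    rotations: tuple[int, ...] = (90, 180, 270)
    crop_mode: str = "none"

    def validate(self) -> None:
        if not self.window_low < self.window_high:
            raise ConfigError("window_low must be < window_high")
        if not set(self.rotations) <= _ALLOWED_ROTATIONS:
            raise ConfigError(f"rotations must be a subset of {_ALLOWED_ROTATIONS}")
        if self.crop_mode not in ("none", "body_bbox"):
            raise ConfigError("crop_mode must be 'none' or 'body_bbox'")


def normalize_slice(slice_: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Window-clip, z-score, then min-max rescale a slice into [0, 1].

    A constant slice has no contrast to normalize and maps to all zeros.
    For any non-constant input the output min is exactly 0 and max exactly 1.
    """
    config = config or PreprocessConfig()
    config.validate()
    arr = np.asarray(slice_, dtype=np.float64)
    if arr.size == 0:
        raise ConfigError("cannot normalize an empty slice")
    if not np.all(np.isfinite(arr)):
        raise ConfigError("slice contains non-finite values")
    arr = np.clip(arr, config.window_low, config.window_high)
    if arr.max() == arr.min():  # constant slice: no contrast to normalize
        return np.zeros_like(arr)
    z = (arr - arr.mean()) / arr.std()
    return (z - z.min()) / (z.max() - z.min())


def augment(image: np.ndarray, mask: np.ndarray,
            config: PreprocessConfig | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return the original pair plus one pair per configured rotation.

    Image and mask are rotated identically, so per-pair alignment (and the
    liver pixel count) is preserved in every copy.
    """
    config = config or PreprocessConfig()
    config.validate()
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ConfigError(f"image shape {image.shape} != mask shape {mask.shape}")
    pairs = [(image, mask)]
    for degrees in config.rotations:
        k = degrees // 90
        pairs.append((np.rot90(image, k), np.rot90(mask, k)))
    return pairs


def crop_body(image: np.ndarray, mask: np.ndarray,
              margin: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Crop both arrays to the above-background bounding box.

    The box is the union of non-background image content and the full liver
    mask, expanded by ``margin`` pixels where available, so the liver is
    never truncated.  An all-background image is returned unchanged.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ConfigError(f"image shape {image.shape} != mask shape {mask.shape}")
    background = np.min(image)
    content = (image > background) | (mask > 0)
    if not np.any(content):
        return image, mask
    rows = np.any(content, axis=1)
    cols = np.any(content, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    r0 = max(0, r0 - margin)
    c0 = max(0, c0 - margin)
    r1 = min(image.shape[0], r1 + margin)
    c1 = min(image.shape[1], c1 + margin)
    return image[r0:r1, c0:c1], mask[r0:r1, c0:c1]
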