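"""Dense patch-wise inference: per-pixel liver probability maps,
thresholding, and median post-smoothing.

Every lattice centre on a slice is classified through a 32x32 patch
(reflection-padded at borders); the softmax liver probability is written to
that pixel.  With stride > 1 the remaining pixels take the value of their
nearest lattice centre — an explicit speed concession recorded in the
provenance.  The binary mask is then smoothed with a window x window median
filter (majority vote over the binary neighbourhood, integer-exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .patches import cut_patches, inference_grid
from .phantom import ImageVolume
from .preprocess import PreprocessConfig, normalize_slice

__all__ = [
    "ProbabilityMap",
    "SegmentationMask",
    "SegmentConfig",
    "probability_map",
    "binarize",
    "median_smooth",
    "largest_component",
    "segment_volume",
]


@dataclass
class ProbabilityMap:
    """Per-pixel liver probabilities for one slice, aligned to its grid."""

    values: np.ndarray
    source_id: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError("probability map must be 2D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise DataError("probabilities must lie in [0, 1]")


@dataclass
class SegmentationMask:
    """Binary liver mask plus the provenance that produced it."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.all(np.isin(np.unique(self.values), (0, 1))):
            raise DataError("segmentation mask must be binary")


@dataclass(frozen=True)
class SegmentConfig:
    threshold: float = 0.5
    stride: int = 1
    smooth_window: int = 5
    strict_normalization: bool = False
    keep_largest_component: bool = False  # optional extra post-processing

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0, 1)")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")


def probability_map(model, slice_: np.ndarray, stride: int = 1,
                    source_id: int = 0, batch_size: int = 128,
                    strict: bool = False) -> ProbabilityMap:
    """Classify every lattice centre of a normalized slice -> ProbabilityMap.

    ``model`` is anything exposing ``forward(batch) -> (N, 2)`` class
    probabilities (column 1 = liver).  Input outside [0, 1] beyond a small
    tolerance is clipped with a warning, or rejected when ``strict``.
    """
    slice_ = np.asarray(slice_, dtype=np.float32)
    if slice_.ndim != 2:
        raise DataError("probability_map expects a 2D slice")
    if slice_.min() < -1e-6 or slice_.max() > 1 + 1e-6:
        if strict:
            raise DataError("slice is not normalized to [0, 1]")
        warnings.warn("slice values outside [0, 1]; clipping", stacklevel=2)
        slice_ = np.clip(slice_, 0.0, 1.0)

    h, w = slice_.shape
    centers = inference_grid((h, w), stride)
    liver_p = np.empty(len(centers), dtype=np.float64)
    for start in range(0, len(centers), batch_size):
        batch_centers = centers[start:start + batch_size]
        probs = model.forward(cut_patches(slice_, batch_centers))
        liver_p[start:start + len(batch_centers)] = np.clip(probs[:, 1], 0.0, 1.0)

    n_rows = -(-h // stride)
    n_cols = -(-w // stride)
    lattice = liver_p.reshape(n_rows, n_cols)
    if stride == 1:
        values = lattice
    else:
        # nearest-centre fill between lattice points
        offset = stride // 2
        idx_r = np.clip(np.rint((np.arange(h) - offset) / stride), 0, n_rows - 1).astype(int)
        idx_c = np.clip(np.rint((np.arange(w) - offset) / stride), 0, n_cols - 1).astype(int)
        values = lattice[np.ix_(idx_r, idx_c)]
    return ProbabilityMap(values=values, source_id=source_id, stride=stride)


def binarize(pmap: ProbabilityMap, threshold: float = 0.5,
             provenance: dict | None = None) -> SegmentationMask:
    """Threshold a probability map; ties (value == threshold) map to liver."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must lie strictly inside (0, 1)")
    values = (pmap.values >= threshold).astype(np.uint8)
    prov = dict(provenance or {})
    prov.update(threshold=threshold, stride=pmap.stride, source_id=pmap.source_id)
    return SegmentationMask(values=values, provenance=prov)


def median_smooth(mask: SegmentationMask, window: int = 5) -> SegmentationMask:
    """Median filter of a binary mask = majority vote in each window.

    Implemented as an integer box count compared against half the window
    area, with mirror-reflected borders; window must be odd (1 = identity).
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("median window must be odd and >= 1")
    if window == 1:
        return SegmentationMask(mask.values.copy(), dict(mask.provenance))
    counts = ndimage.correlate(
        mask.values.astype(np.int64),
        np.ones((window, window), dtype=np.int64),
        mode="mirror",
    )
    majority = (window * window + 1) // 2
    smoothed = (counts >= majority).astype(np.uint8)
    prov = dict(mask.provenance)
    prov["median_window"] = window
    return SegmentationMask(values=smoothed, provenance=prov)


def largest_component(mask: SegmentationMask) -> SegmentationMask:
    """Keep only the largest connected foreground component (optional extra
    post-processing, off by default in the pipeline)."""
    labeled, n = ndimage.label(mask.values)
    if n <= 1:
        return SegmentationMask(mask.values.copy(), dict(mask.provenance))
    sizes = ndimage.sum_labels(np.ones_like(mask.values), labeled,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    prov = dict(mask.provenance)
    prov["largest_component"] = True
    return SegmentationMask((labeled == keep).astype(np.uint8), prov)


def segment_volume(model, volume: ImageVolume,
                   config: SegmentConfig | None = None,
                   preprocess_config: PreprocessConfig | None = None,
                   model_id: str = "") -> tuple[np.ndarray, dict]:
    """normalize -> probability_map -> binarize -> median_smooth, per slice.

    Returns the stacked binary mask (same shape as the input intensities)
    and a provenance dictionary.
    """
    config = config or SegmentConfig()
    config.validate()
    preprocess_config = preprocess_config or PreprocessConfig()
    masks = np.zeros_like(np.asarray(volume.intensities), dtype=np.uint8)
    for index, image2d, _ in volume.iter_slices():
        try:
            normalized = normalize_slice(image2d, preprocess_config)
            pmap = probability_map(model, normalized, stride=config.stride,
                                   source_id=index,
                                   strict=config.strict_normalization)
            mask = binarize(pmap, config.threshold)
            mask = median_smooth(mask, config.smooth_window)
            if config.keep_largest_component:
                mask = largest_component(mask)
        except Exception as exc:
            raise type(exc)(f"slice {index}: {exc}") from exc
        if masks.ndim == 2:
            masks[:] = mask.values
        else:
            masks[index] = mask.values
    provenance = {
        "model": model_id,
        "threshold": config.threshold,
        "stride": config.stride,
        "median_window": config.smooth_window,
        "n_slices": volume.n_slices,
    }
    return masks, provenance
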