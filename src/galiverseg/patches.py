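"""Patch extraction: balanced labeled training patches and inference lattices.

The classification unit of the pipeline is a single-channel 32x32 patch
centred on a pixel.  A patch centred at (r, c) covers rows [r-16, r+16) and
columns [c-16, c+16), 0-based and half-open; the centre pixel sits at patch
index (16, 16).  Out-of-bounds pixels are served by reflection padding
(zero padding by flag).  A patch's label is the mask value at its centre
pixel, which makes training labels and dense per-pixel reconstruction
semantics coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "PATCH_SIZE",
    "PATCH_HALF",
    "PatchSet",
    "label_at",
    "cut_patch",
    "cut_patches",
    "extract_balanced",
    "inference_grid",
]

PATCH_SIZE = 32
PATCH_HALF = PATCH_SIZE // 2


@dataclass
class PatchSet:
    """N labeled patches with their source coordinates.

    patches: (N, 1, 32, 32) float32; labels: (N,) in {0, 1} with 1 = liver;
    centers: (N, 2) 0-based (row, col) into the source slice;
    source_ids: (N,) integer slice identifiers.
    """

    patches: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    source_ids: np.ndarray

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centers = np.asarray(self.centers, dtype=np.int64)
        self.source_ids = np.asarray(self.source_ids, dtype=np.int64)
        n = len(self.labels)
        if self.patches.shape != (n, 1, PATCH_SIZE, PATCH_SIZE):
            raise ConfigError(
                f"patches must be (N, 1, {PATCH_SIZE}, {PATCH_SIZE}); "
                f"got {self.patches.shape}"
            )
        if self.centers.shape != (n, 2) or self.source_ids.shape != (n,):
            raise ConfigError("centers/source_ids are inconsistent with N")
        if n and not np.all(np.isin(self.labels, (0, 1))):
            raise ConfigError("labels must be in {0, 1}")

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        return PatchSet(
            np.concatenate([s.patches for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.centers for s in sets]),
            np.concatenate([s.source_ids for s in sets]),
        )

    def save(self, path) -> None:
        """Compressed array container plus a JSON sidecar of the metadata."""
        path = Path(path)
        np.savez_compressed(path, patches=self.patches, labels=self.labels,
                            centers=self.centers, source_ids=self.source_ids)
        sidecar = {
            "n": int(len(self)),
            "n_liver": int(self.labels.sum()),
            "patch_size": PATCH_SIZE,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path) -> "PatchSet":
        with np.load(Path(path)) as data:
            return PatchSet(data["patches"], data["labels"],
                            data["centers"], data["source_ids"])


def label_at(mask: np.ndarray, center: tuple[int, int]) -> int:
    """Patch label = mask value at the centre pixel."""
    mask = np.asarray(mask)
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise DataError(f"center {center!r} outside mask grid {mask.shape}")
    return int(mask[r, c])


def _reflect_indices(idx: np.ndarray, length: int) -> np.ndarray:
    # mirror-without-edge-repeat, period 2*(length-1); matches np.pad 'reflect'
    if length == 1:
        return np.zeros_like(idx)
    period = 2 * (length - 1)
    idx = np.mod(idx, period)
    return np.where(idx >= length, period - idx, idx)


def cut_patch(image: np.ndarray, center: tuple[int, int],
              pad_mode: str = "reflect") -> np.ndarray:
    """Cut the (1, 32, 32) patch centred at (row, col).

    Border patches are completed by reflection (or zeros with
    ``pad_mode='zero'``) via direct index arithmetic.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise DataError("cut_patch expects a 2D slice")
    r, c = int(center[0]), int(center[1])
    rows = np.arange(r - PATCH_HALF, r + PATCH_HALF)
    cols = np.arange(c - PATCH_HALF, c + PATCH_HALF)
    if pad_mode == "reflect":
        rr = _reflect_indices(rows, image.shape[0])
        cc = _reflect_indices(cols, image.shape[1])
        patch = image[np.ix_(rr, cc)]
    elif pad_mode == "zero":
        patch = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=image.dtype)
        r_in = (rows >= 0) & (rows < image.shape[0])
        c_in = (cols >= 0) & (cols < image.shape[1])
        patch[np.ix_(r_in, c_in)] = image[np.ix_(rows[r_in], cols[c_in])]
    else:
        raise ConfigError(f"unknown pad_mode {pad_mode!r}")
    return patch[None].astype(np.float32, copy=False)


def cut_patches(image: np.ndarray, centers: np.ndarray,
                pad_mode: str = "reflect") -> np.ndarray:
    """Vectorized batch form of :func:`cut_patch` -> (N, 1, 32, 32)."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise DataError("cut_patches expects a 2D slice")
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
    mode = {"reflect": "reflect", "zero": "constant"}.get(pad_mode)
    if mode is None:
        raise ConfigError(f"unknown pad_mode {pad_mode!r}")
    padded = np.pad(image, PATCH_HALF, mode=mode)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (PATCH_SIZE, PATCH_SIZE))
    return windows[centers[:, 0], centers[:, 1]][:, None, :, :].copy()


def extract_balanced(image: np.ndarray, mask: np.ndarray, n_per_class: int,
                     seed: int, source_id: int = 0,
                     allow_border: bool = False) -> PatchSet:
    """Sample n_per_class liver-centred and n_per_class background-centred
    patches, uniformly without replacement within each class.

    Eligible centres keep the whole patch in-bounds (>= 16 px from every
    border) unless ``allow_border`` enables reflection-padded border
    sampling.  Raises naming the deficient class when a class has fewer
    eligible pixels than requested.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ConfigError("image and mask shapes differ")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ConfigError("mask must be binary")
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")

    eligible = np.ones(image.shape, dtype=bool)
    if not allow_border:
        eligible[:] = False
        eligible[PATCH_HALF:image.shape[0] - PATCH_HALF + 1,
                 PATCH_HALF:image.shape[1] - PATCH_HALF + 1] = True

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    chosen = []
    for class_label, class_name in ((1, "liver"), (0, "background")):
        pool = np.argwhere(eligible & (mask == class_label))
        if len(pool) < n_per_class:
            raise DataError(
                f"only {len(pool)} eligible {class_name} pixels; "
                f"requested {n_per_class}"
            )
        pick = rng.choice(len(pool), size=n_per_class, replace=False)
        chosen.append((pool[pick], class_label))

    centers = np.concatenate([c for c, _ in chosen])
    labels = np.concatenate(
        [np.full(n_per_class, lab, dtype=np.int64) for _, lab in chosen]
    )
    patches = cut_patches(image, centers)
    source_ids = np.full(len(labels), source_id, dtype=np.int64)
    return PatchSet(patches, labels, centers, source_ids)


def inference_grid(image_shape: tuple[int, int], stride: int = 1) -> np.ndarray:
    """Regular lattice of patch centres covering the slice -> (N, 2).

    stride 1 yields one centre per pixel; larger strides place
    ceil(dim/stride) centres per axis, offset by stride//2 and clamped to
    the grid, so every pixel has a nearby lattice point.
    """
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    h, w = int(image_shape[0]), int(image_shape[1])
    rows = np.minimum(stride // 2 + stride * np.arange(-(-h // stride)), h - 1)
    cols = np.minimum(stride // 2 + stride * np.arange(-(-w // stride)), w - 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)
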