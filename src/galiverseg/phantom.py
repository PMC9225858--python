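"""Synthetic abdominal-CT phantoms with paired ground-truth liver masks.

Real abdominal CT is hard to segment because the liver is large and
irregular while neighbouring organs (spleen, stomach, right kidney, heart)
sit at nearly the same intensity.  The phantom generator reproduces exactly
those statistical challenges on a controllable grid: one irregular,
simply-connected "liver" region, a configurable number of smaller
confounder regions whose intensity distribution overlaps (or, at offset 0,
equals) the liver's, optional darker internal "lesions", and additive
Gaussian noise.  Intensities are in arbitrary units; windowing and
normalization belong to :mod:`galiverseg.preprocess`.

Every output is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, GenerationError

__all__ = [
    "PhantomConfig",
    "ImageVolume",
    "generate_slice",
    "generate_volume",
    "write_fixture_set",
    "derive_slice_seed",
]

#: smallest slice side able to host interior 32x32 patch centres
MIN_IMAGE_SIZE = 64


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic abdominal slice generator.

    Intensity parameters are in arbitrary units on a nominal [0, 1] display
    scale.  ``confounder_intensity_offset`` shifts the confounder mean away
    from the liver mean; at 0 the two tissue classes have identical
    intensity distributions by construction.
    """

    image_size: int = 128
    n_slices: int = 1
    liver_intensity_mean: float = 0.55
    liver_intensity_sd: float = 0.06
    confounder_count: int = 3
    confounder_intensity_offset: float = 0.03
    lesion_probability: float = 0.2
    lesion_intensity_offset: float = -0.15
    noise_sd: float = 0.03
    background_intensity_mean: float = 0.2
    area_band: tuple[float, float] = (0.08, 0.45)
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < MIN_IMAGE_SIZE:
            raise ConfigError(
                f"image_size must be >= {MIN_IMAGE_SIZE} (got {self.image_size})"
            )
        if self.n_slices < 1:
            raise ConfigError("n_slices must be >= 1")
        if self.confounder_count < 0:
            raise ConfigError("confounder_count must be >= 0")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ConfigError("lesion_probability must lie in [0, 1]")
        lo, hi = self.area_band
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError("area_band must satisfy 0 < lo < hi < 1")
        if self.noise_sd < 0 or self.liver_intensity_sd < 0:
            raise ConfigError("intensity standard deviations must be >= 0")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ImageVolume:
    """A 2D slice or 3D axial stack with optional paired binary mask.

    ``intensities`` is (H, W) or (D, H, W); the axial plane is always the
    last two axes.  ``mask`` (if present) has the same shape and holds
    {0, 1} with 1 = liver.
    """

    intensities: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if not np.all(np.isfinite(self.intensities)):
            raise ConfigError("intensities must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensities.shape:
                raise ConfigError(
                    f"mask shape {self.mask.shape} != intensities shape "
                    f"{self.intensities.shape}"
                )
            values = np.unique(self.mask)
            if not np.all(np.isin(values, (0, 1))):
                raise ConfigError("mask must be binary {0, 1}")

    @property
    def n_slices(self) -> int:
        return 1 if self.intensities.ndim == 2 else self.intensities.shape[0]

    def iter_slices(self):
        """Yield (index, image2d, mask2d-or-None) over axial slices."""
        if self.intensities.ndim == 2:
            yield 0, self.intensities, self.mask
        else:
            for k in range(self.intensities.shape[0]):
                yield k, self.intensities[k], None if self.mask is None else self.mask[k]


@dataclass
class _LiverShape:
    """Star-convex boundary: perturbed ellipse in polar form.

    radius(theta) = r0 * (1 + sum_k coeffs[k] * cos(k*theta + phases[k]))
    evaluated in coordinates squeezed by the axis ratio, so the region is
    simply connected by construction.
    """

    center: tuple[float, float]
    r0: float
    axis_ratio: float
    orders: np.ndarray
    coeffs: np.ndarray
    phases: np.ndarray

    def scaled(self, radial_factor: float) -> "_LiverShape":
        return dataclasses.replace(self, r0=self.r0 * radial_factor)


def _sample_shape(rng: np.random.Generator, config: PhantomConfig,
                  frac_band: tuple[float, float]) -> _LiverShape:
    size = config.image_size
    target_frac = rng.uniform(*frac_band)
    axis_ratio = rng.uniform(0.65, 0.95)
    # area of the unperturbed ellipse: pi * r0^2 * axis_ratio
    r0 = size * np.sqrt(target_frac / (np.pi * axis_ratio))
    center = (
        size * (0.5 + rng.uniform(-0.08, 0.08)),
        size * (0.5 + rng.uniform(-0.08, 0.08)),
    )
    orders = np.arange(2, 6)
    coeffs = rng.uniform(-0.14, 0.14, size=orders.size) / np.sqrt(orders)
    phases = rng.uniform(0, 2 * np.pi, size=orders.size)
    return _LiverShape(center, r0, axis_ratio, orders, coeffs, phases)


def _rasterize_shape(shape: _LiverShape, size: int) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows - shape.center[0]
    dx = (cols - shape.center[1]) / shape.axis_ratio
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    modulation = 1.0 + np.sum(
        shape.coeffs[:, None, None]
        * np.cos(shape.orders[:, None, None] * theta[None] + shape.phases[:, None, None]),
        axis=0,
    )
    boundary = shape.r0 * np.clip(modulation, 0.3, None)
    return (rho <= boundary).astype(np.uint8)


def _place_confounders(rng: np.random.Generator, config: PhantomConfig,
                       liver_mask: np.ndarray) -> np.ndarray:
    """Confounder label map; never overlaps the liver (2 px margin)."""
    size = config.image_size
    from scipy import ndimage

    forbidden = ndimage.binary_dilation(liver_mask, iterations=2)
    rows, cols = np.mgrid[0:size, 0:size]
    conf = np.zeros((size, size), dtype=np.uint8)
    for _ in range(config.confounder_count):
        placed = False
        for _attempt in range(500):
            radius = rng.uniform(0.04, 0.09) * size
            ratio = rng.uniform(0.7, 1.0)
            cy = rng.uniform(radius, size - radius)
            cx = rng.uniform(radius, size - radius)
            rho = np.hypot(rows - cy, (cols - cx) / ratio)
            blob = rho <= radius
            if not np.any(blob & (forbidden | conf.astype(bool))):
                conf[blob] = 1
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place a confounder outside the liver after 500 tries"
            )
    return conf


def generate_slice(config: PhantomConfig, slice_seed: int,
                   _shape: _LiverShape | None = None) -> ImageVolume:
    """Generate one 2D phantom slice with its ground-truth liver mask.

    Deterministic in ``(config, slice_seed)``.  The liver is a single
    connected star-convex region whose area fraction falls inside
    ``config.area_band``; confounders never touch it; Gaussian noise with
    sd ``config.noise_sd`` is added last.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(slice_seed) & 0x7FFFFFFF]))
    size = config.image_size
    lo, hi = config.area_band
    # sample inside a slightly shrunk band so boundary perturbation cannot
    # push the realized fraction out of it
    frac_band = (lo + 0.02, hi - 0.05)

    if _shape is not None:
        liver = _rasterize_shape(_shape, size)
        frac = liver.mean()
        if not lo <= frac <= hi:
            raise GenerationError(
                f"volume slice area fraction {frac:.3f} outside band [{lo}, {hi}]"
            )
    else:
        liver = None
        for _attempt in range(50):
            candidate = _rasterize_shape(_sample_shape(rng, config, frac_band), size)
            frac = candidate.mean()
            if lo <= frac <= hi:
                liver = candidate
                break
        if liver is None:
            raise GenerationError(
                f"no liver shape within area band [{lo}, {hi}] after 50 tries"
            )

    conf = (
        _place_confounders(rng, config, liver)
        if config.confounder_count > 0
        else np.zeros_like(liver)
    )

    mean_map = np.full((size, size), config.background_intensity_mean, dtype=np.float64)
    mean_map[liver.astype(bool)] = config.liver_intensity_mean
    mean_map[conf.astype(bool)] = (
        config.liver_intensity_mean + config.confounder_intensity_offset
    )

    # one shared texture field: with offset 0 the liver and confounder
    # intensity distributions are identical by construction
    texture = config.liver_intensity_sd * rng.standard_normal((size, size))
    image = mean_map + texture

    if config.lesion_probability > 0 and rng.random() < config.lesion_probability:
        interior = np.argwhere(liver.astype(bool))
        if interior.size:
            cy, cx = interior[rng.integers(len(interior))]
            radius = rng.uniform(0.08, 0.16) * np.sqrt(liver.sum() / np.pi)
            rows, cols = np.mgrid[0:size, 0:size]
            lesion = (np.hypot(rows - cy, cols - cx) <= radius) & liver.astype(bool)
            image[lesion] += config.lesion_intensity_offset  # mask stays liver

    if config.noise_sd > 0:
        image = image + config.noise_sd * rng.standard_normal((size, size))

    return ImageVolume(intensities=image, spacing=(1.0, 1.0), mask=liver)


def derive_slice_seed(config_seed: int, index: int) -> int:
    """Deterministic per-slice seed from the volume seed and slice index."""
    state = np.random.SeedSequence([int(config_seed) & 0x7FFFFFFF, int(index)])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


def generate_volume(config: PhantomConfig) -> ImageVolume:
    """Stack ``config.n_slices`` phantom slices into an axial volume.

    For multi-slice volumes one base liver shape is sampled from
    ``config.seed`` and modulated along the axial direction (an elliptic
    radial profile plus a small per-slice boundary jitter), so adjacent
    masks overlap strongly, as liver cross-sections do.  A single-slice
    volume is exactly ``generate_slice(config, derive_slice_seed(seed, 0))``.
    """
    config.validate()
    if config.n_slices == 1:
        vol = generate_slice(config, derive_slice_seed(config.seed, 0))
        return ImageVolume(
            intensities=vol.intensities[None],
            spacing=(1.0,) + vol.spacing,
            mask=vol.mask[None],
        )

    base_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xBA5E])
    )
    # keep the base fraction high enough that the axial taper stays in band
    lo, hi = config.area_band
    base_band = (max(lo / 0.5, lo + 0.06), hi - 0.05)
    base = None
    for _ in range(50):
        candidate = _sample_shape(base_rng, config, base_band)
        frac = _rasterize_shape(candidate, config.image_size).mean()
        if base_band[0] <= frac <= hi:
            base = candidate
            break
    if base is None:
        raise GenerationError("no feasible base liver shape for the volume")

    n = config.n_slices
    mid = (n - 1) / 2.0
    half = max(mid, 1.0)
    images, masks = [], []
    for k in range(n):
        # elliptic taper: radius factor in [~0.75, 1.0] across the stack
        profile = np.sqrt(1.0 - 0.45 * ((k - mid) / half) ** 2)
        jitter_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x51DE, k])
        )
        shape_k = dataclasses.replace(
            base,
            r0=base.r0 * profile,
            coeffs=base.coeffs + 0.01 * jitter_rng.standard_normal(base.coeffs.shape),
            center=(
                base.center[0] + jitter_rng.uniform(-1.0, 1.0),
                base.center[1] + jitter_rng.uniform(-1.0, 1.0),
            ),
        )
        sl = generate_slice(config, derive_slice_seed(config.seed, k), _shape=shape_k)
        images.append(sl.intensities)
        masks.append(sl.mask)
    return ImageVolume(
        intensities=np.stack(images),
        spacing=(1.0, 1.0, 1.0),
        mask=np.stack(masks),
    )


def write_fixture_set(config: PhantomConfig, n_volumes: int, out_dir) -> dict:
    """Write ``n_volumes`` phantom volumes as NIfTI image/mask pairs.

    Returns (and writes) a JSON manifest listing file names, per-volume
    seeds and the config content hash.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_volumes):
        vol_config = dataclasses.replace(config, seed=derive_slice_seed(config.seed, i))
        vol = generate_volume(vol_config)
        img_name = f"phantom_{i:03d}_image.nii.gz"
        mask_name = f"phantom_{i:03d}_mask.nii.gz"
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), out / img_name)
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), out / mask_name)
        entries.append({"image": img_name, "mask": mask_name, "seed": vol_config.seed})
    manifest = {
        "config_hash": config.content_hash(),
        "n_volumes": n_volumes,
        "volumes": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
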