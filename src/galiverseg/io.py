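"""Format handling, run configuration, and the end-to-end pipeline driver.

Conventions: 0-based (row, col) = (y, x) coordinates; the axial slice axis
is the FIRST axis of in-memory 3D arrays, while NIfTI files store slices
along the last (Z) axis — the readers and writers transpose accordingly.
Masks are written as unsigned 8-bit, intensity volumes as 32-bit float.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics as metrics_mod
from .errors import ConfigError, DataError
from .network import NetworkSpec, default_spec, init_gaussian
from .patches import PatchSet, extract_balanced
from .phantom import ImageVolume, PhantomConfig, derive_slice_seed, generate_slice
from .preprocess import PreprocessConfig, augment, normalize_slice
from .segment import SegmentConfig, segment_volume
from .train import TrainConfig, fit

__all__ = ["RunConfig", "SamplingConfig", "read_volume", "write_mask",
           "write_volume", "run_end_to_end"]

logger = logging.getLogger("galiverseg.io")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume or a 2D PNG/TIFF slice into an ImageVolume.

    NIfTI input is reoriented to the closest canonical orientation (the
    original orientation code is kept in ``meta``); the slice axis is moved
    first.  Integer data keeps its dtype so masks round-trip bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path does not exist: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        original_ornt = "".join(nib.orientations.aff2axcodes(img.affine))
        img = nib.as_closest_canonical(img)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim == 3:
            arr = np.moveaxis(arr, -1, 0)  # slices first in memory
        elif arr.ndim != 2:
            raise DataError(f"unsupported NIfTI dimensionality {arr.ndim}")
        zooms = img.header.get_zooms()
        meta = {"orientation": original_ornt, "format": "nifti"}
        vol = ImageVolume(intensities=arr, spacing=tuple(float(z) for z in zooms))
        vol.meta = meta
        return vol
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse RGB(A) to a scalar grid
            arr = arr[..., 0]
        vol = ImageVolume(intensities=arr, spacing=(1.0, 1.0))
        vol.meta = {"format": path.suffix.lower().lstrip(".")}
        return vol
    if path.suffix.lower() == ".dcm":
        raise DataError("DICOM series reading is not supported; convert to NIfTI")
    raise DataError(f"unsupported input format: {path.name}")


def write_volume(array: np.ndarray, path, dtype=np.float32) -> None:
    """Write an intensity array ((D,)H,W) as NIfTI or a 2D PNG/TIFF."""
    path = Path(path)
    array = np.asarray(array)
    if _is_nifti(path):
        import nibabel as nib

        out = array.astype(dtype)
        if out.ndim == 3:
            out = np.moveaxis(out, 0, -1)
        nib.save(nib.Nifti1Image(out, np.eye(4)), str(path))
        return
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        if array.ndim != 2:
            raise DataError("PNG/TIFF output supports 2D slices only")
        iio.imwrite(path, array.astype(np.uint8) if dtype == np.uint8
                    else array.astype(np.float32))
        return
    raise DataError(f"unsupported output format: {path.name}")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask losslessly (uint8)."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise DataError("mask must be binary")
    if Path(path).suffix.lower() == ".png":
        # scale to the display range so the mask is visible in viewers
        import imageio.v3 as iio

        iio.imwrite(Path(path), (mask * 255).astype(np.uint8))
        return
    write_volume(mask.astype(np.uint8), path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingConfig:
    n_per_class: int = 200
    allow_border: bool = False
    augment: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run from a single YAML
    document: per-stage sections plus the global seed."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    network: NetworkSpec = field(default_factory=default_spec)
    train: TrainConfig = field(default_factory=TrainConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    n_train_slices: int = 8
    n_test_slices: int = 2
    use_oracle_stub: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        def build(cls, key):
            sub = dict(d.get(key) or {})
            for f in dataclasses.fields(cls):
                if f.name in sub and isinstance(sub[f.name], list):
                    sub[f.name] = tuple(sub[f.name])
            return cls(**sub)

        return RunConfig(
            phantom=build(PhantomConfig, "phantom"),
            preprocess=build(PreprocessConfig, "preprocess"),
            sampling=build(SamplingConfig, "sampling"),
            network=(NetworkSpec.from_dict(d["network"]) if d.get("network")
                     else default_spec()),
            train=build(TrainConfig, "train"),
            segment=build(SegmentConfig, "segment"),
            n_train_slices=d.get("n_train_slices", 8),
            n_test_slices=d.get("n_test_slices", 2),
            use_oracle_stub=d.get("use_oracle_stub", False),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(source) -> "RunConfig":
        text = str(source)
        if isinstance(source, Path) or ("\n" not in text and len(text) < 4096
                                        and Path(text).exists()):
            text = Path(source).read_text()
        return RunConfig.from_dict(yaml.safe_load(text) or {})

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class CenterPixelStub:
    """Oracle classifier: 'probability' = the patch's centre-pixel value.

    Pushed over a ground-truth mask it reproduces that mask exactly, which
    makes it the reference model for pipeline round-trip checks.
    """

    def forward(self, batch: np.ndarray) -> np.ndarray:
        p1 = np.asarray(batch)[:, 0, 16, 16].astype(np.float64)
        p1 = np.clip(p1, 0.0, 1.0)
        return np.stack([1.0 - p1, p1], axis=1)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def _build_training_set(config: RunConfig) -> PatchSet:
    sets = []
    for i in range(config.n_train_slices):
        phantom_cfg = dataclasses.replace(config.phantom,
                                          seed=derive_slice_seed(config.seed, i))
        sl = generate_slice(phantom_cfg, derive_slice_seed(config.seed, i))
        image = normalize_slice(sl.intensities, config.preprocess)
        pairs = (augment(image, sl.mask, config.preprocess)
                 if config.sampling.augment else [(image, sl.mask)])
        for j, (img, msk) in enumerate(pairs):
            sets.append(extract_balanced(
                img, msk, config.sampling.n_per_class,
                seed=derive_slice_seed(config.seed, 7919 + 13 * i + j),
                source_id=i, allow_border=config.sampling.allow_border))
    return PatchSet.concatenate(sets)


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """simulate -> preprocess -> patches -> train -> segment -> evaluate.

    Writes the resolved config, per-unit metric CSV and a summary JSON to
    ``out_dir`` and returns the summary.  Fully deterministic in
    (config, config.seed); stage failures are re-raised naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "simulate"
    try:
        patchset = _build_training_set(config)

        stage = "train"
        if config.use_oracle_stub:
            model = CenterPixelStub()
            history = None
        else:
            train_cfg = dataclasses.replace(config.train, seed=config.seed)
            model = init_gaussian(config.network, sigma=train_cfg.sigma_init,
                                  seed=config.seed)
            if train_cfg.max_epochs > 0:
                model, history = fit(model, patchset, train_cfg)
                history.to_csv(out / "history.csv")
            else:
                history = None

        stage = "segment"
        reports = []
        for i in range(config.n_test_slices):
            test_seed = derive_slice_seed(config.seed, 100_000 + i)
            phantom_cfg = dataclasses.replace(config.phantom, seed=test_seed)
            sl = generate_slice(phantom_cfg, test_seed)
            # the oracle stub classifies by centre-pixel ground truth
            target = sl.mask.astype(np.float64) if config.use_oracle_stub \
                else sl.intensities
            vol = ImageVolume(intensities=target, mask=sl.mask)
            masks, _prov = segment_volume(
                model, vol, config.segment,
                preprocess_config=(None if config.use_oracle_stub
                                   else config.preprocess))
            stage = "evaluate"
            counts = metrics_mod.confusion(masks, sl.mask)
            reports.append(metrics_mod.report(counts, id=f"test_{i}"))
            stage = "segment"

        stage = "evaluate"
        pooled = metrics_mod.aggregate(reports, "pooled_counts")
        mean = metrics_mod.aggregate(reports, "mean_of_metrics")
        frame = metrics_mod.reports_to_dataframe(reports + [pooled])
        frame.to_csv(out / "metrics.csv", index=False)
        summary = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "n_train_patches": int(len(patchset)),
            "n_test_slices": config.n_test_slices,
            "epochs_trained": 0 if history is None else len(history),
            "pooled": pooled.as_dict(),
            "mean_of_metrics": mean.as_dict(),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
        return summary
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        (out / "failure.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}))
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
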