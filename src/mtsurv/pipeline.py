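"""Deterministic preprocessing and stochastic augmentation of tumor-centered
volumes, plus multi-crop inference averaging.

Axis order is (Z, Y, X) throughout, matching the 48x64x64 crop convention;
all crop windows are 0-based and half-open.  Isotropic resampling to 1 mm³
is treated as a precondition of the input data (delegated to standard
imaging tooling); this module starts from resampled volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .autodiff import Tensor
from .survival import SurvivalRecord

__all__ = [
    "VolumeSample",
    "AugmentationPolicy",
    "clip_normalize_ct",
    "normalize_sample",
    "center_of_mass_crop",
    "enlarged_size",
    "training_crop",
    "multicrop_inference",
    "load_cohort",
    "save_cohort",
]

CT_CLIP_RANGE = (-200.0, 200.0)


@dataclass
class VolumeSample:
    """One patient's image (channels, Z, Y, X), binary mask, and outcome."""

    image: np.ndarray
    mask: np.ndarray
    record: SurvivalRecord
    patient_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim == 3:
            self.image = self.image[None]
        self.mask = np.asarray(self.mask)
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image spatial shape {self.image.shape[1:]} != mask shape {self.mask.shape}"
            )


@dataclass(frozen=True)
class AugmentationPolicy:
    """Training-time augmentation settings, each applied with
    ``apply_probability`` independently per sample."""

    apply_probability: float = 0.5
    max_translation_voxels: int = 25
    noise_sd: float = 0.1
    intensity_shift_range: tuple = (-2.0, 2.0)
    contrast_gamma_range: tuple = (0.5, 2.5)
    smooth_variance_range: tuple = (0.25, 0.75)
    max_rotation_degrees: float = 20.0
    flips: bool = True
    rotate_all_axes: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.apply_probability <= 1:
            raise ValueError("apply_probability must lie in [0, 1]")
        for name in ("intensity_shift_range", "contrast_gamma_range", "smooth_variance_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered: ({lo}, {hi})")


def clip_normalize_ct(channel: np.ndarray, clip_range=CT_CLIP_RANGE) -> np.ndarray:
    """Clip CT intensities to [-200, 200] HU and min-max rescale to [0, 1].

    The rescaling is per patient (per call).  A channel that is constant
    after clipping carries no intensity information and is zeroed with a
    warning.
    """
    lo, hi = clip_range
    clipped = np.clip(np.asarray(channel, dtype=np.float32), lo, hi)
    cmin, cmax = float(clipped.min()), float(clipped.max())
    if cmax == cmin:
        warnings.warn("constant CT channel after clipping; returning zeros", stacklevel=2)
        return np.zeros_like(clipped)
    return (clipped - cmin) / (cmax - cmin)


def normalize_sample(sample: VolumeSample, ct_channels=(0,)) -> VolumeSample:
    """Normalize CT-like channels; PET-like channels pass through unscaled."""
    image = sample.image.copy()
    for c in ct_channels:
        image[c] = clip_normalize_ct(image[c])
    return replace(sample, image=image)


def _crop_window(volume: np.ndarray, start, size) -> np.ndarray:
    """Extract a zero-padded half-open window; spatial axes are the last 3."""
    out_shape = volume.shape[:-3] + tuple(size)
    out = np.zeros(out_shape, dtype=volume.dtype)
    src, dst = [], []
    for axis in range(3):
        s0 = start[axis]
        s1 = s0 + size[axis]
        extent = volume.shape[volume.ndim - 3 + axis]
        src.append(slice(max(s0, 0), min(s1, extent)))
        dst.append(slice(max(-s0, 0), size[axis] - max(s1 - extent, 0)))
    if all(sl.start < sl.stop for sl in src):
        out[(...,) + tuple(dst)] = volume[(...,) + tuple(src)]
    return out


def mask_center_of_mass(mask: np.ndarray) -> np.ndarray:
    fg = np.argwhere(mask > 0)
    if len(fg) == 0:
        raise ValueError("mask has no foreground voxels")
    return fg.mean(axis=0)


def center_of_mass_crop(sample: VolumeSample, size=(48, 64, 64)) -> VolumeSample:
    """Crop image and mask around the tumor's center of mass.

    The crop is centered on the foreground center of mass rounded to the
    nearest voxel and zero-padded wherever it exceeds the volume.
    """
    # round half up (not banker's) so the crop is translation-equivariant
    com = np.floor(mask_center_of_mass(sample.mask) + 0.5).astype(int)
    start = [com[a] - size[a] // 2 for a in range(3)]
    return replace(
        sample,
        image=_crop_window(sample.image, start, size),
        mask=_crop_window(sample.mask, start, size),
    )


def enlarged_size(size) -> tuple:
    """The 1.25x larger region used for random-crop augmentation."""
    return tuple(int(round(s * 1.25)) for s in size)


def _random_subcrop(image, mask, size, rng):
    big = image.shape[1:]
    start = [int(rng.integers(0, big[a] - size[a] + 1)) for a in range(3)]
    return _crop_window(image, start, size), _crop_window(mask, start, size), start


def _translate(volume, shift):
    return _crop_window(volume, [-s for s in shift], volume.shape[-3:])


def _adjust_contrast(channel, gamma):
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        return channel
    return ((channel - lo) / (hi - lo)) ** gamma * (hi - lo) + lo


def _rotate(volume, angle, axes, order):
    return ndimage.rotate(
        volume, angle, axes=axes, reshape=False, order=order, mode="constant", cval=0.0
    )


def training_crop(
    sample: VolumeSample,
    policy: AugmentationPolicy = AugmentationPolicy(),
    size=(48, 64, 64),
    rng: np.random.Generator | None = None,
) -> VolumeSample:
    """Random crop plus stochastic augmentations for one training sample.

    An enlarged (1.25x) region around the tumor center of mass is extracted
    first and a uniformly random window of the target size is taken from it.
    Each augmentation then triggers independently with the policy
    probability; spatial transforms are applied identically to image and
    mask (nearest-neighbor for the mask, preserving binarity).
    """
    rng = rng or np.random.default_rng(policy.seed)
    enlarged = center_of_mass_crop(sample, enlarged_size(size))
    image, mask, _ = _random_subcrop(enlarged.image, enlarged.mask, size, rng)
    mask = mask.astype(np.float32)
    p = policy.apply_probability

    if rng.random() < p:  # translation
        shift = rng.integers(
            -policy.max_translation_voxels, policy.max_translation_voxels + 1, size=3
        )
        image = _translate(image, shift)
        mask = _translate(mask, shift)
    if rng.random() < p:  # additive Gaussian noise
        image = image + rng.normal(0.0, policy.noise_sd, size=image.shape).astype(np.float32)
    if rng.random() < p:  # intensity shift
        image = image + np.float32(rng.uniform(*policy.intensity_shift_range))
    if rng.random() < p:  # contrast adjustment
        gamma = rng.uniform(*policy.contrast_gamma_range)
        image = np.stack([_adjust_contrast(ch, gamma) for ch in image])
    if rng.random() < p:  # Gaussian smoothing, per-axis variance
        sigmas = np.sqrt(rng.uniform(*policy.smooth_variance_range, size=3))
        image = np.stack([ndimage.gaussian_filter(ch, sigmas) for ch in image])
    if rng.random() < p:  # rotation (about Z unless rotate_all_axes)
        axes_choices = [(-2, -1)] if not policy.rotate_all_axes else [(-2, -1), (-3, -1), (-3, -2)]
        axes = axes_choices[int(rng.integers(len(axes_choices)))]
        angle = rng.uniform(-policy.max_rotation_degrees, policy.max_rotation_degrees)
        image = _rotate(image, angle, axes, order=1)
        mask = (_rotate(mask, angle, axes, order=0) > 0.5).astype(np.float32)
    if policy.flips and rng.random() < p:  # axis flips
        for axis in range(3):
            if rng.random() < 0.5:
                image = np.flip(image, axis=axis + 1)
                mask = np.flip(mask, axis=axis)
    return replace(sample, image=np.ascontiguousarray(image), mask=np.ascontiguousarray(mask))


def multicrop_inference(
    network,
    sample: VolumeSample,
    size=(48, 64, 64),
    n_crops: int = 8,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Average network outputs over random crops of the enlarged region.

    Head outputs (log-hazard, conditional survival probabilities) are
    averaged over ``n_crops`` random windows.  Segmentation maps are
    averaged in the frame of the central crop over the region each random
    window overlaps; voxels no random window covers keep the central crop's
    prediction.
    """
    rng = np.random.default_rng(seed)
    big = enlarged_size(size)
    enlarged = center_of_mass_crop(sample, big)
    central_start = [(big[a] - size[a]) // 2 for a in range(3)]

    was_training = network.training
    network.eval()

    def run(image):
        out = network(Tensor(image[None]))
        return {k: v.value[0] for k, v in out.items()}

    central = run(_crop_window(enlarged.image, central_start, size))
    seg_sum = np.zeros_like(central["segmentation"])
    seg_count = np.zeros(size, dtype=np.int32)
    head_sums: dict[str, np.ndarray] = {}
    for _ in range(n_crops):
        image, _, start = _random_subcrop(enlarged.image, enlarged.mask, size, rng)
        out = run(image)
        for key in ("log_hazard", "conditional_probs"):
            if key in out:
                head_sums[key] = head_sums.get(key, 0.0) + out[key]
        # map this window's prediction back into the central frame
        offset = [start[a] - central_start[a] for a in range(3)]
        dst = [slice(max(offset[a], 0), min(size[a] + offset[a], size[a])) for a in range(3)]
        src = [slice(max(-offset[a], 0), min(size[a] - offset[a], size[a])) for a in range(3)]
        seg_sum[(...,) + tuple(dst)] += out["segmentation"][(...,) + tuple(src)]
        seg_count[tuple(dst)] += 1
    network.train(was_training)

    covered = seg_count > 0
    segmentation = central["segmentation"].copy()
    segmentation[:, covered] = seg_sum[:, covered] / seg_count[covered]
    result = {k: v / n_crops for k, v in head_sums.items()}
    result["segmentation"] = segmentation
    return result


# -- cohort I/O (NIfTI volumes + CSV manifest) ---------------------------------


def save_cohort(samples, directory) -> Path:
    """Write volumes/masks as .nii.gz and a manifest CSV; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        pid = sample.patient_id or f"P{len(rows):04d}"
        image_paths = []
        for c in range(sample.image.shape[0]):
            path = directory / f"{pid}_ch{c}.nii.gz"
            nib.save(nib.Nifti1Image(sample.image[c], affine=np.eye(4)), path)
            image_paths.append(path.name)
        mask_path = directory / f"{pid}_mask.nii.gz"
        nib.save(nib.Nifti1Image(sample.mask.astype(np.uint8), affine=np.eye(4)), mask_path)
        rows.append(
            {
                "patient_id": pid,
                "image_paths": ";".join(image_paths),
                "mask_path": mask_path.name,
                "time_months": sample.record.time,
                "event": sample.record.event,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list[VolumeSample]:
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    samples = []
    for row in pd.read_csv(manifest_path).itertuples():
        channels = [
            np.asanyarray(nib.load(directory / p).dataobj, dtype=np.float32)
            for p in str(row.image_paths).split(";")
        ]
        mask = np.asanyarray(nib.load(directory / row.mask_path).dataobj)
        record = SurvivalRecord(float(row.time_months), int(row.event), str(row.patient_id))
        samples.append(
            VolumeSample(np.stack(channels), mask, record, patient_id=str(row.patient_id))
        )
    return samples
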