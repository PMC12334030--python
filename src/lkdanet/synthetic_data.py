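"""Synthetic multi-organ phantoms, NIfTI I/O, cropping and augmentation.

The phantom generator stands in for clinical CT/MRI volumes: K compact
"organs" (random non-overlapping ellipsoids) of distinct mean intensities
on a zero-mean background, with additive Gaussian noise and a per-voxel
integer label map.  Everything here is a pure function of its inputs and
seed, so training and evaluation paths are reproducible end to end with
no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class LabeledSample:
    """An image volume paired with its integer label map and voxel spacing."""

    image: np.ndarray          # rank-3 float volume
    labels: np.ndarray         # rank-3 integer volume, same dims
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm per axis

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.image.ndim != 3 or self.labels.ndim != 3:
            raise ValueError("image and labels must be rank-3 volumes")
        if self.image.shape != self.labels.shape:
            raise ValueError(f"image {self.image.shape} and labels "
                             f"{self.labels.shape} dims differ")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive mm values, got {sp}")
        self.spacing = sp


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one deterministic phantom volume.

    ``intensity_means`` gives the mean image value inside each of the K
    organs (background has mean 0); they must be pairwise distinct so the
    classes stay separable.  Radii are in voxels.
    """

    size: tuple[int, int, int] = (64, 64, 64)
    n_classes: int = 3
    intensity_means: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    min_organ_radius: int = 4
    max_organ_radius: int = 10
    seed: int = 0

    def resolved_means(self) -> tuple[float, ...]:
        if self.intensity_means is not None:
            means = tuple(float(m) for m in self.intensity_means)
        else:
            # evenly spread in [0.5, 1.5]: distinct, well away from background
            means = tuple(0.5 + k / max(self.n_classes - 1, 1)
                          for k in range(self.n_classes))
        if len(means) != self.n_classes:
            raise ValueError(f"{len(means)} intensity means for "
                             f"{self.n_classes} organ classes")
        if len(set(means)) != len(means):
            raise ValueError(f"intensity means must be pairwise distinct: {means}")
        return means

    def __post_init__(self):
        if len(self.size) != 3 or any(s < 1 for s in self.size):
            raise ValueError(f"invalid volume size {self.size}")
        if self.n_classes < 1:
            raise ValueError("need at least one organ class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 1 <= self.min_organ_radius <= self.max_organ_radius:
            raise ValueError("need 1 <= min_organ_radius <= max_organ_radius")
        if any(2 * self.max_organ_radius >= s for s in self.size):
            raise ValueError(f"organs of radius {self.max_organ_radius} do "
                             f"not fit inside volume {self.size}")
        self.resolved_means()  # validate


def generate_phantom(spec: PhantomSpec,
                     max_attempts: int = 1000) -> LabeledSample:
    """Place K non-overlapping random ellipsoids and paint the image.

    Rejection sampling, fully seeded: organ k (label k, 1-based) occupies
    an axis-aligned ellipsoid with per-axis radii drawn from
    [min_organ_radius, max_organ_radius]; voxels inside organ k get
    intensity Normal(mean_k, noise_sd), background Normal(0, noise_sd).
    Every organ is guaranteed non-empty.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    labels = np.zeros(size, dtype=np.int64)
    grids = np.indices(size).astype(np.float64)
    for k in range(1, spec.n_classes + 1):
        for attempt in range(max_attempts):
            radii = rng.uniform(spec.min_organ_radius,
                                spec.max_organ_radius, size=3)
            center = [rng.uniform(r, s - r) for r, s in zip(radii, size)]
            dist = sum(((grids[a] - center[a]) / radii[a]) ** 2
                       for a in range(3))
            mask = dist <= 1.0
            if mask.any() and not (labels[mask] != 0).any():
                labels[mask] = k
                break
        else:
            raise RuntimeError(
                f"could not place organ {k} without overlap after "
                f"{max_attempts} attempts; reduce the organ radii or class "
                f"count for volume {size}")
    means = (0.0,) + spec.resolved_means()
    image = np.asarray(means)[labels]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=size)
    return LabeledSample(image=image, labels=labels)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and magnitudes of the augmentation suite.

    Defaults follow common 3-D segmentation practice: mild affine jitter
    (scale 0.9–1.1, rotation up to 15° about a random axis pair) and
    intensity perturbations that leave the labels untouched.
    """

    p_scale: float = 0.2
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_rotate: float = 0.2
    max_rotation_deg: float = 15.0
    p_noise: float = 0.1
    noise_sd: float = 0.05
    p_blur: float = 0.2
    blur_sigma_range: tuple[float, float] = (0.5, 1.0)
    p_brightness: float = 0.15
    brightness_range: tuple[float, float] = (-0.2, 0.2)
    p_contrast: float = 0.15
    contrast_range: tuple[float, float] = (0.75, 1.25)


def _affine_about_center(matrix: np.ndarray, shape) -> np.ndarray:
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = center - matrix @ center
    return offset


def augment(sample: LabeledSample, seed: int,
            config: AugmentConfig | None = None) -> LabeledSample:
    """Seeded stochastic augmentation of one sample.

    Spatial transforms (scaling, rotation) resample the image trilinearly
    and the labels with nearest-neighbour, preserving the volume dims;
    intensity transforms (brightness, contrast, additive Gaussian noise,
    Gaussian blur) touch only the image.
    """
    cfg = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    image = sample.image.copy()
    labels = sample.labels.copy()
    shape = image.shape

    matrix = np.eye(3)
    transformed = False
    if rng.random() < cfg.p_scale:
        s = rng.uniform(*cfg.scale_range)
        matrix = matrix / s  # output->input mapping: inverse scale
        transformed = True
    if rng.random() < cfg.p_rotate:
        angle = np.deg2rad(rng.uniform(-cfg.max_rotation_deg,
                                       cfg.max_rotation_deg))
        axes = rng.permutation(3)[:2]
        rot = np.eye(3)
        c, s = np.cos(angle), np.sin(angle)
        a, b = sorted(axes)
        rot[a, a] = c
        rot[a, b] = -s
        rot[b, a] = s
        rot[b, b] = c
        matrix = matrix @ rot.T  # inverse rotation
        transformed = True
    if transformed:
        offset = _affine_about_center(matrix, shape)
        image = ndimage.affine_transform(image, matrix, offset=offset,
                                         order=1, mode="constant", cval=0.0)
        labels = ndimage.affine_transform(labels, matrix, offset=offset,
                                          order=0, mode="constant", cval=0,
                                          output=labels.dtype)
    if rng.random() < cfg.p_brightness:
        image = image + rng.uniform(*cfg.brightness_range)
    if rng.random() < cfg.p_contrast:
        mean = image.mean()
        image = (image - mean) * rng.uniform(*cfg.contrast_range) + mean
    if rng.random() < cfg.p_noise:
        image = image + rng.normal(0.0, cfg.noise_sd, size=shape)
    if rng.random() < cfg.p_blur:
        image = ndimage.gaussian_filter(
            image, sigma=rng.uniform(*cfg.blur_sigma_range))
    return LabeledSample(image=image, labels=labels, spacing=sample.spacing)


def crop_patch(sample: LabeledSample, patch_size, seed: int,
               fg_bias: float = 0.5) -> LabeledSample:
    """Seeded random crop, optionally biased to contain foreground.

    With probability ``fg_bias`` the crop is centred on a uniformly drawn
    foreground voxel (clamped to keep the patch inside the volume);
    otherwise the corner is uniform.  Volumes smaller than the patch are
    zero-padded first (labels padded with background).
    """
    patch = tuple(int(p) for p in (patch_size if hasattr(patch_size, "__len__")
                                   else (patch_size,) * 3))
    if any(p < 1 for p in patch):
        raise ValueError(f"invalid patch size {patch}")
    rng = np.random.default_rng(seed)
    image, labels = sample.image, sample.labels
    pad = [(0, max(p - s, 0)) for p, s in zip(patch, image.shape)]
    if any(hi for _, hi in pad):
        image = np.pad(image, pad)
        labels = np.pad(labels, pad)
    shape = image.shape
    fg = np.argwhere(labels > 0)
    if fg.size and rng.random() < fg_bias:
        center = fg[rng.integers(len(fg))]
        corner = [int(np.clip(c - p // 2, 0, s - p))
                  for c, p, s in zip(center, patch, shape)]
    else:
        corner = [int(rng.integers(0, s - p + 1))
                  for p, s in zip(patch, shape)]
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
    return LabeledSample(image=image[sl].copy(), labels=labels[sl].copy(),
                        spacing=sample.spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_nifti(volume: np.ndarray, spacing, path) -> None:
    """Write a volume with a diagonal affine built from the voxel spacing."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a rank-3 volume, got rank {volume.ndim}")
    spacing = tuple(float(s) for s in spacing)
    if np.issubdtype(volume.dtype, np.integer):
        data = volume.astype(np.int32)
    else:
        data = volume.astype(np.float32)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume and its voxel spacing (mm) from a NIfTI file."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_labeled_pair(image_path, labels_path) -> LabeledSample:
    image, spacing = read_nifti(image_path)
    labels, lab_spacing = read_nifti(labels_path)
    if image.shape != labels.shape:
        raise IOError(f"image {image.shape} and labels {labels.shape} "
                      f"dims differ")
    return LabeledSample(image=np.asarray(image, dtype=np.float64),
                        labels=np.rint(labels).astype(np.int64),
                        spacing=spacing)


# ---------------------------------------------------------------------------
# resampling


def resample_to_spacing(sample: LabeledSample,
                        target_spacing) -> LabeledSample:
    """Resample to a uniform target spacing (image trilinear, labels NN).

    Output dims are ``round(dims · spacing / target)``; the sample's
    spacing metadata is updated to the target.
    """
    target = tuple(float(t) for t in
                   (target_spacing if hasattr(target_spacing, "__len__")
                    else (target_spacing,) * 3))
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if target == sample.spacing:
        return LabeledSample(image=sample.image.copy(),
                            labels=sample.labels.copy(),
                            spacing=sample.spacing)
    factors = [s / t for s, t in zip(sample.spacing, target)]
    out_dims = [max(int(round(d * f)), 1)
                for d, f in zip(sample.image.shape, factors)]
    zoom = [o / d for o, d in zip(out_dims, sample.image.shape)]
    image = ndimage.zoom(sample.image, zoom, order=1, mode="nearest",
                         grid_mode=True)
    labels = ndimage.zoom(sample.labels, zoom, order=0, mode="nearest",
                          grid_mode=True, output=sample.labels.dtype)
    return LabeledSample(image=image, labels=labels, spacing=target)
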