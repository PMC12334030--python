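"""Training losses and evaluation metrics for volumetric segmentation.

Loss: the usual compound of mean soft-Dice over classes plus mean voxel
cross-entropy, optionally deep-supervised across decoder resolutions with
geometrically decaying weights α_k ∝ 2^{-k} normalised to unit sum.

Metrics: per-class Dice similarity coefficient and the 95th-percentile
symmetric surface distance (HD95) in millimetres, reported per class and
averaged (background excluded by default, the multi-organ convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .nn import Tensor
from .nn import core as F

DICE_SMOOTH = 1e-5


# ---------------------------------------------------------------------------
# losses


def _check_targets(logits: Tensor, targets: np.ndarray) -> np.ndarray:
    targets = np.asarray(targets)
    K = logits.shape[1]
    if targets.shape != (logits.shape[0],) + tuple(logits.shape[2:]):
        raise ValueError(f"target shape {targets.shape} does not match "
                         f"logits {tuple(logits.shape)}")
    if not np.issubdtype(targets.dtype, np.integer):
        raise ValueError("targets must be an integer label volume")
    bad = (targets < 0) | (targets >= K)
    if bad.any():
        offender = int(targets[bad][0])
        raise ValueError(f"label {offender} outside [0, {K})")
    return targets


def _one_hot(targets: np.ndarray, K: int) -> np.ndarray:
    eye = np.eye(K)
    return np.moveaxis(eye[targets], -1, 1)  # (N, K, D, H, W)


def dice_ce_loss(logits: Tensor, targets: np.ndarray,
                 eps: float = DICE_SMOOTH) -> Tensor:
    """Soft-Dice loss (mean over classes) plus mean cross-entropy.

    With P the channel softmax and Z the one-hot target::

        L_dice = 1 − (1/K) Σ_j 2 Σ_i Z_ij P_ij / (Σ_i Z_ij² + Σ_i P_ij² + ε)
        L_ce   = −(1/I) Σ_i log P_{i, z(i)}

    Both terms are non-negative and vanish as the prediction approaches
    the one-hot truth (up to the ε smoothing in the Dice term).
    """
    targets = _check_targets(logits, targets)
    K = logits.shape[1]
    Z = _one_hot(targets, K)
    logp = F.log_softmax(logits, axis=1)
    P = F.exp(logp)
    spatial = (0, 2, 3, 4)
    inter = (P * Z).sum(axis=spatial)
    denom = (P * P).sum(axis=spatial) + Z.sum(axis=spatial) + eps
    dice = 1.0 - (2.0 * inter * F.div(Tensor(1.0), denom)).sum() * (1.0 / K)
    ce = -(logp * Z).sum() * (1.0 / targets.size)
    return dice + ce


def supervision_weights(n: int) -> tuple[Fraction, ...]:
    """Deep-supervision weights α_k = 2^{n−k} / (2ⁿ − 1), finest first.

    Exact rationals: the unique halving chain (α_{k+1} = α_k / 2) with
    unit sum.
    """
    if n < 1:
        raise ValueError(f"need at least one resolution, got {n}")
    denom = 2 ** n - 1
    return tuple(Fraction(2 ** (n - k), denom) for k in range(1, n + 1))


def deep_supervised_loss(final_logits: Tensor, aux_logits: list[Tensor],
                         targets: np.ndarray) -> Tensor:
    """Weighted multi-resolution loss.

    ``aux_logits`` are ordered fine → coarse; each is trilinearly
    upsampled to the full target resolution and scored against the same
    ground truth, with weights halving from the full-resolution term.
    """
    alphas = supervision_weights(1 + len(aux_logits))
    size = tuple(final_logits.shape[2:])
    total = dice_ce_loss(final_logits, targets) * float(alphas[0])
    for alpha, aux in zip(alphas[1:], aux_logits):
        up = F.interpolate(aux, size)
        total = total + dice_ce_loss(up, targets) * float(alpha)
    return total


# ---------------------------------------------------------------------------
# metrics


def dice_score(pred_labels: np.ndarray, gt_labels: np.ndarray,
               class_id: int) -> float:
    """Dice similarity coefficient of one class: 2|z∧p| / (|z| + |p|).

    Returns 1.0 when the class is absent from both volumes (correctly
    predicted absence).
    """
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError(f"shape mismatch: {pred_labels.shape} vs "
                         f"{gt_labels.shape}")
    p = pred_labels == class_id
    z = gt_labels == class_id
    denom = int(p.sum()) + int(z.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, z).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask with at least one face-neighbour outside it."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    return mask & ~eroded


def hd95(pred_labels: np.ndarray, gt_labels: np.ndarray, class_id: int,
         spacing=(1.0, 1.0, 1.0)) -> float | None:
    """95th-percentile symmetric surface distance in millimetres.

    Boundary voxels (face-connectivity) of each mask are extracted; the
    two directed distance sets are computed with an exact Euclidean
    distance transform honouring anisotropic voxel spacing, and the metric
    is the max of their 95th percentiles (linear-interpolation
    percentile).  Returns ``None`` when either mask is empty.
    """
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError(f"shape mismatch: {pred_labels.shape} vs "
                         f"{gt_labels.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or (spacing <= 0).any():
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    p = pred_labels == class_id
    z = gt_labels == class_id
    if not p.any() or not z.any():
        return None
    bp = _boundary(p)
    bz = _boundary(z)
    # distance from every voxel to the nearest boundary voxel of the other set
    d_to_z = ndimage.distance_transform_edt(~bz, sampling=spacing)
    d_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    forward = d_to_z[bp]
    backward = d_to_p[bz]
    return float(max(np.percentile(forward, 95), np.percentile(backward, 95)))


@dataclass
class MetricReport:
    """Per-class and averaged segmentation quality for one volume pair.

    ``per_class_hd95`` holds ``None`` for classes absent from either
    volume; averages are taken over the classes with defined values and
    exclude the background class when ``include_background`` was off.
    """

    per_class_dsc: dict[int, float]
    per_class_hd95: dict[int, float | None]
    mean_dsc: float
    mean_hd95: float | None

    def to_dict(self) -> dict:
        return {
            "per_class_dsc": {str(k): v for k, v in self.per_class_dsc.items()},
            "per_class_hd95": {str(k): v for k, v in self.per_class_hd95.items()},
            "mean_dsc": self.mean_dsc,
            "mean_hd95": self.mean_hd95,
        }


def evaluate_segmentation(pred_labels: np.ndarray, gt_labels: np.ndarray,
                          num_classes: int, spacing=(1.0, 1.0, 1.0),
                          include_background: bool = False) -> MetricReport:
    """Per-class DSC/HD95 and their means for one prediction/label pair."""
    classes = range(0 if include_background else 1, num_classes)
    dscs: dict[int, float] = {}
    hds: dict[int, float | None] = {}
    for k in classes:
        dscs[k] = dice_score(pred_labels, gt_labels, k)
        hds[k] = hd95(pred_labels, gt_labels, k, spacing)
    defined = [v for v in hds.values() if v is not None]
    return MetricReport(
        per_class_dsc=dscs,
        per_class_hd95=hds,
        mean_dsc=float(np.mean(list(dscs.values()))) if dscs else float("nan"),
        mean_hd95=float(np.mean(defined)) if defined else None,
    )
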