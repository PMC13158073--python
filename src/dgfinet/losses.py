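"""Training objectives for binary segmentation.

The primary objective is the soft Dice loss

    L_Dice = 1 - 2 * sum(y * p) / (sum(y^2) + sum(p^2))

summed over every pixel of the batch, with a small smoothing term added to
numerator and denominator so an all-empty batch yields loss 0.  The
alternative family covers binary cross-entropy, a soft IoU loss, the Tversky
loss (false-negative / false-positive weighted generalization of Dice) and a
distance-transform Hausdorff surrogate.

Every function accepts either plain numpy arrays (returning a float) or
autodiff :class:`~dgfinet.autodiff.Tensor` predictions (returning a scalar
Tensor suitable for ``backward``), so the same formulas drive both the
hand-checkable API and the training loop.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt

from . import autodiff as ad
from .autodiff import Tensor

LOSS_KINDS = ("dice", "bce", "hausdorff", "iou", "tversky")

DEFAULT_EPS = 1e-6


def _as_result(value, was_array):
    return float(value.data) if (was_array and isinstance(value, Tensor)) else value


def _check(pred, target):
    p = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {t.shape}")
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValueError("pred values must lie in [0, 1]")
    return t.astype(np.float64, copy=False)


def dice_loss(pred, target, eps: float = DEFAULT_EPS):
    """Soft Dice loss (squared-sum denominator), batch-summed."""
    t = _check(pred, target)
    was_array = not isinstance(pred, Tensor)
    if was_array:
        pred = np.asarray(pred, dtype=np.float64)
    inter = (pred * t).sum()
    denom = (pred * pred).sum() + (t * t).sum()
    loss = 1.0 - (2.0 * inter + eps) / (denom + eps)
    return _as_result(loss, was_array)


def bce_loss(pred, target, eps: float = 1e-7):
    """Mean pixelwise binary cross-entropy, probabilities clamped at eps."""
    t = _check(pred, target)
    was_array = not isinstance(pred, Tensor)
    if was_array:
        pred = np.asarray(pred, dtype=np.float64)
    p = ad.clip(pred, eps, 1.0 - eps)
    loss = -(t * ad.log(p) + (1.0 - t) * ad.log(1.0 - p)).mean()
    return _as_result(loss, was_array)


def iou_loss(pred, target, eps: float = DEFAULT_EPS):
    """Soft Jaccard loss: 1 - sum(yp) / (sum(y) + sum(p) - sum(yp))."""
    t = _check(pred, target)
    was_array = not isinstance(pred, Tensor)
    if was_array:
        pred = np.asarray(pred, dtype=np.float64)
    inter = (pred * t).sum()
    union = pred.sum() + t.sum() - inter
    loss = 1.0 - (inter + eps) / (union + eps)
    return _as_result(loss, was_array)


def tversky_loss(pred, target, alpha: float = 0.7, beta: float = 0.3,
                 eps: float = DEFAULT_EPS):
    """Tversky loss; alpha weights false negatives, beta false positives.

    At alpha = beta = 0.5 and binary predictions this reduces exactly to the
    Dice loss.
    """
    t = _check(pred, target)
    was_array = not isinstance(pred, Tensor)
    if was_array:
        pred = np.asarray(pred, dtype=np.float64)
    inter = (pred * t).sum()
    fn = ((1.0 - pred) * t).sum()
    fp = (pred * (1.0 - t)).sum()
    loss = 1.0 - (inter + eps) / (inter + alpha * fn + beta * fp + eps)
    return _as_result(loss, was_array)


def hausdorff_loss(pred, target, alpha: float = 2.0, threshold: float = 0.5):
    """Distance-transform surrogate of the Hausdorff distance.

    Squared prediction error weighted by the sum of the unsigned boundary
    distance transforms (raised to ``alpha``) of the ground-truth mask and of
    the thresholded prediction.  The distance maps are treated as constants,
    which makes the surrogate differentiable in the prediction.
    """
    t = _check(pred, target)
    was_array = not isinstance(pred, Tensor)
    if was_array:
        pred = np.asarray(pred, dtype=np.float64)
    p_np = pred.data if isinstance(pred, Tensor) else pred
    pb = (p_np >= threshold).astype(np.float64)
    w = _boundary_dt(t) ** alpha + _boundary_dt(pb) ** alpha
    loss = ((pred - t) ** 2 * w).mean()
    return _as_result(loss, was_array)


def _boundary_dt(mask: np.ndarray) -> np.ndarray:
    """Unsigned distance to the mask boundary, per trailing 2-D slice."""
    m = mask.reshape(-1, mask.shape[-2], mask.shape[-1]) if mask.ndim > 2 \
        else mask[None]
    out = np.zeros_like(m, dtype=np.float64)
    for i, sl in enumerate(m):
        if sl.any() and not sl.all():
            out[i] = distance_transform_edt(sl == 0) + distance_transform_edt(
                sl == 1
            )
        # all-empty or all-full slice: no boundary, zero weight
    return out.reshape(mask.shape)


def alt_loss(kind: str, pred, target, params: dict | None = None):
    """Dispatch over the loss family by name."""
    params = dict(params or {})
    if kind == "dice":
        return dice_loss(pred, target, **params)
    if kind == "bce":
        return bce_loss(pred, target, **params)
    if kind == "iou":
        return iou_loss(pred, target, **params)
    if kind == "tversky":
        return tversky_loss(pred, target, **params)
    if kind == "hausdorff":
        return hausdorff_loss(pred, target, **params)
    raise ValueError(f"unknown loss kind {kind!r}; valid kinds: "
                     f"{', '.join(LOSS_KINDS)}")
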