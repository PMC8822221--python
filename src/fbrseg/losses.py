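"""Training objectives and evaluation metrics.

Three families:

* a class-balanced multiclass Dice loss (immune-cell task), with per-class
  coefficients ``alpha_C`` proportional to inverse pixel frequency so that
  pixel-rich classes are not favoured;
* a boundary-weighted binary cross-entropy (fibroblast task): background
  pixels between nearby cells receive a Gaussian weight
  ``w_B = a * exp(-(d1+d2)^2 / (2 sigma^2))`` of the summed distances to the
  two nearest 8-connected cells, shifted by a class-importance offset
  ``i_B`` so classes stay balanced while touching-cell borders dominate;
* a weighted likelihood metric ``M`` in [0, 1] that reads the same weights
  as an accuracy rather than a loss, plus plain intersection-over-union.

Value functions operate on probabilities; the ``*_grad`` companions return
the derivative with respect to the predicted probabilities and are consumed
by the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import MulticlassMask

DICE_SMOOTH = 1e-6
PROB_EPS = 1e-7

#: defaults for the Gaussian boundary-weight term
BOUNDARY_AMPLITUDE = 100.0
BOUNDARY_SIGMA = 5.0


@dataclass
class ClassBalance:
    """Per-class Dice coefficients alpha_C; non-negative, summing to 1."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if (self.alpha < 0).any():
            raise ValueError("alpha coefficients must be non-negative")
        if not np.isclose(self.alpha.sum(), 1.0):
            raise ValueError("alpha coefficients must sum to 1")


@dataclass
class BoundaryWeightMap:
    """Per-pixel boundary weight w_B and final class-boundary weight w_C-B."""

    w_b: np.ndarray
    w_cb: np.ndarray | None = None
    amplitude: float = BOUNDARY_AMPLITUDE
    sigma: float = BOUNDARY_SIGMA


def class_balance_coefficients(masks: list[MulticlassMask]) -> ClassBalance:
    """Inverse-pixel-frequency class weights over a training mask set.

    Every class must occur at least once; the coefficients are normalized to
    sum to 1, so equally frequent classes get equal weight.
    """
    n_classes = max(m.n_classes for m in masks)
    counts = np.zeros(n_classes, dtype=np.float64)
    for m in masks:
        counts += np.bincount(m.labels.ravel(), minlength=n_classes)
    missing = np.nonzero(counts == 0)[0]
    if missing.size:
        raise ValueError(f"class {missing[0]} absent from the training masks")
    inv = 1.0 / (counts / counts.sum())
    return ClassBalance(inv / inv.sum())


# ---------------------------------------------------------------------------
# multiclass Dice


def _as_batch(arr: np.ndarray) -> np.ndarray:
    """Promote (C, H, W) to (1, C, H, W)."""
    return arr[None] if arr.ndim == 3 else arr


def multiclass_dice_loss(
    y_onehot: np.ndarray, yhat: np.ndarray, balance: ClassBalance
) -> float:
    """Class-balanced Dice loss, averaged over the mini-batch.

    ``y_onehot`` and ``yhat`` are (N, C, H, W) (or unbatched (C, H, W));
    per sample the loss is ``1 - sum_C alpha_C * 2<y_C, p_C> / (|y_C| + |p_C|)``.
    """
    y = _as_batch(np.asarray(y_onehot, dtype=np.float64))
    p = _as_batch(np.asarray(yhat, dtype=np.float64))
    if y.shape != p.shape:
        raise ValueError("shape mismatch between target and prediction")
    inter = (y * p).sum(axis=(2, 3))            # (N, C)
    denom = y.sum(axis=(2, 3)) + p.sum(axis=(2, 3))
    dice = (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)
    per_sample = 1.0 - (balance.alpha[None, :] * dice).sum(axis=1)
    return float(per_sample.mean())


def multiclass_dice_grad(
    y_onehot: np.ndarray, yhat: np.ndarray, balance: ClassBalance
) -> np.ndarray:
    """d(loss)/d(yhat) for the class-balanced Dice loss (same shape as yhat)."""
    y = _as_batch(np.asarray(y_onehot, dtype=np.float64))
    p = _as_batch(np.asarray(yhat, dtype=np.float64))
    n = y.shape[0]
    inter = (y * p).sum(axis=(2, 3)) + DICE_SMOOTH
    denom = y.sum(axis=(2, 3)) + p.sum(axis=(2, 3)) + DICE_SMOOTH
    a = balance.alpha[None, :, None, None]
    num = 2.0 * inter[..., None, None]
    den = denom[..., None, None]
    # d/dp of 2<y,p>/(|y|+|p|) = (2 y den - num) / den^2
    grad = -a * (2.0 * y * den - num) / den**2 / n
    return grad.reshape(np.asarray(yhat).shape)


def total_loss(base: float, weights: list[np.ndarray] | np.ndarray, lam: float = 0.01) -> float:
    """L2-regularized objective ``base + (lam/2) * ||w||^2``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if isinstance(weights, np.ndarray):
        weights = [weights]
    sq = sum(float((w**2).sum()) for w in weights)
    return base + 0.5 * lam * sq


# ---------------------------------------------------------------------------
# boundary weights (touching-fibroblast separation)


def boundary_weight_map(
    label: MulticlassMask | np.ndarray,
    amplitude: float = BOUNDARY_AMPLITUDE,
    sigma: float = BOUNDARY_SIGMA,
) -> BoundaryWeightMap:
    """Gaussian boundary weights from distances to the two nearest cells.

    Cells are 8-connected foreground clusters.  Foreground pixels weigh 0;
    a background pixel at Euclidean distances ``d1 <= d2`` from the two
    nearest cells weighs ``amplitude * exp(-(d1+d2)^2 / (2 sigma^2))``.  With
    a single cell ``d2 = d1``; with no cells the map is identically zero.
    """
    lab = label.labels if isinstance(label, MulticlassMask) else np.asarray(label)
    fg = lab > 0
    comp, n_cells = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_cells == 0:
        return BoundaryWeightMap(np.zeros(lab.shape), amplitude=amplitude, sigma=sigma)
    # one Euclidean distance transform per cell; keep the two smallest
    d1 = np.full(lab.shape, np.inf)
    d2 = np.full(lab.shape, np.inf)
    for cid in range(1, n_cells + 1):
        d = ndimage.distance_transform_edt(comp != cid)
        closer = d < d1
        d2 = np.where(closer, d1, np.minimum(d2, d))
        d1 = np.where(closer, d, d1)
    if n_cells == 1:
        d2 = d1
    w = amplitude * np.exp(-((d1 + d2) ** 2) / (2.0 * sigma**2))
    w[fg] = 0.0
    return BoundaryWeightMap(w, amplitude=amplitude, sigma=sigma)


def background_importance(training_labels: list[np.ndarray], wmaps: list[BoundaryWeightMap]) -> float:
    """i_B: mean of (w_B + 1) over all background pixels of the training set."""
    total, count = 0.0, 0
    for lab, wm in zip(training_labels, wmaps):
        bg = np.asarray(lab) == 0
        if bg.any():
            total += float((wm.w_b[bg] + 1.0).sum())
            count += int(bg.sum())
    if count == 0:
        raise ValueError("training set has no background pixels")
    return total / count


def class_boundary_weights(
    label: MulticlassMask | np.ndarray, wmap: BoundaryWeightMap, i_b: float
) -> BoundaryWeightMap:
    """Final per-pixel weights: 1 on foreground (i_F = 1 by construction,
    since w_B vanishes there), ``w_B + i_B`` on background."""
    lab = label.labels if isinstance(label, MulticlassMask) else np.asarray(label)
    fg = lab > 0
    w_cb = np.where(fg, 1.0, wmap.w_b + i_b)
    return BoundaryWeightMap(wmap.w_b, w_cb=w_cb, amplitude=wmap.amplitude, sigma=wmap.sigma)


# ---------------------------------------------------------------------------
# weighted BCE and the likelihood metric


def _batchify(*arrays: np.ndarray) -> list[np.ndarray]:
    """Promote 2D (H, W) arrays to (1, H, W); pass (N, H, W) through."""
    out = []
    for a in arrays:
        a = np.asarray(a, dtype=np.float64)
        out.append(a[None] if a.ndim == 2 else a)
    return out


def weighted_bce_loss(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    """Pixel-weighted binary cross-entropy, normalized per sample by the
    total weight and averaged over the mini-batch."""
    y, p, wt = _batchify(y, yhat, np.broadcast_to(np.asarray(w, dtype=np.float64), np.shape(yhat)))
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    per_sample = (wt * bce).sum(axis=(1, 2)) / wt.sum(axis=(1, 2))
    return float(per_sample.mean())


def weighted_bce_grad(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """d(loss)/d(yhat) for the weighted BCE (same shape as yhat)."""
    shape = np.shape(yhat)
    y, p, wt = _batchify(y, yhat, np.broadcast_to(np.asarray(w, dtype=np.float64), shape))
    n = y.shape[0]
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    norm = wt.sum(axis=(1, 2), keepdims=True)
    grad = wt * (p - y) / (p * (1.0 - p)) / norm / n
    return grad.reshape(shape)


def custom_metric(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    """Weighted mean of per-pixel likelihoods ``y*p + (1-y)*(1-p)`` in [0, 1].

    Reads the boundary weights as an accuracy: 1 for a perfect prediction,
    0 for a fully inverted one, 0.5 for a maximally uncertain one.
    """
    y, p, wt = _batchify(y, yhat, np.broadcast_to(np.asarray(w, dtype=np.float64), np.shape(yhat)))
    lik = y * p + (1.0 - y) * (1.0 - p)
    per_sample = (wt * lik).sum(axis=(1, 2)) / wt.sum(axis=(1, 2))
    return float(per_sample.mean())


def iou(y: np.ndarray, pred: np.ndarray) -> float:
    """Intersection over union of two binary masks; IoU of two empty masks is 1."""
    a = np.asarray(y).astype(bool)
    b = np.asarray(pred).astype(bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
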