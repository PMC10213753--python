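"""Training recipe for region-specific and multiclass segmentation models.

Region-specific models are trained on binary targets: the *wall* target is
the filled region enclosed by the outer rectal wall boundary (lumen ∪ wall
labels), *lumen* is the lumen label, *fat* the perirectal-fat label.  The
wall annulus alone is available as ``wall_annulus`` for the alternative
reading of the wall task.  The multiclass model is trained on the exhaustive
4-class partition background / lumen / wall / fat (the reference muscle
counts as background — it is never a segmentation target).

Loss is the soft Dice loss ``1 − (2·Σpt + ε) / (Σp + Σt + ε)`` with
ε = 1e-6; the multiclass head averages per-class soft Dice over the
non-background classes.  On-the-fly augmentation applies vertical flips
(up/down, probability 0.5) and rotations uniform in [−30, 30]°, with the
identical geometric transform on image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam
from .nn.layers import F32

EPS = 1e-6

REGIONS = ("wall", "lumen", "fat")
_REGION_LABELS = {
    "wall": (1, 2),  # filled region inside the outer wall boundary
    "lumen": (1,),
    "fat": (3,),
    "wall_annulus": (2,),
}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 0.003
    optimizer: str = "adam"
    loss: str = "dice"
    aug_flip_prob: float = 0.5
    aug_rot_range_deg: tuple[float, float] = (-30.0, 30.0)
    seed: int = 0
    region: str = "wall"

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        lo, hi = self.aug_rot_range_deg
        if not (-180 <= lo <= hi <= 180):
            raise ValueError("rotation range must lie within [-180, 180]")
        if self.optimizer != "adam" or self.loss != "dice":
            raise ValueError("supported recipe is adam + dice loss")
        if self.region not in (*_REGION_LABELS, "multiclass"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class RegionTarget:
    mask: np.ndarray
    region: str
    case_id: str = ""
    slice_index: int = -1


def region_mask(labels: np.ndarray, region: str) -> np.ndarray:
    """Binary mask of one region task from an integer label array (2D or 3D)."""
    if region not in _REGION_LABELS:
        raise ValueError(f"unknown region {region!r}")
    return np.isin(np.asarray(labels), _REGION_LABELS[region])


def make_region_target(labels: np.ndarray, region: str,
                       case_id: str = "", slice_index: int = -1) -> RegionTarget:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {0, 1, 2, 3, 4}
    if bad:
        raise ValueError(f"labels contain unexpected values {sorted(bad)}")
    return RegionTarget(
        mask=region_mask(labels, region).astype(np.uint8),
        region=region,
        case_id=case_id,
        slice_index=slice_index,
    )


def one_hot_targets(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """4-class one-hot partition; muscle (4) maps to background."""
    labels = np.asarray(labels)
    clean = np.where(labels == 4, 0, labels)
    out = np.zeros(labels.shape + (n_classes,), dtype=F32)
    for c in range(n_classes):
        out[..., c] = clean == c
    return out


def _as_values(pred) -> np.ndarray:
    values = getattr(pred, "values", pred)
    return np.asarray(values, dtype=np.float64)


def dice_loss(pred, target, eps: float = EPS, multiclass: bool | None = None) -> float:
    """Soft Dice loss in [0, 1]; ``pred`` may be a ProbabilityMap or array.

    Binary: ``1 − (2Σpt + ε)/(Σp + Σt + ε)`` over all elements.  Multiclass
    (softmax ProbabilityMap, or pred with one more axis than an integer
    target, or ``multiclass=True``): mean of per-class soft Dice over the
    non-background classes 1..K-1, with ``target`` one-hot or integer.
    """
    p = _as_values(pred)
    t = np.asarray(target)
    if multiclass is None:
        multiclass = getattr(pred, "head", None) == "softmax_multiclass" or p.ndim == t.ndim + 1
    if not multiclass:
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
        inter = float((p * t).sum())
        denom = float(p.sum() + t.sum())
        return 1.0 - (2.0 * inter + eps) / (denom + eps)
    k = p.shape[-1]
    if t.shape == p.shape:
        t_hot = t
    elif t.shape == p.shape[:-1]:
        t_hot = one_hot_targets(t, k)
    else:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    losses = []
    for c in range(1, k):
        inter = float((p[..., c] * t_hot[..., c]).sum())
        denom = float(p[..., c].sum() + t_hot[..., c].sum())
        losses.append(1.0 - (2.0 * inter + eps) / (denom + eps))
    return float(np.mean(losses))


def _batch_dice_loss_grad(p: np.ndarray, t: np.ndarray, eps: float = EPS):
    """Per-sample soft Dice averaged over the batch (and, for multiclass,
    over non-background channels); returns (loss, dL/dp)."""
    b = p.shape[0]
    k = p.shape[-1]
    axes = (1, 2)
    grad = np.zeros_like(p)
    if k == 1:
        inter = (p * t).sum(axis=(1, 2, 3))
        sp = p.sum(axis=(1, 2, 3))
        st = t.sum(axis=(1, 2, 3))
        num = 2.0 * inter + eps
        den = sp + st + eps
        loss = float(np.mean(1.0 - num / den))
        coef = 1.0 / b
        grad[...] = -coef * (
            (2.0 * t * den[:, None, None, None] - num[:, None, None, None])
            / (den**2)[:, None, None, None]
        )
        return loss, grad.astype(F32)
    n_fg = k - 1
    total = 0.0
    for c in range(1, k):
        pc, tc = p[..., c], t[..., c]
        inter = (pc * tc).sum(axis=axes)
        num = 2.0 * inter + eps
        den = pc.sum(axis=axes) + tc.sum(axis=axes) + eps
        total += float(np.mean(1.0 - num / den))
        grad[..., c] = (
            -(2.0 * tc * den[:, None, None] - num[:, None, None]) / (den**2)[:, None, None]
        ) / (b * n_fg)
    return total / n_fg, grad.astype(F32)


def augment_pair(image: np.ndarray, mask: np.ndarray, config: TrainConfig, seed):
    """One augmentation draw: vertical (up/down) flip with ``aug_flip_prob``
    and a rotation uniform over ``aug_rot_range_deg``, identical for image
    (linear interp) and mask (nearest; stays integer-valued)."""
    if image.shape != mask.shape:
        raise ValueError("image and mask must share shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img, msk = image, mask
    if rng.random() < config.aug_flip_prob:
        img, msk = img[::-1], msk[::-1]
    lo, hi = config.aug_rot_range_deg
    angle = float(rng.uniform(lo, hi))
    if angle != 0.0:
        img = ndimage.rotate(img.astype(np.float64), angle, reshape=False,
                             order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def train_model(model, train_set, val_set, config: TrainConfig):
    """Train with Adam on the soft Dice loss; returns (model, history).

    ``train_set``/``val_set`` are ``(images, targets)`` with images of shape
    (N, H, W); targets are binary masks (N, H, W) for sigmoid models or
    integer label slices (N, H, W) for the multiclass model.  History is a
    DataFrame with per-epoch mean train loss and val loss.
    """
    config.validate()
    images, targets = train_set
    images = np.asarray(images, dtype=F32)
    targets = np.asarray(targets)
    if len(images) == 0:
        raise ValueError("empty training set")
    multiclass = config.region == "multiclass"
    k = model.n_out
    rng = np.random.default_rng(config.seed)
    model.rng = rng  # one stream drives shuffling, augmentation and dropout
    for ly in model.layers():
        if hasattr(ly, "rng"):
            ly.rng = rng
    opt = Adam(list(model.layers()), lr=config.learning_rate)

    def _prep_batch(idx, augment: bool):
        xs, ts = [], []
        for i in idx:
            img, msk = images[i], targets[i]
            if augment:
                img, msk = augment_pair(img, msk, config, rng)
            xs.append(img)
            ts.append(msk)
        x = np.asarray(xs, dtype=F32)[..., None]
        t = np.asarray(ts)
        if multiclass:
            t = one_hot_targets(t, k)
        else:
            t = t.astype(F32)[..., None]
        return x, t

    def _eval_loss(data) -> float:
        imgs, tgts = data
        if len(imgs) == 0:
            return float("nan")
        losses, weights = [], []
        for s in range(0, len(imgs), config.batch_size):
            idx = range(s, min(s + config.batch_size, len(imgs)))
            x = np.asarray([imgs[i] for i in idx], dtype=F32)[..., None]
            t = np.asarray([tgts[i] for i in idx])
            t = one_hot_targets(t, k) if multiclass else t.astype(F32)[..., None]
            p = model.forward(x, train=False)
            loss, _ = _batch_dice_loss_grad(p.astype(np.float64), t)
            losses.append(loss)
            weights.append(len(x))
        return float(np.average(losses, weights=weights))

    history = []
    n = len(images)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses, epoch_w = [], []
        for s in range(0, n, config.batch_size):
            idx = perm[s : s + config.batch_size]
            x, t = _prep_batch(idx, augment=True)
            p = model.forward(x, train=True)
            loss, grad = _batch_dice_loss_grad(p.astype(np.float64), t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {s // config.batch_size}"
                )
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
            epoch_w.append(len(idx))
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.average(epoch_losses, weights=epoch_w)),
                "val_loss": _eval_loss(val_set) if val_set is not None else float("nan"),
            }
        )
    return model, pd.DataFrame(history)
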