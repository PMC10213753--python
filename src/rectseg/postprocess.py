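"""Probability maps to final masks.

The binarization threshold of each region-specific model is optimized on
the internal validation set by grid search on mean per-case Dice, with the
largest-connected-component step applied inside the search so the
optimized criterion matches deployment.  Multiclass maps are resolved by
per-pixel argmax instead of a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import dice
from .unet import SIGMOID, SOFTMAX, ProbabilityMap


@dataclass
class ThresholdResult:
    threshold: float
    criterion_value: float
    grid: np.ndarray  # (n, 2): threshold, mean per-case Dice
    region: str = ""


def binarize(prob, threshold: float) -> np.ndarray:
    """mask = (values >= threshold) for a sigmoid-head probability map."""
    if isinstance(prob, ProbabilityMap):
        if prob.head != SIGMOID:
            raise ValueError("binarize expects a sigmoid map; use multiclass_to_masks")
        values = prob.values
    else:
        values = np.asarray(prob)
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    return (values >= threshold).astype(np.uint8)


def multiclass_to_masks(prob) -> dict[int, np.ndarray]:
    """Per-pixel argmax of a softmax map -> one binary mask per non-background
    class (mutually exclusive; ties break to the lowest class index)."""
    if isinstance(prob, ProbabilityMap):
        if prob.head != SOFTMAX:
            raise ValueError("multiclass_to_masks expects a softmax map")
        values = prob.values
    else:
        values = np.asarray(prob)
        if values.ndim != 3:
            raise ValueError("expected an (H, W, K) softmax map")
    assign = values.argmax(axis=-1)  # np.argmax ties -> lowest index
    return {c: (assign == c).astype(np.uint8) for c in range(1, values.shape[-1])}


_STRUCTS = {
    "4": ndimage.generate_binary_structure(2, 1),
    "8": ndimage.generate_binary_structure(2, 2),
    "26": ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: np.ndarray, connectivity: str = "8") -> np.ndarray:
    """Retain only the largest connected foreground component.

    ``connectivity`` is ``'8'`` (default) or ``'4'`` for 2D masks, ``'26'``
    for 3D.  Empty input passes through; size ties resolve to the smallest
    component label under scipy's deterministic raster labeling order.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    struct = _STRUCTS[connectivity]
    if struct.ndim != mask.ndim:
        raise ValueError(f"connectivity {connectivity} does not match a {mask.ndim}D mask")
    labeled, n = ndimage.label(mask, structure=struct)
    if n <= 1:
        return mask.astype(np.uint8)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax ties -> smallest label
    return (labeled == keep).astype(np.uint8)


def largest_component_per_slice(volume: np.ndarray, connectivity: str = "8") -> np.ndarray:
    """Apply 2D largest-component retention independently on each slice of a
    (rows, cols, slices) volume."""
    volume = np.asarray(volume).astype(bool)
    out = np.zeros_like(volume, dtype=np.uint8)
    for z in range(volume.shape[2]):
        out[:, :, z] = largest_component(volume[:, :, z], connectivity)
    return out


def postprocess_probability_volume(probs: np.ndarray, threshold: float,
                                   connectivity: str = "8") -> np.ndarray:
    """Binarize a (rows, cols, slices) sigmoid probability volume and keep
    the largest component per slice."""
    hard = (np.asarray(probs) >= threshold)
    return largest_component_per_slice(hard, connectivity)


def optimize_threshold(val_probs, val_targets, grid_step: float = 0.01,
                       region: str = "", connectivity: str = "8") -> ThresholdResult:
    """Grid-search the binarization threshold on the validation set.

    ``val_probs``/``val_targets`` are per-case sigmoid probability volumes
    and binary target volumes (rows, cols, slices).  For each threshold in
    {step, 2·step, …, 1−step} the full deployment pipeline (binarize +
    per-slice largest component) is evaluated by mean per-case Dice; ties
    break to the smallest threshold.
    """
    if len(val_probs) == 0 or len(val_probs) != len(val_targets):
        raise ValueError("need matching, nonempty probability and target lists")
    if not (0 < grid_step <= 0.5):
        raise ValueError("grid step must lie in (0, 0.5]")
    n_steps = int(round(1.0 / grid_step))
    thresholds = np.arange(1, n_steps) * grid_step
    scores = np.empty(len(thresholds))
    for i, th in enumerate(thresholds):
        case_dice = [
            dice(postprocess_probability_volume(p, th, connectivity), t)
            for p, t in zip(val_probs, val_targets)
        ]
        scores[i] = float(np.mean(case_dice))
    best = int(np.argmax(scores))  # argmax ties -> first (smallest threshold)
    return ThresholdResult(
        threshold=float(thresholds[best]),
        criterion_value=float(scores[best]),
        grid=np.column_stack([thresholds, scores]),
        region=region,
    )
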