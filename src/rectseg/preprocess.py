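"""MRI harmonization chain and network-input geometry.

The fixed pipeline order is: resample to a common voxel spacing →
bias-field correction → intensity normalization against the reference
muscle → per-slice center-crop and resize to the network input size.
Label volumes pass only through the nearest-neighbor branches, so no label
value is ever interpolated.

Coordinate convention: voxel indices are 0-based and physical position is
``index * spacing`` (identity orientation).  Resampling maps output index
``i`` to input index ``i * target / source``, which preserves the physical
extent to within one output voxel per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_BIAS_METHODS = ("n4", "smooth_div", "none")


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (0.781, 0.781, 4.0)
    bias_method: str = "smooth_div"
    bias_params: dict = field(default_factory=dict)
    crop_fraction: float = 0.5
    net_input_size: int = 128

    def validate(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if not (0 < self.crop_fraction <= 1):
            raise ValueError("crop_fraction must lie in (0, 1]")
        if self.net_input_size < 16:
            raise ValueError("net_input_size must be >= 16")
        if self.bias_method not in _BIAS_METHODS:
            raise ValueError(f"bias_method must be one of {_BIAS_METHODS}")


def resample_to_spacing(
    volume: np.ndarray,
    spacing,
    target_spacing,
    interp: str = "linear",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample a 3D volume from *spacing* to *target_spacing* (mm).

    ``interp='linear'`` for images, ``'nearest'`` for label volumes.
    Returns (resampled volume, target spacing).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    spacing = np.asarray(spacing, dtype=np.float64)
    target = np.asarray(target_spacing, dtype=np.float64)
    if np.any(spacing <= 0) or np.any(target <= 0):
        raise ValueError("spacings must be positive")
    if interp not in ("linear", "nearest"):
        raise ValueError("interp must be 'linear' or 'nearest'")

    new_shape = np.maximum(np.round(np.array(volume.shape) * spacing / target), 1).astype(int)
    if np.any(new_shape < 2):
        raise ValueError(f"resampled shape {tuple(new_shape)} has < 2 voxels on an axis")
    if np.array_equal(new_shape, volume.shape) and np.allclose(spacing, target):
        return volume.copy(), tuple(float(t) for t in target)

    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, spacing)],
        indexing="ij",
    )
    coords = np.stack(grids)
    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(
        volume.astype(np.float64 if order else volume.dtype),
        coords,
        order=order,
        mode="nearest",
    )
    if order == 0:
        out = out.astype(volume.dtype)
    return out, tuple(float(t) for t in target)


def correct_bias_field(volume: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Suppress smooth multiplicative intensity trends.

    ``smooth_div`` divides by a heavily Gaussian-smoothed copy of the volume
    and rescales to preserve the global mean — self-contained and fast.  The
    divisor kernel is wide (in-plane sigma ≈ 3/8 of the in-plane extent by
    default): a narrower kernel would capture more of the bias but leaks
    anatomy into the divisor, which distorts homogeneous tissue more than
    the bias it removes.  ``n4`` delegates to the N4 algorithm (SimpleITK)
    for full fidelity.  ``none`` is the identity.
    """
    volume = np.asarray(volume, dtype=np.float64)
    method = config.bias_method
    if method == "none":
        return volume.copy()
    if method == "smooth_div":
        frac = float(config.bias_params.get("kernel_fraction", 0.75))
        sigma = (volume.shape[0] * frac / 2.0, volume.shape[1] * frac / 2.0, 1.0)
        smooth = ndimage.gaussian_filter(volume, sigma=sigma, mode="nearest")
        floor = 1e-6 * max(abs(volume).max(), 1.0)
        smooth = np.clip(smooth, floor, None)
        out = volume / smooth
        mean = out.mean()
        if mean > 0:
            out *= volume.mean() / mean
        return out
    if method == "n4":
        if np.any(volume <= 0):
            raise ValueError("n4 (log-domain) requires strictly positive intensities")
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume)
        shrink = int(config.bias_params.get("shrink_factor", 2))
        small = sitk.Shrink(img, [shrink] * 3) if shrink > 1 else img
        corrector = sitk.N4BiasFieldCorrectionImageFilter()
        corrector.Execute(small)
        log_bias = sitk.GetArrayFromImage(corrector.GetLogBiasFieldAsImage(img))
        return volume / np.exp(log_bias)
    raise ValueError(f"unknown bias method {method!r}")


def normalize_by_muscle(volume: np.ndarray, muscle_mask: np.ndarray) -> np.ndarray:
    """Divide the volume by its mean intensity over the reference-muscle mask.

    After normalization the mean over the muscle mask is exactly 1, which
    puts scans from different scanners/institutions on a common intensity
    scale.  The mean is taken over the full 3D mask of the case.
    """
    volume = np.asarray(volume, dtype=np.float64)
    muscle_mask = np.asarray(muscle_mask).astype(bool)
    if muscle_mask.shape != volume.shape:
        raise ValueError("muscle mask and volume shapes differ")
    if not muscle_mask.any():
        raise ValueError("muscle mask is empty")
    mean = volume[muscle_mask].mean()
    if mean <= 0:
        raise ValueError(f"muscle mean must be positive, got {mean}")
    return volume / mean


@dataclass(frozen=True)
class CropResizeMap:
    """Geometry record of a center-crop + resize, sufficient to invert it."""

    orig_shape: tuple[int, int]
    offset: tuple[int, int]
    crop_shape: tuple[int, int]
    out_size: int


def center_crop_resize(
    slice2d: np.ndarray,
    config: PreprocessConfig,
    is_mask: bool = False,
) -> tuple[np.ndarray, CropResizeMap]:
    """Center-crop a slice to ``crop_fraction`` of each axis and resize to
    ``net_input_size`` squared.  Masks use nearest-neighbor (values are
    preserved exactly); images use linear interpolation.  Returns the
    output together with the geometry needed to map predictions back.
    """
    arr = np.asarray(slice2d)
    if arr.ndim != 2:
        raise ValueError("expected a 2D slice")
    h, w = arr.shape
    ch = max(int(round(h * config.crop_fraction)), 1)
    cw = max(int(round(w * config.crop_fraction)), 1)
    if ch < 2 or cw < 2:
        raise ValueError("crop window smaller than 2x2")
    oy, ox = (h - ch) // 2, (w - cw) // 2
    crop = arr[oy : oy + ch, ox : ox + cw]
    size = int(config.net_input_size)
    mapping = CropResizeMap((h, w), (oy, ox), (ch, cw), size)
    out = _resize2d(crop, (size, size), nearest=is_mask)
    if is_mask:
        out = out.astype(arr.dtype)
    return out, mapping


def uncrop_prediction(pred: np.ndarray, mapping: CropResizeMap, is_mask: bool = True) -> np.ndarray:
    """Map a net-sized prediction back onto the pre-crop grid (zeros outside
    the crop window)."""
    pred = np.asarray(pred)
    if pred.shape != (mapping.out_size, mapping.out_size):
        raise ValueError(
            f"prediction shape {pred.shape} does not match mapping size {mapping.out_size}"
        )
    back = _resize2d(pred, mapping.crop_shape, nearest=is_mask)
    out = np.zeros(mapping.orig_shape, dtype=back.dtype)
    oy, ox = mapping.offset
    ch, cw = mapping.crop_shape
    out[oy : oy + ch, ox : ox + cw] = back
    return out


def _resize2d(arr: np.ndarray, out_shape: tuple[int, int], nearest: bool) -> np.ndarray:
    """Resize by sampling the input at output-pixel centers (align-corners
    scaling ``(n_in - 1) / (n_out - 1)`` so the field of view is preserved)."""
    if tuple(arr.shape) == tuple(out_shape):
        return arr.copy()
    scale = [
        (arr.shape[k] - 1) / (out_shape[k] - 1) if out_shape[k] > 1 else 0.0 for k in (0, 1)
    ]
    yy, xx = np.meshgrid(
        np.arange(out_shape[0]) * scale[0],
        np.arange(out_shape[1]) * scale[1],
        indexing="ij",
    )
    order = 0 if nearest else 1
    return ndimage.map_coordinates(
        arr.astype(np.float64 if order else arr.dtype),
        np.stack([yy, xx]),
        order=order,
        mode="nearest",
    )


def preprocess_case(
    image: np.ndarray,
    labels: np.ndarray,
    spacing,
    config: PreprocessConfig,
    muscle_label: int = 4,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Full volume-level chain: resample → bias-correct → muscle-normalize.

    Returns (image, labels, spacing) on the common grid; the per-slice
    crop/resize step is applied separately where network inputs are built.
    """
    config.validate()
    img, sp = resample_to_spacing(image, spacing, config.target_spacing, "linear")
    lab, _ = resample_to_spacing(labels, spacing, config.target_spacing, "nearest")
    img = correct_bias_field(img, config)
    img = normalize_by_muscle(img, lab == muscle_label)
    return img, lab, sp
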