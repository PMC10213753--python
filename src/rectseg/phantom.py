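"""Synthetic rectal-MRI phantom generator.

Real post-treatment pelvic T2w MRI cohorts are private, so every downstream
stage of this package is exercised on seeded synthetic "rectal phantoms"
that reproduce the *structure* of such data without any patient scans:

* nested anatomy on each axial slice — a lumen disk inside a rectal-wall
  annulus inside a perirectal-fat ring — with smooth through-slice and
  angular boundary variation;
* a separate circular "obturator-internus-like" muscle region used as the
  intensity-normalization reference;
* bright-lumen ("rectal gel") versus dark-lumen contrast regimes;
* smooth multiplicative bias fields, additive Gaussian noise, and
  institution-like affine intensity shifts;
* an ``axial_like`` versus ``coronal_like`` in-plane shape regime and a
  ``degraded`` quality mode (doubled noise, halved wall/fat contrast).

Label convention: 0 background, 1 lumen, 2 wall, 3 perirectal fat,
4 reference muscle.  Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_WALL = 2
LABEL_FAT = 3
LABEL_MUSCLE = 4

_QUALITY_MODES = ("standard", "degraded")
_PLANE_MODES = ("axial_like", "coronal_like")


def _default_intensities() -> dict:
    # T2w-like ordering: fluid/gel brightest, fat bright, wall intermediate,
    # muscle moderately dark, background darkest.  Arbitrary units.
    return {
        "background": 20.0,
        "lumen": 220.0,
        "wall": 90.0,
        "fat": 170.0,
        "muscle": 110.0,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom cohort's generating distribution.

    Lengths are in mm.  ``noise_sigma`` is the additive Gaussian noise scale
    as a fraction of the wall intensity; ``bias_amplitude`` is the peak
    multiplicative deviation of the bias field from 1.0.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 12)
    voxel_spacing: tuple[float, float, float] = (0.781, 0.781, 4.0)
    lumen_radius_range: tuple[float, float] = (3.5, 6.0)
    wall_thickness_range: tuple[float, float] = (2.5, 4.5)
    fat_ring_thickness_range: tuple[float, float] = (5.0, 8.0)
    region_intensities: dict = field(default_factory=_default_intensities)
    gel_mode: bool = True
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.2
    bias_smoothness: float = 40.0
    deform_magnitude: float = 1.0
    muscle_offset: float = 30.0
    muscle_radius: float = 5.0
    quality_mode: str = "standard"
    plane_mode: str = "axial_like"

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(shape) != 3 or any(s < 4 for s in shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 4 voxels, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel_spacing must be positive, got {spacing}")
        for name in ("lumen_radius_range", "wall_thickness_range", "fat_ring_thickness_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        for key, val in self.region_intensities.items():
            if val <= 0:
                raise ValueError(f"region intensity {key!r} must be positive, got {val}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.deform_magnitude < 0:
            raise ValueError("deform_magnitude must be >= 0")
        if self.quality_mode not in _QUALITY_MODES:
            raise ValueError(f"quality_mode must be one of {_QUALITY_MODES}")
        if self.plane_mode not in _PLANE_MODES:
            raise ValueError(f"plane_mode must be one of {_PLANE_MODES}")
        # Anatomy-fits-grid check: worst-case outer fat radius plus the random
        # center jitter (2 mm) and boundary deformation must stay inside the
        # in-plane half extent, and the muscle disk must fit while remaining
        # disjoint from the fat ring by >= 1 mm.
        stretch = 1.5 if self.plane_mode == "coronal_like" else 1.0
        r_outer = (
            self.lumen_radius_range[1]
            + self.wall_thickness_range[1]
            + self.fat_ring_thickness_range[1]
        ) * 1.15 * stretch + self.deform_magnitude + 2.0
        half_extent = min(shape[0] * spacing[0], shape[1] * spacing[1]) / 2.0
        if r_outer >= half_extent:
            raise ValueError(
                f"anatomy (outer radius up to {r_outer:.1f} mm) does not fit the "
                f"in-plane half extent {half_extent:.1f} mm"
            )
        if self.muscle_radius <= 0:
            raise ValueError("muscle_radius must be positive")
        if self.muscle_offset - self.muscle_radius < r_outer - 2.0 + 1.0:
            raise ValueError("muscle disk would overlap the fat ring")
        if self.muscle_offset + self.muscle_radius >= half_extent:
            raise ValueError("muscle disk does not fit the grid")

    @property
    def spec_id(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


@dataclass
class PhantomCase:
    """One synthetic scan: paired image + label volume with spacing metadata."""

    image: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    spec_id: str
    seed: int
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share shape")

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _angular_perturbation(rng: np.random.Generator, magnitude: float, n_harmonics: int = 3):
    """Low-order Fourier radius perturbation: amplitudes (mm) and phases.

    Harmonics start at k=2 so contours stay simple (no self-intersection)
    and the centroid is preserved to first order.
    """
    if magnitude <= 0:
        return np.zeros(n_harmonics), np.zeros(n_harmonics), np.arange(2, 2 + n_harmonics)
    amp = rng.uniform(0.2, 1.0, n_harmonics)
    amp *= magnitude / amp.sum()
    phase = rng.uniform(0, 2 * np.pi, n_harmonics)
    return amp, phase, np.arange(2, 2 + n_harmonics)


def _radius_field(theta, base, amp, phase, k):
    r = np.full_like(theta, float(base))
    for a, p, kk in zip(amp, phase, k):
        r = r + a * np.cos(kk * theta + p)
    return r


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Generate one phantom case, deterministically from (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    nr, nc, ns = (int(s) for s in spec.grid_shape)
    sr, sc, ss = (float(s) for s in spec.voxel_spacing)

    center = np.array([(nr - 1) / 2.0 * sr, (nc - 1) / 2.0 * sc])
    center = center + rng.uniform(-2.0, 2.0, 2)

    lumen_r = rng.uniform(*spec.lumen_radius_range)
    wall_t = rng.uniform(*spec.wall_thickness_range)
    fat_t = rng.uniform(*spec.fat_ring_thickness_range)

    # Smooth through-slice modulation of each radial component (up to
    # +/-15 %); geometric perturbation is disabled entirely when
    # deform_magnitude is 0 so the phantom degenerates to a cylinder.
    z_phase = rng.uniform(0, 2 * np.pi, 3)
    z_amp = rng.uniform(0.05, 0.15, 3) * (1.0 if spec.deform_magnitude > 0 else 0.0)

    pert = [_angular_perturbation(rng, spec.deform_magnitude) for _ in range(3)]

    if spec.plane_mode == "coronal_like":
        stretch = np.array([1.0 / 1.5, 1.5])  # elongate along columns
    else:
        stretch = np.array([1.0, 1.0])

    rows = np.arange(nr) * sr
    cols = np.arange(nc) * sc
    Y, X = np.meshgrid(rows - center[0], cols - center[1], indexing="ij")
    U, V = Y * stretch[0], X * stretch[1]
    R = np.hypot(U, V)
    TH = np.arctan2(V, U)

    labels = np.zeros((nr, nc, ns), dtype=np.uint8)
    for z in range(ns):
        zf = 2 * np.pi * z / max(ns - 1, 1)
        m = [1.0 + a * np.cos(zf + p) for a, p in zip(z_amp, z_phase)]
        r_l = np.maximum(_radius_field(TH, lumen_r * m[0], *pert[0]), 0.8)
        t_w = np.maximum(_radius_field(TH, wall_t * m[1], *pert[1]), 0.5)
        t_f = np.maximum(_radius_field(TH, fat_t * m[2], *pert[2]), 0.5)
        r_w = r_l + t_w
        r_f = r_w + t_f
        sl = np.zeros((nr, nc), dtype=np.uint8)
        sl[R < r_f] = LABEL_FAT
        sl[R < r_w] = LABEL_WALL
        sl[R < r_l] = LABEL_LUMEN
        labels[:, :, z] = sl

    # Reference muscle: disk at a fixed offset along +columns, all slices.
    mc = center + np.array([0.0, spec.muscle_offset])
    DM = np.hypot(Y - (mc[0] - center[0]), X - (mc[1] - center[1]))
    muscle = DM < spec.muscle_radius
    for z in range(ns):
        sl = labels[:, :, z]
        sl[muscle & (sl == 0)] = LABEL_MUSCLE

    intens = dict(spec.region_intensities)
    wall_i = float(intens["wall"])
    if spec.gel_mode:
        intens["lumen"] = max(float(intens["lumen"]), 2.0 * wall_i)
    else:
        # without endorectal gel the lumen is nearly isointense with the wall
        intens["lumen"] = 0.95 * wall_i
    noise_sigma = float(spec.noise_sigma)
    if spec.quality_mode == "degraded":
        noise_sigma *= 2.0
        intens["fat"] = wall_i + 0.5 * (float(intens["fat"]) - wall_i)

    lut = np.array(
        [intens["background"], intens["lumen"], intens["wall"], intens["fat"], intens["muscle"]],
        dtype=np.float64,
    )
    image = lut[labels]
    # light in-plane smoothing so boundaries are not single-voxel steps
    image = ndimage.gaussian_filter(image, sigma=(0.5, 0.5, 0.0))

    if spec.bias_amplitude > 0:
        image = apply_bias_field(
            image,
            spec.bias_amplitude,
            spec.bias_smoothness,
            seed=int(rng.integers(0, 2**31 - 1)),
            spacing=(sr, sc, ss),
        )
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma * wall_i, image.shape)

    case = PhantomCase(
        image=image.astype(np.float32),
        labels=labels,
        spacing=(sr, sc, ss),
        spec_id=spec.spec_id,
        seed=int(seed),
    )
    for lab in (LABEL_LUMEN, LABEL_WALL, LABEL_FAT, LABEL_MUSCLE):
        if not np.any(case.labels == lab):
            raise RuntimeError(f"generated phantom lost label {lab}; spec too tight for grid")
    return case


def generate_cohort(
    spec: PhantomSpec,
    n_cases: int,
    seed: int,
    split: str = "train",
    out_dir: str | None = None,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate ``n_cases`` phantoms with per-case seeds derived from *seed*.

    If *out_dir* is given, volumes are written there as NIfTI and the
    manifest paths point at the files; otherwise paths are the logical
    filenames the cases would be written to.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases).astype(np.int64)
    cases, rows = [], []
    for i, cs in enumerate(child_seeds):
        case_id = f"{split}_{i:04d}"
        try:
            case = generate_phantom(spec, int(cs))
        except Exception as exc:  # surface which case failed
            raise RuntimeError(f"case {i} ({case_id}) failed to generate: {exc}") from exc
        case.case_id = case_id
        img_name = f"{case_id}_image.nii.gz"
        lbl_name = f"{case_id}_labels.nii.gz"
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            io.write_volume(os.path.join(out_dir, img_name), case.image, case.spacing)
            io.write_volume(os.path.join(out_dir, lbl_name), case.labels, case.spacing)
        rows.append(
            {
                "case_id": case_id,
                "image_path": img_name,
                "label_path": lbl_name,
                "split": split,
                "spec_id": spec.spec_id,
                "seed": int(cs),
            }
        )
        cases.append(case)
    manifest = pd.DataFrame(rows, columns=io.MANIFEST_COLUMNS)
    if out_dir is not None:
        io.write_manifest(os.path.join(out_dir, "manifest.csv"), manifest)
    return cases, manifest


def apply_bias_field(
    image: np.ndarray,
    amplitude: float,
    smoothness: float,
    seed: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Multiply *image* by a smooth positive field in [1-amplitude, 1+amplitude].

    The field is Gaussian-correlated with correlation length *smoothness*
    (mm), rescaled so its extrema hit the band edges exactly; amplitude 0
    returns the input unchanged.
    """
    if not (0 <= amplitude < 1):
        raise ValueError("amplitude must lie in [0, 1)")
    image = np.asarray(image, dtype=np.float64)
    if amplitude == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(image.shape)
    sigma = [max(float(smoothness) / float(s), 1e-6) for s in spacing[: image.ndim]]
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    f = f - f.mean()
    peak = np.max(np.abs(f))
    if peak == 0:
        return image.copy()
    field = 1.0 + amplitude * (f / peak)
    return image * field


def shift_institution(case: PhantomCase, scale: float, offset: float) -> PhantomCase:
    """Affine intensity shift (scale*image + offset) emulating an institution
    change; labels and geometry are untouched."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return replace(
        case,
        image=(case.image.astype(np.float64) * scale + offset).astype(np.float32),
        labels=case.labels.copy(),
    )
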