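# Methods

This note documents the models, algorithms and design decisions behind
`rectseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic benchmark
does and does not establish.

## 1. Synthetic rectal phantoms

**Anatomy model.** Each case is a 3D volume whose axial slices contain
concentric, perturbed rings: a lumen disk of radius `r_L(θ, z)`, a wall
annulus of thickness `t_W(θ, z)` and a perirectal-fat ring of thickness
`t_F(θ, z)`, rasterized from the cumulative radii `r_L`, `r_L + t_W`,
`r_L + t_W + t_F`. Because thicknesses are strictly positive everywhere,
the lumen ⊂ wall ⊂ fat nesting holds by construction on every slice. A
circular "muscle" disk at a fixed in-plane offset provides the
intensity-normalization reference and never overlaps the rings (enforced at
spec validation).

**Boundary perturbation.** Radii are perturbed by a low-order Fourier
series in θ (harmonics 2–4, total amplitude `deform_magnitude`, in mm) and
modulated smoothly through slices (≤ ±15 %). Harmonics start at k = 2 so
contours remain simple; setting `deform_magnitude = 0` collapses the case
to an exact cylinder, which the closed-form geometry tests exploit.

**Intensity model.** Region mean intensities default to a T2w-like
ordering (fluid/gel ≫ fat > muscle > wall ≫ background, arbitrary units).
`gel_mode=True` forces the lumen to ≥ 2× the wall intensity (endorectal gel
brightens the lumen); `gel_mode=False` places it within 5 % of the wall,
making the lumen boundary nearly invisible — the regime where lumen
segmentation is genuinely hard. `quality_mode="degraded"` doubles the
noise and halves the wall/fat contrast. The label image is lightly smoothed
in-plane (σ = 0.5 px) so boundaries are not single-voxel steps; eroded
region cores retain the configured means, which the intensity contracts
assert.

**Corruptions.** The bias field is a Gaussian-correlated random field
(correlation length `bias_smoothness`, mm) affinely rescaled so its extrema
hit `1 ± bias_amplitude` exactly; noise is additive Gaussian with standard
deviation `noise_sigma ×` wall intensity. Institution shifts are affine
intensity maps `scale·I + offset` with labels untouched.

**What the phantoms are not.** No k-space or pulse-sequence physics, no
Rician noise floor (additive Gaussian is adequate at the simulated SNRs and
could be swapped behind the same interface), no tumor/fibrosis texture, no
partial-volume model beyond the boundary smoothing, and `coronal_like`
merely elongates in-plane shape statistics (factor 1.5) rather than
reformatting a 3D volume — which is all a 2D slice-wise network can see
anyway. Consequently, passing tests show the *pipeline* works and learns;
they say nothing about absolute performance on patient MRI.

## 2. Harmonization chain

Order is fixed: resample → bias-correct → muscle-normalize → center-crop +
resize. Coordinates are deliberately simple: voxel indices are 0-based,
physical position is `index × spacing`, no orientation matrices. Resampling
maps output index `i` to input index `i·target/source` (linear for images,
nearest for labels, so label values are never interpolated).

**Bias correction.** `n4` delegates to SimpleITK's N4 implementation — the
fidelity option. `smooth_div`, the self-contained default used throughout
the tests, divides the volume by a wide Gaussian-smoothed copy of itself
and rescales to preserve the global mean. The divisor kernel width matters:
a kernel of ~1/4 of the in-plane extent leaks anatomy into the divisor and
can *raise* the coefficient of variation of homogeneous tissue when the
underlying bias is weak. Sweeping the kernel on biased phantoms (amplitude
0.4) showed the residual CV on eroded homogeneous cores is minimized for an
in-plane σ around 3/8 of the extent (0.028 → 0.013, with 99/100 seeded
fields improved), so `kernel_fraction` defaults to 0.75 (σ = 0.75 ×
extent/2). The trade-off is explicit: a wider divisor removes only the
smoothest bias component but injects almost no anatomy.

**Muscle normalization.** Division by the mean intensity over the full 3D
muscle mask of the case (not per slice); after it the muscle-mask mean is
exactly 1 and the operation is idempotent and scale-invariant. Division —
rather than a z-score against the muscle — is the simplest reading of
normalizing "with respect to the mean intensity" of a reference muscle, and
is what is implemented.

**Crop/resize.** Center crop of `crop_fraction` (default 0.5) per in-plane
axis, then resize to `net_input_size`² (images bilinear, masks nearest).
The geometry record is kept so predictions can be mapped back; all distance
metrics are computed on the pre-crop resampled grid, so reported mm never
depend on the network input size. Resizing samples output-pixel centers
with align-corners scaling `(n_in − 1)/(n_out − 1)`.

## 3. Networks and training

A standard 2D U-Net: `depth` contracting levels (two 3×3 conv + batch-norm
+ ReLU, dropout after the second conv, 2×2 max-pool), a bottleneck block,
and mirrored expanding levels (2×2 transposed convolution, skip
concatenation, two 3×3 conv + batch-norm + ReLU). 'Same' padding keeps
128 → 128. Channel widths double per level from `base_filters`. Defaults
`depth=4`, `base_filters=16` are declared choices, not tuned values — at
full scale the best widths are data-dependent and would be selected by a
grid search on the validation split. Dropout rate 0.2; its placement
(after each block's second convolution) is a choice of this package.

The heads: region-specific models end in a 1-channel sigmoid; the
multiclass model in a 4-channel softmax over background/lumen/wall/fat
(softmax needs an exhaustive partition, so background is explicit and the
reference muscle counts as background). Both heads share every other
parameter shape, so the two arms differ only in the output layer — asserted
by parameter accounting in the tests.

**Engine.** The layers, backpropagation and Adam are implemented directly
on NumPy (NHWC float32; convolutions as sums of shifted channel-matmuls so
the arithmetic runs in BLAS). Gradients of every layer type are verified
against central finite differences in the test suite. Training is
single-threaded deterministic given the seed: one `numpy` Generator drives
shuffling, augmentation and dropout.

**Region targets.** `wall` is the filled region inside the outer wall
boundary (lumen ∪ wall labels) — the boundary-oriented reading of the wall
task; the bare annulus is available as `wall_annulus` behind the same
interface for the alternative reading. `lumen` and `fat` are their labels.
Slices with empty targets stay in training (fat/lumen can vanish on end
slices); the ε = 1e-6 in the soft Dice keeps the loss defined there.

**Recipe.** Soft Dice loss (per-sample, averaged over the batch; the
multiclass loss averages per-class soft Dice over the three non-background
classes), Adam at constant lr 0.003, batch 16, 50 epochs at full scale;
augmentation applies an up/down flip with p = 0.5 and a rotation uniform in
[−30°, 30°] identically to image (bilinear) and mask (nearest).
Final-epoch weights are returned; no early stopping or schedule.

## 4. Post-processing

Region-specific probability maps are binarized at a threshold grid-searched
on the validation set over {0.01, …, 0.99}, maximizing mean per-case Dice
with the largest-connected-component step applied *inside* the search so
the optimized criterion matches deployment; ties break to the smallest
threshold. Multiclass maps are resolved by per-pixel argmax (ties to the
lowest class index). Connected-component analysis uses 8-connectivity per
2D slice by default (the models and thresholds are 2D); a 26-connectivity
3D mode exists behind a flag.

## 5. Metrics

* **Dice** on stacked 3D masks. Conventions: both masks empty → 1.0
  (perfect agreement on absence); exactly one empty → 0.0.
* **Boundaries** are sub-pixel 0.5-level contours (marching squares),
  scaled to mm; only the largest contour per slice enters the distance
  metrics, consistent with post-CCA single-component masks.
* **Hausdorff distance**: symmetric max-min over contour point sets.
* **Fréchet distance**: the discrete Fréchet distance via the standard
  dynamic-programming coupling recurrence (numba-compiled). The
  discretization error relative to the continuous definition is bounded by
  one contour-segment length, ≤ one voxel diagonal by construction. For
  closed contours the distance is minimized over cyclic start-point shifts
  (every `max(1, n/64)`-th shift; exact all-shift minimization behind a
  flag) and over traversal orientation. FD ≥ HD always holds, since any
  coupling covers both point sets.
* **Per-case aggregation** is pseudo-volumetric: Dice over the 3D stacks;
  HD/FD per slice, median across slices where both masks are nonempty
  (slices where exactly one is empty are excluded from distance medians but
  count fully in the 3D Dice). Distances are reported in mm by default,
  voxel units behind a flag.

## 6. Statistics

Cohort tables report the median of each metric with the standard deviation
alongside, both labeled — published "median ± x" tables rarely define the
±, so nothing is silently assumed. Arm comparisons use the two-sided
Wilcoxon rank-sum test: exact enumeration of all C(n₁+n₂, n₁) rank
assignments when n₁+n₂ ≤ 12 without ties (cross-checked exhaustively
against an independent implementation), otherwise a normal approximation
with midranks, tie-corrected variance and 0.5 continuity correction.
Bonferroni threshold α/m with m = 6 comparisons per metric by default,
consistent with the conventional 0.008 cutoff at α = 0.05.

## 7. Experiment recipes and scaled-down conditions

`run_experiment` mirrors the study design: train/val cohorts, three
region-specific models + one multiclass model from identical configs,
validation thresholds, held-out cohorts, metrics + report + provenance
(every seed fans out deterministically from one global seed, so reruns are
bit-identical single-threaded).

Held-out cohort analogues: `c1_like` is in-distribution (ground truth plays
reader 1; a simulated second reader — smooth boundary-noise perturbation of
the truth masks, largest component kept — exercises the inter-reader
machinery); the out-of-distribution cohort is a *stratified mixture* with
one acquisition shift per stratum (coronal-like, no gel, degraded quality),
matching how such robustness sub-cohorts are grouped in practice;
compounding all three shifts onto every case makes the no-gel lumen task
degenerate on phantoms (no texture cues remain once the lumen is
isointense with the wall and noise is doubled). `c3_like` applies an
affine institution-style intensity shift.

The scaled-down conditions used by the tests and the acceptance script —
64×64 slices (1 mm in-plane), 4-slice volumes, depth-2 `base_filters=8`
U-Net, 60 train / 10 val cases, 15 epochs, batch 8, no crop — are the
package's declared small-problem sizes; they were chosen so a full
experiment is a few minutes of single-CPU NumPy while still leaving the
tasks non-trivial. At these conditions the region-specific wall and lumen
models reach median test Dice ≳ 0.95 in distribution. The multiclass model
is markedly less stable at small budgets (its mean-over-classes Dice loss
gives each region only a third of the gradient signal), which reproduces
the direction of the region-specific advantage, most dramatically on the
lumen.

## 8. Known limitations

* Phantom realism as in §1; absolute metric values on phantoms do not
  transfer to patient MRI.
* The NumPy engine targets small 2D problems; it is single-threaded and
  has no GPU path. Full-scale (128×128, depth-4, 50-epoch) training is
  supported but slow.
* `smooth_div` removes only smooth multiplicative trends; strong
  anatomy-correlated bias requires `n4`.
* The simulated second reader perturbs truth masks with spatially smooth
  noise; real inter-reader disagreement is structured (systematic boundary
  interpretation differences), so inter-reader numbers on phantoms are
  optimistic.
* Rank-sum (not signed-rank) is used even for paired-looking designs,
  following the reference reporting convention.
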