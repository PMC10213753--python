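"""End-to-end experiment recipes on phantom cohorts.

``run_experiment`` mirrors the study design: generate seeded phantom
cohorts (train / validation / held-out test cohorts), run the harmonization
chain, train three region-specific models and one multiclass model from
identical configurations (only the output head differs), optimize the
binarization thresholds on the validation split, predict and evaluate every
test cohort pseudo-volumetrically, and emit ``metrics.csv``,
``report.csv`` and a provenance JSON.

Test-cohort analogues of the study's held-out sub-cohorts:

* ``c1_like`` — in-distribution phantoms.  Ground truth plays the role of
  reader 1; a simulated second reader is obtained by perturbing the truth
  masks with smooth boundary noise, so the inter-reader machinery runs.
* ``c2_like`` — out-of-distribution phantoms (degraded quality, coronal-like
  shapes, no endorectal gel).
* ``c3_like`` — institution-shifted phantoms (affine intensity shift).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .metrics import MetricRecord, evaluate_case
from .phantom import PhantomSpec, generate_cohort, shift_institution
from .postprocess import (
    largest_component_per_slice,
    optimize_threshold,
    postprocess_probability_volume,
)
from .preprocess import PreprocessConfig, center_crop_resize, preprocess_case, uncrop_prediction
from .stats_eval import compare_models, records_to_frame, summarize_cohort
from .train import REGIONS, TrainConfig, region_mask, train_model
from .unet import SIGMOID, SOFTMAX, UNetConfig, build_unet

REGION_MODELS = REGIONS  # ("wall", "lumen", "fat")


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    seed: int = 0
    out_dir: str = "results"
    n_train: int = 24
    n_val: int = 6
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    test_cohorts: dict = field(default_factory=dict)  # name -> {"n": int, "spec": PhantomSpec, ...}
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    grid_step: float = 0.01
    reader_sigma_px: float = 1.0
    save_volumes: bool = False

    def validate(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ValueError("n_train and n_val must be >= 1")
        self.phantom.validate()
        self.preprocess.validate()
        self.unet.validate()
        self.train.validate()
        for name, cohort in self.test_cohorts.items():
            if cohort.get("n", 0) < 1:
                raise ValueError(f"test cohort {name!r} needs n >= 1")
            cohort.get("spec", self.phantom).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = _spec_from_dict(kwargs["phantom"])
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**_tupled(kwargs["preprocess"], ["target_spacing"]))
        if "unet" in kwargs:
            kwargs["unet"] = UNetConfig(**kwargs["unet"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**_tupled(kwargs["train"], ["aug_rot_range_deg"]))
        cohorts = {}
        for name, cohort in (kwargs.get("test_cohorts") or {}).items():
            cohort = dict(cohort)
            if "spec" in cohort:
                cohort["spec"] = _spec_from_dict(cohort["spec"])
            cohorts[name] = cohort
        kwargs["test_cohorts"] = cohorts
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def _spec_from_dict(d) -> PhantomSpec:
    if isinstance(d, PhantomSpec):
        return d
    d = _tupled(
        d,
        [
            "grid_shape",
            "voxel_spacing",
            "lumen_radius_range",
            "wall_thickness_range",
            "fat_ring_thickness_range",
        ],
    )
    return PhantomSpec(**d)


# ---------------------------------------------------------------------------
# case preparation


@dataclass
class PreparedCase:
    """One case after the harmonization chain, ready for the network."""

    case_id: str
    net_images: np.ndarray  # (Z, S, S) float32 network-input slices
    net_labels: np.ndarray  # (Z, S, S) label slices on the network grid
    mappings: list  # per-slice CropResizeMap
    labels_grid: np.ndarray  # (H, W, Z) labels on the resampled pre-crop grid
    spacing: tuple[float, float, float]


def prepare_case(case, config: PreprocessConfig) -> PreparedCase:
    img, lab, sp = preprocess_case(case.image, case.labels, case.spacing, config)
    net_imgs, net_labs, maps = [], [], []
    for z in range(img.shape[2]):
        im, mapping = center_crop_resize(img[:, :, z], config, is_mask=False)
        lb, _ = center_crop_resize(lab[:, :, z], config, is_mask=True)
        net_imgs.append(im)
        net_labs.append(lb)
        maps.append(mapping)
    return PreparedCase(
        case_id=case.case_id,
        net_images=np.asarray(net_imgs, dtype=np.float32),
        net_labels=np.asarray(net_labs),
        mappings=maps,
        labels_grid=lab,
        spacing=sp,
    )


def training_arrays(prepared: list[PreparedCase]):
    """Stack prepared cases into (images, label_slices) slice arrays."""
    imgs = np.concatenate([p.net_images for p in prepared], axis=0)
    labs = np.concatenate([p.net_labels for p in prepared], axis=0)
    return imgs, labs


def predict_probability_volume(model, prepared: PreparedCase, batch_size: int = 16) -> np.ndarray:
    """Sigmoid model -> (H, W, Z) probability volume on the pre-crop grid."""
    probs = model.predict(prepared.net_images, batch_size=batch_size)[..., 0]
    planes = [
        uncrop_prediction(probs[z], prepared.mappings[z], is_mask=False)
        for z in range(len(probs))
    ]
    return np.stack(planes, axis=-1)


def predict_multiclass_masks(model, prepared: PreparedCase, batch_size: int = 16) -> dict:
    """Softmax model -> per-region binary volumes on the pre-crop grid.

    Per-pixel argmax resolves the partition; the *wall* region mask is the
    filled union of the lumen and wall classes, matching the region-specific
    wall target; largest-component retention is applied per slice.
    """
    probs = model.predict(prepared.net_images, batch_size=batch_size)
    assign = probs.argmax(axis=-1)  # (Z, S, S)
    class_masks = {
        "lumen": assign == 1,
        "wall_annulus": assign == 2,
        "fat": assign == 3,
    }
    region_vols = {}
    for region in REGION_MODELS:
        if region == "wall":
            net_mask = class_masks["lumen"] | class_masks["wall_annulus"]
        elif region == "lumen":
            net_mask = class_masks["lumen"]
        else:
            net_mask = class_masks["fat"]
        planes = [
            uncrop_prediction(net_mask[z].astype(np.uint8), prepared.mappings[z], is_mask=True)
            for z in range(len(net_mask))
        ]
        region_vols[region] = largest_component_per_slice(np.stack(planes, axis=-1))
    return region_vols


def simulate_reader(mask: np.ndarray, rng: np.random.Generator,
                    sigma_px: float = 1.0) -> np.ndarray:
    """Simulated second annotator: smooth boundary-noise perturbation of a
    binary volume (per slice), emulating small inter-reader disagreement."""
    mask = np.asarray(mask).astype(float)
    out = np.zeros_like(mask, dtype=np.uint8)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        smooth = ndimage.gaussian_filter(sl, sigma=1.0)
        noise = ndimage.gaussian_filter(rng.standard_normal(sl.shape), sigma=3.0)
        peak = np.abs(noise).max()
        if peak > 0:
            noise = noise / peak
        wobbled = (smooth + 0.25 * sigma_px * noise) >= 0.5
        if not wobbled.any():
            wobbled = sl >= 0.5
        out[:, :, z] = wobbled
    return largest_component_per_slice(out)


# ---------------------------------------------------------------------------
# experiment driver


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s % (2**31 - 1)) for name, s in zip(names, state)}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline; returns a result bundle and writes
    metrics.csv, report.csv, thresholds.json, history CSVs and
    provenance.json under ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    model_names = [*REGION_MODELS, "multiclass"]
    seed_names = (
        ["cohort_train", "cohort_val", "reader"]
        + [f"cohort_{n}" for n in config.test_cohorts]
        + [f"init_{m}" for m in model_names]
        + [f"train_{m}" for m in model_names]
    )
    seeds = _stage_seeds(config.seed, seed_names)

    # --- cohorts ---------------------------------------------------------
    def _stage(stage, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"[stage: {stage}] {exc}") from exc

    train_cases, train_manifest = _stage(
        "phantom", generate_cohort, config.phantom, config.n_train, seeds["cohort_train"], "train"
    )
    val_cases, val_manifest = _stage(
        "phantom", generate_cohort, config.phantom, config.n_val, seeds["cohort_val"], "val"
    )
    test_sets = {}
    for name, cohort in config.test_cohorts.items():
        spec = cohort.get("spec", config.phantom)
        cases, manifest = _stage(
            "phantom", generate_cohort, spec, int(cohort["n"]), seeds[f"cohort_{name}"], "test"
        )
        scale, offset = cohort.get("scale", 1.0), cohort.get("offset", 0.0)
        if scale != 1.0 or offset != 0.0:
            cases = [shift_institution(c, scale, offset) for c in cases]
        test_sets[name] = (cases, manifest)

    # --- preprocessing ---------------------------------------------------
    prep_train = [_stage("preprocess", prepare_case, c, config.preprocess) for c in train_cases]
    prep_val = [_stage("preprocess", prepare_case, c, config.preprocess) for c in val_cases]
    prep_test = {
        name: [_stage("preprocess", prepare_case, c, config.preprocess) for c in cases]
        for name, (cases, _) in test_sets.items()
    }
    train_imgs, train_labs = training_arrays(prep_train)
    val_imgs, val_labs = training_arrays(prep_val)

    # --- training: three region-specific models + one multiclass --------
    models, histories, thresholds = {}, {}, {}
    for name in model_names:
        head = SOFTMAX if name == "multiclass" else SIGMOID
        ucfg = replace(config.unet, head=head, input_size=config.preprocess.net_input_size)
        tcfg = replace(config.train, region=name if name != "multiclass" else "multiclass",
                       seed=seeds[f"train_{name}"])
        model = _stage("build", build_unet, ucfg, seeds[f"init_{name}"])
        if name == "multiclass":
            tr_t, va_t = train_labs, val_labs
        else:
            tr_t = region_mask(train_labs, name).astype(np.uint8)
            va_t = region_mask(val_labs, name).astype(np.uint8)
        model, hist = _stage(
            "train", train_model, model, (train_imgs, tr_t), (val_imgs, va_t), tcfg
        )
        models[name] = model
        histories[name] = hist
        hist.to_csv(os.path.join(config.out_dir, f"history_{name}.csv"), index=False)

    # --- threshold optimization on validation ----------------------------
    for name in REGION_MODELS:
        val_probs = [predict_probability_volume(models[name], p) for p in prep_val]
        val_targets = [region_mask(p.labels_grid, name) for p in prep_val]
        thresholds[name] = _stage(
            "postprocess", optimize_threshold, val_probs, val_targets, config.grid_step, name
        )
    with open(os.path.join(config.out_dir, "thresholds.json"), "w") as fh:
        json.dump(
            {k: {"threshold": v.threshold, "criterion_value": v.criterion_value}
             for k, v in thresholds.items()},
            fh,
            indent=2,
        )

    # --- prediction + evaluation on every test cohort --------------------
    reader_rng = np.random.default_rng(seeds["reader"])
    records: list[MetricRecord] = []
    for cohort_name, prepared_cases in prep_test.items():
        for prep in prepared_cases:
            truth = {r: region_mask(prep.labels_grid, r) for r in REGION_MODELS}
            rs_pred = {}
            for region in REGION_MODELS:
                probs = predict_probability_volume(models[region], prep)
                rs_pred[region] = postprocess_probability_volume(
                    probs, thresholds[region].threshold
                )
            mc_pred = predict_multiclass_masks(models["multiclass"], prep)
            refs = {"truth": truth}
            if cohort_name == "c1_like":
                refs["reader2"] = {
                    r: simulate_reader(truth[r], reader_rng, config.reader_sigma_px)
                    for r in REGION_MODELS
                }
            for region in REGION_MODELS:
                for ref_name, ref in refs.items():
                    records.append(
                        evaluate_case(
                            rs_pred[region], ref[region], prep.spacing, region,
                            case_id=f"{cohort_name}/{prep.case_id}",
                            comparison=f"{cohort_name}:region_specific_vs_{ref_name}",
                        )
                    )
                    records.append(
                        evaluate_case(
                            mc_pred[region], ref[region], prep.spacing, region,
                            case_id=f"{cohort_name}/{prep.case_id}",
                            comparison=f"{cohort_name}:multiclass_vs_{ref_name}",
                        )
                    )
                if cohort_name == "c1_like":
                    records.append(
                        evaluate_case(
                            refs["reader2"][region], truth[region], prep.spacing, region,
                            case_id=f"{cohort_name}/{prep.case_id}",
                            comparison=f"{cohort_name}:inter_reader",
                        )
                    )

    metrics_df = records_to_frame(records)
    metrics_df.to_csv(os.path.join(config.out_dir, "metrics.csv"), index=False)

    # --- summaries and region-specific vs multiclass comparison ----------
    summaries = summarize_cohort(records)
    summary_df = pd.DataFrame([asdict(s) for s in summaries])
    comparisons = {}
    for cohort_name in config.test_cohorts:
        arm_a = metrics_df[
            metrics_df.comparison == f"{cohort_name}:region_specific_vs_truth"
        ]
        arm_b = metrics_df[metrics_df.comparison == f"{cohort_name}:multiclass_vs_truth"]
        if len(arm_a) and len(arm_b):
            comparisons[cohort_name] = compare_models(
                arm_a, arm_b, label_a="region_specific", label_b="multiclass"
            )
    report_rows = []
    for cohort_name, rep in comparisons.items():
        rows = rep.rows.copy()
        rows.insert(0, "cohort", cohort_name)
        report_rows.append(rows)
    report_df = (
        pd.concat(report_rows, ignore_index=True) if report_rows else pd.DataFrame()
    )
    report_df.to_csv(os.path.join(config.out_dir, "report.csv"), index=False)
    summary_df.to_csv(os.path.join(config.out_dir, "summary.csv"), index=False)

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "thresholds": {k: v.threshold for k, v in thresholds.items()},
    }
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    return {
        "models": models,
        "histories": histories,
        "thresholds": thresholds,
        "metrics": metrics_df,
        "summary": summary_df,
        "report": report_df,
        "comparisons": comparisons,
        "provenance": provenance,
        "manifests": {
            "train": train_manifest,
            "val": val_manifest,
            **{k: m for k, (_, m) in test_sets.items()},
        },
    }


# ---------------------------------------------------------------------------
# canonical scaled-down configurations


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Phantom spec for the 64x64 scaled-down experiments."""
    base = dict(
        grid_shape=(64, 64, 4),
        voxel_spacing=(1.0, 1.0, 4.0),
        lumen_radius_range=(3.0, 5.0),
        wall_thickness_range=(2.5, 4.0),
        fat_ring_thickness_range=(4.0, 6.0),
        muscle_offset=24.0,
        muscle_radius=4.0,
        bias_amplitude=0.15,
        bias_smoothness=30.0,
        noise_sigma=0.05,
        deform_magnitude=0.8,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def degraded_phantom_spec(**overrides) -> PhantomSpec:
    """Out-of-distribution phantom spec: degraded quality, no endorectal
    gel, coronal-like elongation.  The anatomy is proportionally smaller so
    the 1.5x in-plane stretch still fits the 64 mm grid beside the
    reference-muscle disk."""
    base = dict(
        lumen_radius_range=(2.5, 4.0),
        wall_thickness_range=(2.0, 3.0),
        fat_ring_thickness_range=(3.0, 4.5),
        muscle_offset=26.0,
        quality_mode="degraded",
        gel_mode=False,
        plane_mode="coronal_like",
    )
    base.update(overrides)
    return small_phantom_spec(**base)


def c2_like_specs() -> list[PhantomSpec]:
    """The three out-of-distribution strata of the robustness cohort, one
    acquisition shift per stratum (coronal-like view, no endorectal gel,
    visibly degraded quality), mirroring how such sub-cohorts are grouped
    in practice rather than compounding every shift onto every case."""
    coronal = degraded_phantom_spec(quality_mode="standard", gel_mode=True)
    nogel = small_phantom_spec(gel_mode=False)
    degraded = small_phantom_spec(quality_mode="degraded")
    return [coronal, nogel, degraded]


def _small_shared(seed: int, epochs: int, n_train: int, n_val: int,
                  test_cohorts: dict, name: str, out_dir: str) -> ExperimentConfig:
    return ExperimentConfig(
        name=name,
        seed=seed,
        out_dir=out_dir,
        n_train=n_train,
        n_val=n_val,
        phantom=small_phantom_spec(),
        test_cohorts=test_cohorts,
        preprocess=PreprocessConfig(
            target_spacing=(1.0, 1.0, 4.0),
            bias_method="smooth_div",
            crop_fraction=1.0,
            net_input_size=64,
        ),
        unet=UNetConfig(input_size=64, depth=2, base_filters=8, dropout_rate=0.2),
        train=TrainConfig(epochs=epochs, batch_size=8, learning_rate=0.003, seed=seed),
        grid_step=0.01,
    )


def tiny_config(seed: int = 0, out_dir: str = "results/tiny") -> ExperimentConfig:
    """Smoke-scale experiment: 24 train / 6 val cases, one in-distribution
    test cohort, 5 epochs."""
    return _small_shared(
        seed,
        epochs=5,
        n_train=24,
        n_val=6,
        test_cohorts={"c1_like": {"n": 6}},
        name="tiny",
        out_dir=out_dir,
    )


def learning_config(seed: int = 0, out_dir: str = "results/learning") -> ExperimentConfig:
    """Scaled-down learning experiment: 60 train / 10 val / 20 test cases at
    64x64 with a depth-2 U-Net, 15 epochs, batch 8."""
    return _small_shared(
        seed,
        epochs=15,
        n_train=60,
        n_val=10,
        test_cohorts={"c1_like": {"n": 20}},
        name="learning",
        out_dir=out_dir,
    )


def degraded_config(seed: int = 0, out_dir: str = "results/degraded") -> ExperimentConfig:
    """Out-of-distribution robustness experiment: train on standard phantoms,
    test on a degraded / no-gel / coronal-like cohort plus an
    intensity-shifted cohort."""
    cfg = _small_shared(
        seed,
        epochs=15,
        n_train=40,
        n_val=8,
        test_cohorts={
            "c2_coronal": {"n": 6, "spec": c2_like_specs()[0]},
            "c2_nogel": {"n": 6, "spec": c2_like_specs()[1]},
            "c2_degraded": {"n": 6, "spec": c2_like_specs()[2]},
            "c3_like": {"n": 8, "scale": 1.8, "offset": 25.0},
        },
        name="degraded",
        out_dir=out_dir,
    )
    return cfg
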