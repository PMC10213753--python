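"""U-Net model construction and slice-wise inference.

Two head configurations share one architecture:

* ``sigmoid_binary`` — a single-channel sigmoid output, one network per
  anatomical region (region-specific model);
* ``softmax_multiclass`` — a K-channel softmax output segmenting
  background, lumen, wall and fat simultaneously.

Checkpoints are written as ``.npz`` weight archives with a JSON sidecar
echoing the configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .nn import UNet2D

SIGMOID = "sigmoid_binary"
SOFTMAX = "softmax_multiclass"


@dataclass(frozen=True)
class UNetConfig:
    input_size: int = 128
    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.2
    head: str = SIGMOID
    n_classes: int = 4  # softmax head only: background, lumen, wall, fat
    in_channels: int = 1

    def validate(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth={2**self.depth}"
            )
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.head not in (SIGMOID, SOFTMAX):
            raise ValueError(f"head must be {SIGMOID!r} or {SOFTMAX!r}")
        if self.head == SOFTMAX and self.n_classes < 2:
            raise ValueError("softmax head needs n_classes >= 2")


@dataclass
class ProbabilityMap:
    """Per-pixel model output before binarization.

    ``values`` is (H, W) for a sigmoid head and (H, W, K) for softmax.
    """

    values: np.ndarray
    head: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.head == SIGMOID and self.values.ndim != 2:
            raise ValueError("sigmoid probability map must be 2D")
        if self.head == SOFTMAX and self.values.ndim != 3:
            raise ValueError("softmax probability map must be 2D x K")


def build_unet(config: UNetConfig, seed: int = 0) -> UNet2D:
    """Instantiate a U-Net with seeded weight initialization."""
    config.validate()
    model = UNet2D(
        input_size=config.input_size,
        depth=config.depth,
        base_filters=config.base_filters,
        dropout_rate=config.dropout_rate,
        head=config.head,
        n_classes=config.n_classes,
        in_channels=config.in_channels,
        seed=seed,
    )
    model.config = config
    return model


def predict_slices(model: UNet2D, slices, batch_size: int = 16) -> list[ProbabilityMap]:
    """Evaluation-mode inference on a batch of 2D slices, order preserved."""
    arr = np.asarray(slices, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if len(arr) and arr.shape[1:3] != (model.input_size, model.input_size):
        raise ValueError(
            f"slice shape {arr.shape[1:3]} does not match model input size "
            f"{model.input_size}"
        )
    probs = model.predict(arr, batch_size=batch_size)
    head = model.head
    out = []
    for p in probs:
        if head == SIGMOID:
            out.append(ProbabilityMap(values=p[..., 0], head=SIGMOID))
        else:
            out.append(ProbabilityMap(values=p, head=SOFTMAX))
    return out


def save_checkpoint(model: UNet2D, path: str) -> None:
    """Write weights (.npz) plus a JSON config sidecar."""
    np.savez(path, **model.state_dict())
    cfg = getattr(model, "config", None)
    if cfg is not None:
        with open(os.path.splitext(path)[0] + ".json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=2)


def load_checkpoint(path: str) -> UNet2D:
    with open(os.path.splitext(path)[0] + ".json") as fh:
        cfg = UNetConfig(**json.load(fh))
    model = build_unet(cfg, seed=0)
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
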