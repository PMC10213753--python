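"""U-Net assembled from the NumPy layers, with explicit backward wiring.

Architecture: ``depth`` contracting blocks (two 3x3 conv + batch-norm +
ReLU, dropout after the second conv, then 2x2 max-pool), a bottleneck
block, and ``depth`` expanding blocks (2x2 transposed convolution, skip
concatenation, two 3x3 conv + batch-norm + ReLU, dropout), closed by a 1x1
convolution with a sigmoid (single-channel) or softmax (K-channel) head.
'Same' padding keeps every spatial size equal to the input size.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    F32,
    BatchNorm,
    Conv1x1,
    Conv3x3,
    ConvTranspose2x2,
    Dropout,
    MaxPool2,
    ReLU,
)


class ConvBlock:
    """conv-BN-ReLU, conv-BN-ReLU, dropout."""

    def __init__(self, c_in, c_out, dropout_rate, rng):
        self.layers = [
            Conv3x3(c_in, c_out, rng),
            BatchNorm(c_out),
            ReLU(),
            Conv3x3(c_out, c_out, rng),
            BatchNorm(c_out),
            ReLU(),
            Dropout(dropout_rate, rng),
        ]

    def forward(self, x, train):
        for ly in self.layers:
            x = ly.forward(x, train)
        return x

    def backward(self, dy):
        for ly in reversed(self.layers):
            dy = ly.backward(dy)
        return dy


class UNet2D:
    def __init__(self, input_size: int, depth: int, base_filters: int,
                 dropout_rate: float, head: str, n_classes: int,
                 in_channels: int = 1, seed: int = 0):
        if input_size % (2**depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^depth = {2**depth}"
            )
        if head not in ("sigmoid_binary", "softmax_multiclass"):
            raise ValueError(f"unknown head {head!r}")
        if head == "softmax_multiclass" and n_classes < 2:
            raise ValueError("softmax head needs n_classes >= 2")
        self.input_size, self.depth, self.head = input_size, depth, head
        self.n_out = 1 if head == "sigmoid_binary" else n_classes
        rng = np.random.default_rng(seed)
        self.rng = rng

        ch = [base_filters * 2**k for k in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for c in ch[:-1]:
            self.enc.append(ConvBlock(c_prev, c, dropout_rate, rng))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(ch[-2] if depth else in_channels, ch[-1], dropout_rate, rng)
        self.ups, self.dec = [], []
        c_prev = ch[-1]
        for c in reversed(ch[:-1]):
            self.ups.append(ConvTranspose2x2(c_prev, c, rng))
            self.dec.append(ConvBlock(2 * c, c, dropout_rate, rng))
            c_prev = c
        self.out_conv = Conv1x1(c_prev, self.n_out, rng)

    # -- plumbing ---------------------------------------------------------
    def layers(self):
        for blk in self.enc:
            yield from blk.layers
        yield from self.bottleneck.layers
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk.layers
        yield self.out_conv

    def n_params(self) -> int:
        return sum(int(p.size) for ly in self.layers() for p in ly.params.values())

    def state_dict(self) -> dict:
        state = {}
        for i, ly in enumerate(self.layers()):
            for k, v in ly.params.items():
                state[f"{i}.{k}"] = v
            if isinstance(ly, BatchNorm):
                state[f"{i}.running_mean"] = ly.running_mean
                state[f"{i}.running_var"] = ly.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, ly in enumerate(self.layers()):
            for k in ly.params:
                ly.params[k][...] = state[f"{i}.{k}"]
            if isinstance(ly, BatchNorm):
                ly.running_mean[...] = state[f"{i}.running_mean"]
                ly.running_var[...] = state[f"{i}.running_var"]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """x: (B, H, W, Cin) float32 -> per-pixel probabilities
        (B, H, W, 1) sigmoid or (B, H, W, K) softmax."""
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=-1)
            h = blk.forward(h, train)
        logits = self.out_conv.forward(h, train)
        if self.head == "sigmoid_binary":
            p = 1.0 / (1.0 + np.exp(-logits))
        else:
            z = logits - logits.max(axis=-1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=-1, keepdims=True)
        self._probs = p.astype(F32)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        p = self._probs
        if self.head == "sigmoid_binary":
            dz = dprobs * p * (1.0 - p)
        else:
            dz = p * (dprobs - (dprobs * p).sum(axis=-1, keepdims=True))
        dy = self.out_conv.backward(dz.astype(F32))
        for up, blk in zip(reversed(self.ups), reversed(self.dec)):
            dy = blk.backward(dy)
            c = dy.shape[-1] // 2
            dskip, dup = dy[..., :c], dy[..., c:]
            dy = up.backward(np.ascontiguousarray(dup))
            # route the skip gradient through the matching pooled path later
            up._dskip = dskip
        dy = self.bottleneck.backward(dy)
        for blk, pool, up in zip(reversed(self.enc), reversed(self.pools),
                                 self.ups):
            dy = pool.backward(dy)
            dy = dy + up._dskip
            up._dskip = None
            dy = blk.backward(dy)
        self._probs = None

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Eval-mode inference over a batch, preserving order."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[..., None]
        outs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        if not outs:
            return np.zeros((0, self.input_size, self.input_size, self.n_out), dtype=F32)
        return np.concatenate(outs, axis=0)
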