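"""The hybrid 3D/2D encoder-decoder for brain extraction.

The network takes a "data block" — three consecutive slices of a resampled,
intensity-normalized volume, shaped ``(N, 1, 3, H, W)`` — and emits per-voxel
two-class probabilities ``(N, 2, 3, H, W)`` (background, brain).

Encoding path: two 3D convolution stages operate on the slice stack to pick
up inter-slice context, then the depth axis is folded into the batch axis
(``to_4d``) so that three cheaper 2D stages can continue downsampling.
Decoding path: two 2D up/conv stages, then the depth axis is restored
(``to_5d``) and the features are channel-concatenated with the second 3D
encoder's pre-pooling output (the hybrid skip), followed by two 3D up/conv
stages and a two-channel softmax head.  Plain skip connections concatenate
each encoder's pre-pooling features at the matching resolution.

All convolutions are 3x3(x3), stride 1, padding 1, each followed by batch
normalization and ReLU.  Upsampling uses transposed convolutions (2D: 4x4,
stride 2; 3D: 3x4x4, stride (1,2,2), so the depth of 3 is preserved)
followed by ReLU.  In-plane resolution halves four times, so ``H = W`` must
be divisible by 16.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv,
    ConvTranspose,
    MaxPool,
    Module,
    Parameter,
    ReLU,
    softmax,
)

__all__ = [
    "HCNetConfig",
    "HCNet",
    "to_4d",
    "to_5d",
    "count_parameters",
    "parameter_table",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class HCNetConfig:
    """Architecture hyperparameters.

    ``channel_widths`` are the output widths of the five encoder stages; the
    decoders mirror them.  ``head_kernel`` selects the output layer: the
    stage table's 3x3x3 convolution ("3x3x3", default) or the 1x1x1 variant
    ("1x1x1").
    """

    in_channels: int = 1
    class_count: int = 2
    depth: int = 3
    channel_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    cube_size: int = 256
    head_kernel: str = "3x3x3"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.depth != 3:
            raise ValueError("the network is defined for data blocks of depth 3")
        if self.cube_size < 16 or self.cube_size % 16:
            raise ValueError("cube_size must be a multiple of 16 (four 2x poolings)")
        if len(self.channel_widths) != 5 or any(
            a >= b for a, b in zip(self.channel_widths, self.channel_widths[1:])
        ):
            raise ValueError("channel_widths must be 5 strictly increasing integers")
        if self.head_kernel not in ("3x3x3", "1x1x1"):
            raise ValueError("head_kernel must be '3x3x3' or '1x1x1'")


def to_4d(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Fold the depth axis of a 5-d feature tensor into the batch axis.

    ``(N, C, D, H, W) -> (D*N stacked as n*D+d, C, H, W)``; the depth is
    returned so :func:`to_5d` can invert the operation exactly.
    """
    if x.ndim != 5:
        raise ValueError(f"expected a rank-5 tensor, got rank {x.ndim}")
    n, c, d, h, w = x.shape
    y = np.ascontiguousarray(x.transpose(0, 2, 1, 3, 4)).reshape(n * d, c, h, w)
    return y, d


def to_5d(x: np.ndarray, depth: int) -> np.ndarray:
    """Inverse of :func:`to_4d`: unfold the batch axis back into depth."""
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 tensor, got rank {x.ndim}")
    b, c, h, w = x.shape
    if depth < 1 or b % depth:
        raise ValueError(f"batch {b} not divisible by depth {depth}")
    return np.ascontiguousarray(
        x.reshape(b // depth, depth, c, h, w).transpose(0, 2, 1, 3, 4)
    )


class ConvStage(Module):
    """Two (conv -> batch norm -> ReLU) units, 2D or 3D."""

    def __init__(self, cin, cout, rank, rng, dtype, name):
        k = 3
        self.layers = [
            Conv(cin, cout, k, stride=1, pad=1, rank=rank, rng=rng, dtype=dtype,
                 name=f"{name}.conv1"),
            BatchNorm(cout, dtype=dtype, name=f"{name}.bn1"),
            ReLU(),
            Conv(cout, cout, k, stride=1, pad=1, rank=rank, rng=rng, dtype=dtype,
                 name=f"{name}.conv2"),
            BatchNorm(cout, dtype=dtype, name=f"{name}.bn2"),
            ReLU(),
        ]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class UpStage(Module):
    """Transposed convolution followed by ReLU."""

    def __init__(self, cin, cout, kernel, stride, rank, rng, dtype, name):
        self.upconv = ConvTranspose(cin, cout, kernel, stride=stride, pad=1,
                                    rank=rank, rng=rng, dtype=dtype, name=name)
        self.relu = ReLU()

    def forward(self, x, training=False):
        return self.relu.forward(self.upconv.forward(x, training), training)

    def backward(self, grad):
        return self.upconv.backward(self.relu.backward(grad))


class HCNet(Module):
    """Hybrid 3D/2D encoder-decoder over data blocks."""

    def __init__(self, config: HCNetConfig | None = None):
        self.config = config or HCNetConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        w0, w1, w2, w3, w4 = cfg.channel_widths

        self.enc1 = ConvStage(cfg.in_channels, w0, 3, rng, dtype, "enc1")
        self.pool1 = MaxPool((1, 2, 2))
        self.enc2 = ConvStage(w0, w1, 3, rng, dtype, "enc2")
        self.pool2 = MaxPool((1, 2, 2))
        self.enc3 = ConvStage(w1, w2, 2, rng, dtype, "enc3")
        self.pool3 = MaxPool((2, 2))
        self.enc4 = ConvStage(w2, w3, 2, rng, dtype, "enc4")
        self.pool4 = MaxPool((2, 2))
        self.enc5 = ConvStage(w3, w4, 2, rng, dtype, "enc5")

        self.up1 = UpStage(w4, w3, 4, 2, 2, rng, dtype, "up1")
        self.dec1 = ConvStage(2 * w3, w3, 2, rng, dtype, "dec1")
        self.up2 = UpStage(w3, w2, 4, 2, 2, rng, dtype, "up2")
        self.dec2 = ConvStage(2 * w2, w2, 2, rng, dtype, "dec2")
        self.up3 = UpStage(w2, w1, 4, 2, 2, rng, dtype, "up3")
        self.dec3 = ConvStage(2 * w1, w1, 3, rng, dtype, "dec3")
        self.up4 = UpStage(w1, w0, (3, 4, 4), (1, 2, 2), 3, rng, dtype, "up4")
        self.dec4 = ConvStage(2 * w0, w0, 3, rng, dtype, "dec4")

        if cfg.head_kernel == "3x3x3":
            self.head = Conv(w0, cfg.class_count, 3, stride=1, pad=1, rank=3,
                             rng=rng, dtype=dtype, name="head")
        else:
            self.head = Conv(w0, cfg.class_count, 1, stride=1, pad=0, rank=3,
                             rng=rng, dtype=dtype, name="head")
        self._probes: dict[str, tuple[int, ...]] = {}

    # -- forward ---------------------------------------------------------

    def _check_input(self, x):
        cfg = self.config
        if x.ndim != 5 or x.shape[1] != cfg.in_channels or x.shape[2] != cfg.depth:
            raise ValueError(
                f"expected input (N, {cfg.in_channels}, {cfg.depth}, H, W), got {x.shape}"
            )
        if x.shape[3] != x.shape[4] or x.shape[3] != cfg.cube_size:
            raise ValueError(
                f"expected H = W = {cfg.cube_size}, got {x.shape[3]}x{x.shape[4]}"
            )

    def forward_logits(self, x, training=False, record_probes=False):
        """Run the network up to (but excluding) the softmax."""
        self._check_input(x)
        probes = self._probes = {}

        e1 = self.enc1.forward(x, training)          # w0 x 3 x S x S
        p1 = self.pool1.forward(e1, training)
        e2 = self.enc2.forward(p1, training)         # w1 x 3 x S/2 x S/2 (hybrid skip)
        p2 = self.pool2.forward(e2, training)
        f4, depth = to_4d(p2)                        # (3N, w1, S/4, S/4)
        e3 = self.enc3.forward(f4, training)
        p3 = self.pool3.forward(e3, training)
        e4 = self.enc4.forward(p3, training)
        p4 = self.pool4.forward(e4, training)
        e5 = self.enc5.forward(p4, training)

        u1 = self.up1.forward(e5, training)
        c1 = np.concatenate([u1, e4], axis=1)
        d1 = self.dec1.forward(c1, training)
        u2 = self.up2.forward(d1, training)
        c2 = np.concatenate([u2, e3], axis=1)
        d2 = self.dec2.forward(c2, training)
        u3 = self.up3.forward(d2, training)
        r5 = to_5d(u3, depth)                        # (N, w1, 3, S/2, S/2)
        c3 = np.concatenate([r5, e2], axis=1)        # hybrid skip fusion
        d3 = self.dec3.forward(c3, training)
        u4 = self.up4.forward(d3, training)
        c4 = np.concatenate([u4, e1], axis=1)
        d4 = self.dec4.forward(c4, training)
        logits = self.head.forward(d4, training)

        if record_probes:
            for name, t in [
                ("enc1", e1), ("pool1", p1), ("enc2", e2), ("pool2", p2),
                ("to_4d", f4), ("enc3", e3), ("pool3", p3), ("enc4", e4),
                ("pool4", p4), ("enc5", e5), ("up1", u1), ("concat1", c1),
                ("dec1", d1), ("up2", u2), ("concat2", c2), ("dec2", d2),
                ("up3", u3), ("to_5d", r5), ("concat3", c3), ("dec3", d3),
                ("up4", u4), ("concat4", c4), ("dec4", d4), ("out", logits),
            ]:
                probes[name] = t.shape
        if training:
            self._cache_depth = depth
            self._split = {
                "c1": u1.shape[1], "c2": u2.shape[1],
                "c3": r5.shape[1], "c4": u4.shape[1],
            }
        return logits

    def forward(self, x, training=False, record_probes=False):
        """Per-voxel class probabilities, normalized over the 2 class channels."""
        logits = self.forward_logits(x, training=training, record_probes=record_probes)
        return softmax(logits, axis=1)

    @property
    def probes(self):
        """Shapes of the intermediate stages of the last probed forward pass."""
        return dict(self._probes)

    # -- backward --------------------------------------------------------

    def backward(self, dlogits):
        """Backpropagate a gradient w.r.t. the logits; accumulates parameter grads."""
        sp = self._split
        g = self.head.backward(dlogits)
        g = self.dec4.backward(g)
        g_u4, g_e1_skip = g[:, : sp["c4"]], g[:, sp["c4"]:]
        g = self.up4.backward(np.ascontiguousarray(g_u4))
        g = self.dec3.backward(g)
        g_r5, g_e2_skip = g[:, : sp["c3"]], g[:, sp["c3"]:]
        g, _ = to_4d(np.ascontiguousarray(g_r5))
        g = self.up3.backward(g)
        g = self.dec2.backward(g)
        g_u2, g_e3_skip = g[:, : sp["c2"]], g[:, sp["c2"]:]
        g = self.up2.backward(np.ascontiguousarray(g_u2))
        g = self.dec1.backward(g)
        g_u1, g_e4_skip = g[:, : sp["c1"]], g[:, sp["c1"]:]
        g = self.up1.backward(np.ascontiguousarray(g_u1))

        g = self.enc5.backward(g)
        g = self.pool4.backward(g)
        g = self.enc4.backward(g + g_e4_skip)
        g = self.pool3.backward(g)
        g = self.enc3.backward(g + g_e3_skip)
        g = to_5d(g, self._cache_depth)
        g = self.pool2.backward(g)
        g = self.enc2.backward(g + g_e2_skip)
        g = self.pool1.backward(g)
        g = self.enc1.backward(g + g_e1_skip)
        return g

    # -- bookkeeping -----------------------------------------------------

    _STAGE_NAMES = (
        "enc1", "enc2", "enc3", "enc4", "enc5",
        "up1", "dec1", "up2", "dec2", "up3", "dec3", "up4", "dec4", "head",
    )

    def stage_parameter_counts(self) -> dict[str, int]:
        return {name: getattr(self, name).num_parameters() for name in self._STAGE_NAMES}

    def state_items(self) -> list[tuple[str, np.ndarray]]:
        """All arrays defining the model: parameters plus batch-norm statistics."""
        items: list[tuple[str, np.ndarray]] = []

        def walk(obj, prefix):
            for key, val in obj.__dict__.items():
                if isinstance(val, Parameter):
                    items.append((f"{prefix}{key}", val.value))
                elif isinstance(val, np.ndarray) and key.startswith("running_"):
                    items.append((f"{prefix}{key}", val))
                elif isinstance(val, Module):
                    walk(val, f"{prefix}{key}.")
                elif isinstance(val, list):
                    for i, item in enumerate(val):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{key}.{i}.")

        walk(self, "")
        return items

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        def walk(obj, prefix):
            for key, val in obj.__dict__.items():
                name = f"{prefix}{key}"
                if isinstance(val, Parameter):
                    val.value[...] = arrays[name]
                elif isinstance(val, np.ndarray) and key.startswith("running_"):
                    val[...] = arrays[name]
                elif isinstance(val, Module):
                    walk(val, name + ".")
                elif isinstance(val, list):
                    for i, item in enumerate(val):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")

        walk(self, "")


def count_parameters(config: HCNetConfig | None = None) -> int:
    """Total number of trainable scalars of the configured network."""
    return HCNet(config).num_parameters()


def parameter_table(config: HCNetConfig | None = None) -> dict[str, int]:
    """Per-stage trainable parameter counts, in stage order."""
    return HCNet(config).stage_parameter_counts()


def save_checkpoint(model: HCNet, path, extra: dict | None = None) -> None:
    """Save model weights, batch-norm statistics, config and metadata."""
    arrays = dict(model.state_items())
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[HCNet, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode("utf-8"))
    cfg_dict = dict(meta["config"])
    cfg_dict["channel_widths"] = tuple(cfg_dict["channel_widths"])
    model = HCNet(HCNetConfig(**cfg_dict))
    model.load_state(arrays)
    return model, meta.get("extra", {})
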