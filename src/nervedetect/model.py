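"""The U-Net with an augmented classification structure.

A standard encoder-decoder segmentation network is extended with an
image-level classification branch taken off the bottleneck: a 1 x 1
convolution reduces the feature channels, a two-layer fully connected head
ends in a single sigmoid unit, and that scalar — duplicated to the input
image size — multiplies the pixel-wise segmentation sigmoid. A pixel in the
final output can only exceed the 0.5 threshold when both the segmentation
map and the image classifier exceed 0.5, which suppresses confident-looking
pixel predictions inside patches the classifier rejects (the dominant source
of false positives in stained tissue).

Architecture conventions: 3 x 3 convolutions with ReLU, batch normalisation
before every activation, 2 x 2 average pooling for downsampling, 2 x 2
nearest-neighbour upsampling followed by a 2 x 2 convolution, concatenation
skip connections both within each convolution block (dense style) and from
encoder to decoder, and dropout 0.5 in the lowest-resolution block and in
the classification head. The whole network trains end-to-end with a single
binary cross-entropy loss on the gated output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import BatchNorm, Conv2D, Dense

__all__ = ["ModelConfig", "ModelOutput", "GatedUNet", "build_model",
           "predict_patch", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The defaults match the full-size network (160 x 160 x 3 input, four
    pooling levels); a tiny configuration (e.g. 64 x 64, depth 2, filters
    (4, 8, 16)) trains in minutes on one CPU and is used throughout the test
    suite. Height and width must be divisible by ``2 ** depth``.
    """

    input_size: tuple[int, int] = (160, 160)
    depth: int = 4
    filters_per_level: tuple[int, ...] = (16, 32, 64, 128, 256)
    dropout_rate: float = 0.5
    classifier_channels: int = 8
    classifier_hidden_units: int = 64
    output_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^{self.depth}"
            )
        if len(self.filters_per_level) != self.depth + 1:
            raise ValueError("filters_per_level must have depth+1 entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class ModelOutput:
    """Per-patch network outputs.

    ``gated_prob = seg_prob * class_prob`` elementwise; ``binary_mask`` is
    the strict ``gated_prob > threshold`` decision, so a pixel can only be
    positive when both branches exceed the threshold.
    """

    seg_prob: np.ndarray  # (H, W) in [0, 1]
    class_prob: float  # scalar in [0, 1]
    gated_prob: np.ndarray  # (H, W)
    binary_mask: np.ndarray = field(init=False)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.binary_mask = self.gated_prob > self.threshold


class _ConvBNRelu:
    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2D(k, k, cin, cout, rng, bias=False)
        self.bn = BatchNorm(cout)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.relu(self.bn(self.conv(x), training))

    def layers(self):
        return [self.conv, self.bn]


class _Block:
    """Two 3x3 conv-BN-ReLU stages whose outputs are concatenated (dense
    style within-block skip), so the block emits 2*filters channels."""

    def __init__(self, cin: int, filters: int, rng: np.random.Generator,
                 dropout_rate: float = 0.0):
        self.c1 = _ConvBNRelu(3, cin, filters, rng)
        self.c2 = _ConvBNRelu(3, filters, filters, rng)
        self.dropout_rate = dropout_rate
        self.out_channels = 2 * filters

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        a = self.c1(x, training)
        h = ad.dropout(a, self.dropout_rate, rng, training)
        b = self.c2(h, training)
        return ad.concat([a, b], axis=3)

    def layers(self):
        return self.c1.layers() + self.c2.layers()


class GatedUNet:
    """U-Net encoder-decoder with the multiplicative classification gate."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        f = config.filters_per_level
        d = config.depth

        self.enc: list[_Block] = []
        cin = 3
        for i in range(d):
            self.enc.append(_Block(cin, f[i], rng))
            cin = 2 * f[i]
        self.bottleneck = _Block(cin, f[d], rng, dropout_rate=config.dropout_rate)
        cin = 2 * f[d]

        self.up_convs: list[_ConvBNRelu] = []
        self.dec: list[_Block] = []
        for i in reversed(range(d)):
            self.up_convs.append(_ConvBNRelu(2, cin, f[i], rng))
            self.dec.append(_Block(f[i] + 2 * f[i], f[i], rng))
            cin = 2 * f[i]
        self.seg_head = Conv2D(1, 1, cin, 1, rng, bias=True)

        # classification branch off the bottleneck
        self.cls_reduce = _ConvBNRelu(1, 2 * f[d], config.classifier_channels, rng)
        hb, wb = (config.input_size[0] >> d), (config.input_size[1] >> d)
        flat = hb * wb * config.classifier_channels
        self.cls_fc1 = Dense(flat, config.classifier_hidden_units, rng)
        self.cls_bn1 = BatchNorm(config.classifier_hidden_units)
        self.cls_fc2 = Dense(config.classifier_hidden_units, 1, rng)

        self._class_override: float | None = None

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        layers = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            layers += blk.layers()
        for up in self.up_convs:
            layers += up.layers()
        layers += [self.seg_head, *self.cls_reduce.layers(), self.cls_fc1,
                   self.cls_bn1, self.cls_fc2]
        return layers

    def parameters(self) -> list[Tensor]:
        return [p for layer in self._all_layers() for p in layer.parameters()]

    def buffers(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            for _, buf in sorted(layer.buffers().items()):
                out.append(buf)
        return out

    def set_class_override(self, value: float | None) -> None:
        """Pin the classification output (e.g. 1.0 ablates the gate to a
        plain U-Net); ``None`` restores normal behaviour."""
        self._class_override = value

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, training: bool = False
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns ``(seg_prob, class_prob, gated_prob)`` as graph tensors.

        ``x`` is an (N, H, W, 3) batch scaled to [0, 1]. Inference mode
        (``training=False``) disables dropout and uses running batch-norm
        statistics, so it is deterministic.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, h, w, c = x.shape
        if (h, w) != self.config.input_size or c != 3:
            raise ValueError(
                f"expected input {self.config.input_size} x 3, got {(h, w, c)}"
            )
        rng = self._dropout_rng
        skips = []
        hcur = x
        for blk in self.enc:
            hcur = blk(hcur, training, rng)
            skips.append(hcur)
            hcur = ad.avg_pool2(hcur)
        hcur = self.bottleneck(hcur, training, rng)
        bott = hcur

        for up, blk, skip in zip(self.up_convs, self.dec, reversed(skips)):
            hcur = up(ad.upsample_nearest2(hcur), training)
            hcur = ad.concat([hcur, skip], axis=3)
            hcur = blk(hcur, training, rng)
        seg = ad.sigmoid(self.seg_head(hcur))  # (N, H, W, 1)

        cls = self.cls_reduce(bott, training)
        cls = ad.dropout(cls, self.config.dropout_rate, rng, training)
        cls = ad.reshape(cls, (n, -1))
        cls = ad.relu(self.cls_bn1(self.cls_fc1(cls), training))
        cls = ad.dropout(cls, self.config.dropout_rate, rng, training)
        cls = ad.sigmoid(self.cls_fc2(cls))  # (N, 1)
        if self._class_override is not None:
            cls = Tensor(np.full((n, 1), self._class_override, dtype=np.float32))

        # duplication of the scalar to image size == broadcast multiply
        gated = ad.mul(seg, ad.reshape(cls, (n, 1, 1, 1)))
        return seg, cls, gated

    def predict(self, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inference on an (N, H, W, 3) float batch; returns numpy arrays
        ``(seg_prob (N,H,W), class_prob (N,), gated_prob (N,H,W))``."""
        seg, cls, gated = self.forward(batch, training=False)
        return seg.data[..., 0], cls.data[:, 0], gated.data[..., 0]


def build_model(config: ModelConfig | None = None) -> GatedUNet:
    """Construct the gated U-Net with He-initialised weights."""
    return GatedUNet(config or ModelConfig())


def predict_patch(model: GatedUNet, patch: np.ndarray) -> ModelOutput:
    """Run one P x P x 3 patch (uint8 or float in [0, 1]) through the model."""
    patch = np.asarray(patch)
    if np.issubdtype(patch.dtype, np.integer):
        patch = patch.astype(np.float32) / 255.0
    if patch.shape != (*model.config.input_size, 3):
        raise ValueError(
            f"expected patch {model.config.input_size} x 3, got {patch.shape}"
        )
    seg, cls, gated = model.predict(patch[None])
    return ModelOutput(
        seg_prob=seg[0],
        class_prob=float(cls[0]),
        gated_prob=gated[0],
        threshold=model.config.output_threshold,
    )


def save_model(model: GatedUNet, path: str | Path) -> None:
    """Serialise config, weights and batch-norm buffers to an .npz file."""
    path = Path(path)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(model.buffers())})
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> GatedUNet:
    """Rebuild a model saved by :func:`save_model`; inference is bit-identical."""
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["input_size"] = tuple(cfg["input_size"])
        cfg["filters_per_level"] = tuple(cfg["filters_per_level"])
        model = GatedUNet(ModelConfig(**cfg))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"].astype(np.float32)
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"buffer_{i}"]
    return model
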