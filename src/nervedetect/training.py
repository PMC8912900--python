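"""Balanced, augmented, seeded training of the gated U-Net.

Class balance is enforced structurally: every batch holds exactly half
positive and half negative samples drawn with replacement from the two
pools, so the classifier branch never sees a skewed class prior regardless
of how unbalanced the extracted ROIs are. Augmentation (flips, 90-degree
rotations, small translations with reflection fill) is applied identically
to the image and its label mask. All randomness flows from one generator
seeded by the config, so a training run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import GatedUNet
from .nn.autodiff import bce_loss
from .nn.layers import Adam
from .preprocessing import TrainingSample

__all__ = ["TrainConfig", "TrainHistory", "augment", "balanced_batch_generator",
           "train"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults are the full-scale settings (Adam, learning rate 1e-4, binary
    cross-entropy, 250 epochs); ``epochs`` is routinely scaled down for small
    synthetic experiments. ``batch_size`` must be even so batches can be
    split equally between the classes.
    """

    learning_rate: float = 1e-4
    epochs: int = 250
    batch_size: int = 16
    shift_frac: float = 0.1
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2 or self.batch_size % 2:
            raise ValueError("batch_size must be even (class-balance contract)")


@dataclass
class TrainHistory:
    loss: list[float]  # mean BCE per epoch


def _sample_key(s: TrainingSample) -> str:
    digest = hashlib.sha1(s.image_patch.tobytes())
    digest.update(s.label_mask.tobytes())
    return digest.hexdigest()


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            shift_frac: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Random flip / rot90 / translation applied jointly to image and mask.

    Translations are at most ``shift_frac`` of the patch side and filled by
    reflection, so an all-false mask stays all-false.
    """
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    k = int(rng.integers(0, 4))
    if k:
        image, mask = np.rot90(image, k), np.rot90(mask, k)
    max_shift = int(round(shift_frac * image.shape[0]))
    if max_shift:
        dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
        pad = max_shift
        imp = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        msp = np.pad(mask, ((pad, pad), (pad, pad)), mode="reflect")
        h, w = image.shape[:2]
        image = imp[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
        mask = msp[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def balanced_batch_generator(
    positives: Sequence[TrainingSample],
    negatives: Sequence[TrainingSample],
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Endless stream of balanced ``(images, labels)`` float batches.

    Each batch holds ``batch_size/2`` positives and ``batch_size/2``
    negatives (sampled with replacement), images scaled to [0, 1] with shape
    (B, P, P, 3) and labels (B, P, P, 1).
    """
    if not positives or not negatives:
        raise ValueError("both the positive and the negative pool must be non-empty")
    rng = rng or np.random.default_rng(config.seed)
    half = config.batch_size // 2
    while True:
        imgs, masks = [], []
        pos_idx = rng.integers(0, len(positives), size=half)
        neg_idx = rng.integers(0, len(negatives), size=half)
        for pool, idx in ((positives, pos_idx), (negatives, neg_idx)):
            for i in idx:
                s = pool[int(i)]
                img = s.image_patch.astype(np.float32) / 255.0
                msk = s.label_mask.astype(np.float32)
                if config.augment:
                    img, msk = augment(img, msk, rng, config.shift_frac)
                imgs.append(img)
                masks.append(msk)
        yield np.stack(imgs), np.stack(masks)[..., None]


def train(
    model: GatedUNet,
    samples: Sequence[TrainingSample],
    config: TrainConfig | None = None,
) -> TrainHistory:
    """Train in place; returns the per-epoch loss history.

    One epoch is ``2 * min(pool sizes) / batch_size`` steps (at least one),
    so each epoch sees roughly every sample of the smaller pool once.
    Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    config = config or TrainConfig()
    positives = [s for s in samples if s.class_label == "positive"]
    negatives = [s for s in samples if s.class_label == "negative"]
    # canonical pool order: training is invariant to how the caller ordered
    # the dataset, because index-based sampling sees the same pools
    positives.sort(key=_sample_key)
    negatives.sort(key=_sample_key)
    batches = balanced_batch_generator(positives, negatives, config)
    steps = max((2 * min(len(positives), len(negatives))) // config.batch_size, 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory(loss=[])
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            x, y = next(batches)
            opt.zero_grad()
            _, _, gated = model.forward(x, training=True)
            loss = bce_loss(gated, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        history.loss.append(epoch_loss / steps)
    return history
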