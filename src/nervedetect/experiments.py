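"""Canned synthetic experiments: the desk-scale end-to-end benchmark.

Real whole-slide inputs are gigapixel rasters and the full-size network
trains for 250 epochs; the benchmark here is a scaled-down analogue that
runs in minutes on one CPU while exercising every stage of the pipeline:
640 x 640 px tiles, 64 x 64 px patches, a depth-2 network with 4-16 filters
per level, and 200 training samples. Slide content (six nerves of
100-900 um^2 across all four appearance classes, twelve distractors split
between in-range and out-of-range staining) is fixed; only the seeds vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .baseline import colour_filter_detect
from .detection import detect
from .evaluation import EvalCounts, aggregate, evaluate_slide
from .model import GatedUNet, ModelConfig, build_model
from .preprocessing import TrainingSample, build_training_samples
from .synthetic import SyntheticSlide, SyntheticSpec, generate_slide
from .training import TrainConfig, TrainHistory, train

__all__ = [
    "TINY_PATCH", "tiny_model_config", "tiny_train_config", "benchmark_slide_spec",
    "build_training_pool", "train_tiny_model", "SyntheticBenchmark",
    "run_synthetic_benchmark",
]

TINY_PATCH = 64


def benchmark_slide_spec(seed: int, completeness: float = 1.0) -> SyntheticSpec:
    """The benchmark's slide conditions; only seed and completeness vary."""
    return SyntheticSpec(
        image_height_px=640,
        image_width_px=640,
        microns_per_pixel=0.5,
        n_nerves=6,
        nerve_area_range_um2=(100.0, 900.0),
        n_distractors=12,
        annotation_completeness=completeness,
        seed=seed,
    )


def tiny_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(
        input_size=(TINY_PATCH, TINY_PATCH),
        depth=2,
        filters_per_level=(4, 8, 16),
        seed=seed,
    )


def tiny_train_config(seed: int = 0) -> TrainConfig:
    # the tiny network tolerates a 10x larger learning rate than the
    # full-scale configuration and converges within 40 epochs
    return TrainConfig(learning_rate=1e-3, epochs=40, batch_size=16, seed=seed)


def build_training_pool(
    n_pos: int = 100,
    n_neg: int = 100,
    start_seed: int = 100,
    max_slides: int = 40,
) -> list[TrainingSample]:
    """Training samples from successive synthetic slides until both class
    pools are full; returns exactly ``n_pos + n_neg`` samples."""
    pos: list[TrainingSample] = []
    neg: list[TrainingSample] = []
    for i in range(max_slides):
        if len(pos) >= n_pos and len(neg) >= n_neg:
            break
        try:
            slide = generate_slide(benchmark_slide_spec(start_seed + i))
        except ValueError:  # rare unlucky packing; use the next seed
            continue
        for s in build_training_samples(
            slide.image, slide.expert_annotations, slide.negative_regions,
            P=TINY_PATCH,
        ):
            (pos if s.class_label == "positive" else neg).append(s)
    if len(pos) < n_pos or len(neg) < n_neg:
        raise RuntimeError(
            f"training pool incomplete after {max_slides} slides: "
            f"{len(pos)} positive, {len(neg)} negative"
        )
    return pos[:n_pos] + neg[:n_neg]


def train_tiny_model(
    samples: list[TrainingSample], seed: int = 0
) -> tuple[GatedUNet, TrainHistory]:
    model = build_model(tiny_model_config(seed))
    history = train(model, samples, tiny_train_config(seed))
    return model, history


@dataclass
class SyntheticBenchmark:
    """Results of the held-out synthetic evaluation."""

    cnn_per_slide: list[EvalCounts] = field(default_factory=list)
    cf_per_slide: list[EvalCounts] = field(default_factory=list)

    @property
    def cnn(self) -> dict:
        return aggregate(self.cnn_per_slide)

    @property
    def cf(self) -> dict:
        return aggregate(self.cf_per_slide)


def run_synthetic_benchmark(
    model: GatedUNet,
    n_slides: int = 5,
    start_seed: int = 200,
    completeness: float = 1.0,
) -> SyntheticBenchmark:
    """Detect on held-out slides with both the CNN and the colour filter and
    score hit-or-miss against the expert annotations, adjudicating
    additional detections with the generator's complete truth mask."""
    bench = SyntheticBenchmark()
    offset = 0
    for j in range(n_slides):
        while True:
            try:
                slide: SyntheticSlide = generate_slide(
                    benchmark_slide_spec(start_seed + j + offset, completeness)
                )
                break
            except ValueError:  # rare unlucky packing; use the next seed
                offset += 1
        cnn = detect(slide.image, model, P=TINY_PATCH)
        bench.cnn_per_slide.append(
            evaluate_slide(cnn.boxes, slide.expert_annotations,
                           truth_mask=slide.truth_mask)
        )
        cf = colour_filter_detect(slide.image)
        bench.cf_per_slide.append(
            evaluate_slide(cf.boxes, slide.expert_annotations,
                           truth_mask=slide.truth_mask)
        )
    return bench
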