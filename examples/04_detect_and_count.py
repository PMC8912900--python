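"""Whole-slide detection: sliding window, stitching, counting rules.

Run 03_train_tiny_model.py first (it writes tiny_model.npz), or this script
will train the model itself.
"""

from pathlib import Path

from nervedetect.baseline import colour_filter_detect
from nervedetect.detection import detect
from nervedetect.experiments import TINY_PATCH, benchmark_slide_spec
from nervedetect.model import load_model
from nervedetect.synthetic import generate_slide

if Path("tiny_model.npz").exists():
    model = load_model("tiny_model.npz")
else:
    from nervedetect.experiments import build_training_pool, train_tiny_model
    model, _ = train_tiny_model(build_training_pool(start_seed=100), seed=0)

slide = generate_slide(benchmark_slide_spec(seed=200))
print(f"slide contains {len(slide.complete_annotations)} nerves "
      f"and {len(slide.distractor_boxes)} distractors")

cnn = detect(slide.image, model, P=TINY_PATCH)
print(f"CNN detector counted {cnn.count} nerves")

cf = colour_filter_detect(slide.image)
print(f"colour-filter detector counted {cf.count} nerves")
# The colour filter cannot reject in-range non-specific staining, so it
# typically over-counts; the classification gate suppresses those regions.
for box in cnn.boxes:
    print(f"  CNN box at ({box.x0}, {box.y0}) size {box.width}x{box.height}")
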