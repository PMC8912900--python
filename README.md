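# nervedetect

Automated detection and quantification of nerves in immunohistochemistry
(IHC) whole-slide images.

Nerve density in and around tumours is a prognostic signal in several
cancers, but counting nerves by eye in a gigapixel PGP9.5/DAB-stained slide
is slow and biased toward large trunks. A plain colour threshold on the
brown DAB signal finds essentially every nerve — and drowns it in
non-specific staining. `nervedetect` implements a pipeline for pathology
image analysts that keeps the colour filter's sensitivity while recovering
precision with a learned gate:

1. **Colour filter** — normalised-HSV range `(0.04, 0.2, 0.4)–(0.2, 1, 1)`
   marks DAB-brown pixels.
2. **Gated U-Net** — a U-Net segmentation network whose bottleneck also
   drives an image-level classifier; the scalar class probability *c*,
   duplicated to image size, multiplies the segmentation map *s*, and a
   pixel is positive only when `s·c > 0.5` — so both branches must agree.
3. **Counting rules** — 20 × 20 px morphological closing bridges axons of
   one nerve, instances of ≤ 100 px (25 µm² at 0.5 µm/px) are discarded,
   and prediction boxes overlapping by ≥ 50% of the smaller box merge into
   one counted nerve.
4. **Hit-or-miss evaluation** — at object level: sensitivity
   `TPR = TP_m/(TP_m+FN)` over expert annotations, precision
   `PPV = (TP_m+TP_a)/(TP_m+TP_a+FP)` with additional detections
   adjudicated against ground truth.

Because no public slide cohort accompanies the method, the package includes
a seedable **synthetic slide generator** (brown nerves in four appearance
classes, non-specific staining distractors, haematoxylin-like background,
deliberately incomplete "expert" annotations) so the entire pipeline —
preprocessing, training, detection, scoring — runs end-to-end with exact
ground truth. The network runs on a compact numpy autodiff engine included
in the package; there is no deep-learning-framework dependency.

See `docs/methods.md` for the full model and design notes.

## Worked example

```python
from nervedetect.baseline import colour_filter_detect
from nervedetect.evaluation import evaluate_slide
from nervedetect.experiments import benchmark_slide_spec
from nervedetect.synthetic import generate_slide

slide = generate_slide(benchmark_slide_spec(seed=201, completeness=0.8))
result = colour_filter_detect(slide.image)
counts = evaluate_slide(result.boxes, slide.expert_annotations,
                        truth_mask=slide.truth_mask)
print(counts.n_annotations, counts.TP_m, counts.FN, counts.TP_a, counts.FP)
print(f"{counts.TPR:.2f} {counts.PPV:.2f}")
```

prints

```
5 5 0 1 4
1.00 0.60
```

— the colour filter found all 5 annotated nerves (`TP_m=5`, sensitivity
1.00) plus one real nerve the "expert" had not annotated (`TP_a=1`), but
also 4 pieces of non-specific staining (`FP=4`), for a precision of 0.60.
Training the gated U-Net and running `nervedetect.detection.detect` on the
same slides lifts precision while keeping sensitivity high (see
`examples/03_train_tiny_model.py` and `examples/04_detect_and_count.py`).

The `examples/` directory has one short script per capability: slide
simulation, colour filtering and ROI extraction, training, detection, and
evaluation. A thin CLI mirrors the same stages:

```sh
nervedetect simulate --seed 3 --out sim/
nervedetect predict --slide sim/slide.png --baseline-cf --out det.geojson
nervedetect evaluate --detections det.geojson --annotations sim/expert.geojson \
    --truth-mask sim/truth_mask.png
```

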