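"""Hit-or-miss object-level scoring of whole-slide detections.

No precise pixel-wise ground truth exists for real slides, so detections are
scored at the object level against coarse expert annotations:

* a hit (TP_m) is any expert annotation intersected by at least one
  prediction box — multiple boxes on one annotation still count one hit;
* an annotation intersected by nothing is a miss (FN);
* a prediction box intersecting no annotation is an *additional* detection,
  adjudicated against complete ground truth (on synthetic slides) or an
  explicit adjudication list (standing in for the study's human scorers):
  it becomes TP_a if it contains real nerve signal, else FP.

Sensitivity TPR = TP_m / (TP_m + FN) counts annotated nerves recovered;
precision PPV = TP / (TP + FP) with TP = TP_m + TP_a counts detections that
are real nerves. Per-slide values aggregate as unweighted means (slides with
no annotations have undefined TPR and are excluded from the TPR mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import AnnotationSet, Box

__all__ = [
    "EvalCounts",
    "match_detections",
    "adjudicate_additional",
    "sensitivity",
    "precision",
    "evaluate_slide",
    "aggregate",
    "pairwise_agreement",
    "sample_precision_estimate",
]


@dataclass
class EvalCounts:
    """Per-slide hit-or-miss counts and derived rates."""

    slide_id: str = "slide"
    n_annotations: int = 0
    TP_m: int = 0
    FN: int = 0
    TP_a: int = 0
    FP: int = 0

    @property
    def TP(self) -> int:
        return self.TP_m + self.TP_a

    @property
    def TPR(self) -> float | None:
        return sensitivity(self.TP_m, self.FN)

    @property
    def PPV(self) -> float | None:
        return precision(self.TP_m, self.TP_a, self.FP)


def match_detections(
    boxes: Sequence[Box], annotations: AnnotationSet
) -> tuple[int, int, list[Box]]:
    """Score prediction boxes against expert annotations.

    Returns ``(TP_m, FN, unmatched_boxes)``. An annotation is hit iff at
    least one box has positive overlap area with it; a box intersecting k
    annotations credits each of the k; boxes hitting no annotation are
    returned for adjudication.
    """
    hit = [False] * len(annotations)
    unmatched: list[Box] = []
    for box in boxes:
        any_hit = False
        for i, ann in enumerate(annotations):
            if box.intersects(ann.box):
                hit[i] = True
                any_hit = True
        if not any_hit:
            unmatched.append(box)
    tp_m = sum(hit)
    return tp_m, len(annotations) - tp_m, unmatched


def adjudicate_additional(
    unmatched: Sequence[Box],
    truth_mask: np.ndarray | None = None,
    complete_annotations: AnnotationSet | None = None,
    adjudications: Sequence[bool] | None = None,
) -> tuple[int, int]:
    """Split additional detections into true positives and false positives.

    Ground truth (a nerve pixel mask or a complete annotation set) replaces
    the human scorers: an unmatched box containing any truth-nerve pixel is
    TP_a, otherwise FP. Alternatively an explicit per-box boolean
    adjudication list may be supplied.
    """
    if adjudications is not None:
        if len(adjudications) != len(unmatched):
            raise ValueError("one adjudication per unmatched box is required")
        tp_a = int(sum(bool(a) for a in adjudications))
        return tp_a, len(unmatched) - tp_a
    if truth_mask is None and complete_annotations is None:
        raise ValueError(
            "adjudication requires ground truth (truth_mask or "
            "complete_annotations) or an explicit adjudication list"
        )
    tp_a = 0
    for box in unmatched:
        if truth_mask is not None:
            h, w = truth_mask.shape
            ys = slice(min(box.y0, h), min(box.y1, h))
            xs = slice(min(box.x0, w), min(box.x1, w))
            is_nerve = bool(truth_mask[ys, xs].any())
        else:
            is_nerve = any(box.intersects(a.box) for a in complete_annotations)
        tp_a += is_nerve
    return tp_a, len(unmatched) - tp_a


def sensitivity(TP_m: int, FN: int) -> float | None:
    """TPR = TP_m / (TP_m + FN); None (undefined) with no annotations."""
    if TP_m + FN == 0:
        return None
    return TP_m / (TP_m + FN)


def precision(TP_m: int, TP_a: int, FP: int) -> float | None:
    """PPV = (TP_m + TP_a) / (TP_m + TP_a + FP); None with no detections."""
    tp = TP_m + TP_a
    if tp + FP == 0:
        return None
    return tp / (tp + FP)


def evaluate_slide(
    boxes: Sequence[Box],
    expert_annotations: AnnotationSet,
    truth_mask: np.ndarray | None = None,
    complete_annotations: AnnotationSet | None = None,
    adjudications: Sequence[bool] | None = None,
    slide_id: str | None = None,
) -> EvalCounts:
    """Full hit-or-miss scoring of one slide's detections."""
    tp_m, fn, unmatched = match_detections(boxes, expert_annotations)
    tp_a, fp = adjudicate_additional(
        unmatched, truth_mask, complete_annotations, adjudications
    )
    return EvalCounts(
        slide_id=slide_id or expert_annotations.slide_id,
        n_annotations=len(expert_annotations),
        TP_m=tp_m, FN=fn, TP_a=tp_a, FP=fp,
    )


def aggregate(per_slide: Sequence[EvalCounts]) -> dict:
    """Overall report across slides.

    Overall TPR and PPV are unweighted means of the per-slide rates (slides
    with undefined values excluded); the count columns are sums.
    """
    if not per_slide:
        raise ValueError("at least one slide is required")
    tprs = [c.TPR for c in per_slide if c.TPR is not None]
    ppvs = [c.PPV for c in per_slide if c.PPV is not None]
    return {
        "n_slides": len(per_slide),
        "n_annotations": sum(c.n_annotations for c in per_slide),
        "TP_m": sum(c.TP_m for c in per_slide),
        "FN": sum(c.FN for c in per_slide),
        "TP_a": sum(c.TP_a for c in per_slide),
        "FP": sum(c.FP for c in per_slide),
        "TP": sum(c.TP for c in per_slide),
        "TPR": float(np.mean(tprs)) if tprs else None,
        "PPV": float(np.mean(ppvs)) if ppvs else None,
    }


def pairwise_agreement(scorer_labels: Sequence[Sequence]) -> dict:
    """Mean pairwise percentage agreement between k scorers' label vectors."""
    k = len(scorer_labels)
    if k < 2:
        raise ValueError("at least two scorers are required")
    n = len(scorer_labels[0])
    if any(len(s) != n for s in scorer_labels):
        raise ValueError("all scorers must label the same detections")
    pairs = {}
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(scorer_labels[i])
            b = np.asarray(scorer_labels[j])
            pairs[(i, j)] = float((a == b).mean() * 100.0)
    return {"pairs": pairs, "mean": float(np.mean(list(pairs.values())))}


def sample_precision_estimate(
    boxes: Sequence[Box],
    truth_mask: np.ndarray,
    n_samples: int = 100,
    seed: int = 0,
) -> tuple[int, int]:
    """Estimate (TP, FP) of a large detection set from a random sample.

    Used for detectors that flood a slide with predictions: ``n_samples``
    boxes are drawn without replacement and adjudicated against ground truth;
    the correct proportion is scaled to the full prediction count.
    """
    rng = np.random.default_rng(seed)
    boxes = list(boxes)
    if not boxes:
        return 0, 0
    if len(boxes) <= n_samples:
        sample = boxes
    else:
        idx = rng.choice(len(boxes), size=n_samples, replace=False)
        sample = [boxes[i] for i in idx]
    tp_s, _ = adjudicate_additional(sample, truth_mask=truth_mask)
    tp = int(round(tp_s / len(sample) * len(boxes)))
    return tp, len(boxes) - tp
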