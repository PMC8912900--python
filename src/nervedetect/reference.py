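"""Published per-slide reference counts for validating the metric arithmetic.

The package ships the per-slide hit-or-miss counts reported for a 22-slide
thyroid IHC test set evaluated with both the colour-filter detector (APR-CF)
and the CNN detector (APR-CNN), together with the sensitivity/precision
values printed alongside them, and the pairwise scoring-agreement
percentages of the three human scorers. Feeding the raw counts through this
package's sensitivity/precision/aggregation code must reproduce every
printed rate — a pure-arithmetic regression surface that needs no image
data. The APR-CF additional detections were too numerous for exhaustive
human review, so their TP_a/FP columns are estimates extrapolated from 100
randomly sampled predictions per slide.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import EvalCounts

__all__ = ["load_reference_counts", "reference_eval_counts", "SCORER_AGREEMENT_PCT"]

#: Mean pairwise percentage agreement of the three human scorers (E1-E2,
#: E1-E3, E2-E3) on the additional-detection adjudications.
SCORER_AGREEMENT_PCT: tuple[float, float, float] = (74.9, 79.3, 80.6)


def load_reference_counts() -> pd.DataFrame:
    """Per-slide reference counts plus the printed TPR/PPV columns."""
    with resources.files("nervedetect.data").joinpath(
        "reference_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"slide_id": str})


def reference_eval_counts(approach: str = "cnn") -> list[EvalCounts]:
    """Reference counts as EvalCounts, for 'cnn' (APR-CNN) or 'cf' (APR-CF).

    For the colour filter the estimated TP_a/FP columns are used.
    """
    if approach not in ("cnn", "cf"):
        raise ValueError("approach must be 'cnn' or 'cf'")
    df = load_reference_counts()
    prefix = approach
    tp_a_col = "cnn_tp_a" if approach == "cnn" else "cf_est_tp_a"
    fp_col = "cnn_fp" if approach == "cnn" else "cf_est_fp"
    out = []
    for _, row in df.iterrows():
        tp_m = int(row[f"{prefix}_tp_m"])
        out.append(
            EvalCounts(
                slide_id=row["slide_id"],
                n_annotations=int(row["n_annotations"]),
                TP_m=tp_m,
                FN=int(row["n_annotations"]) - tp_m,
                TP_a=int(row[tp_a_col]),
                FP=int(row[fp_col]),
            )
        )
    return out
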