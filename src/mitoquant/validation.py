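"""Scoring segmentations against synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LabelMap

__all__ = ["match_labels", "SegmentationScore", "score_segmentation"]


def match_labels(truth: np.ndarray, pred: np.ndarray) -> pd.DataFrame:
    """Best-overlap match of each truth label to a predicted label.

    Returns one row per truth label with the best-overlapping predicted
    label (0 when none overlaps) and the intersection-over-union of the
    matched pair.
    """
    rows = []
    for t in np.unique(truth):
        if t == 0:
            continue
        tmask = truth == t
        overlap_ids, overlap_counts = np.unique(pred[tmask], return_counts=True)
        fg = overlap_ids > 0
        if not fg.any():
            rows.append({"truth_label": int(t), "pred_label": 0, "iou": 0.0})
            continue
        best = overlap_ids[fg][np.argmax(overlap_counts[fg])]
        inter = int(overlap_counts[fg].max())
        union = int(tmask.sum()) + int((pred == best).sum()) - inter
        rows.append(
            {"truth_label": int(t), "pred_label": int(best), "iou": inter / union}
        )
    return pd.DataFrame(rows, columns=["truth_label", "pred_label", "iou"])


@dataclass
class SegmentationScore:
    mean_iou: float
    recall: float  # fraction of truth organelles matched with IoU >= iou_min
    n_truth: int
    n_pred: int
    per_organelle: pd.DataFrame


def score_segmentation(
    truth: LabelMap, pred: LabelMap, iou_min: float = 0.5
) -> SegmentationScore:
    """Per-organelle IoU and component recall of a predicted label map.

    The truth map may live on a coarser (anisotropic) grid than the
    prediction; it is nearest-neighbour resampled onto the prediction grid
    before matching.
    """
    t = truth.labels
    if t.shape != pred.labels.shape:
        factors = tuple(p / q for p, q in zip(pred.labels.shape, t.shape))
        t = ndimage.zoom(t, zoom=factors, order=0, mode="nearest", grid_mode=True)
        # zoom with exact factors can be off by one voxel per axis
        t = t[tuple(slice(0, n) for n in pred.labels.shape)]
        pad = [(0, max(0, n - m)) for n, m in zip(pred.labels.shape, t.shape)]
        if any(p[1] for p in pad):
            t = np.pad(t, pad)
    table = match_labels(t, pred.labels)
    n_truth = len(table)
    matched = table[table["iou"] >= iou_min]
    return SegmentationScore(
        mean_iou=float(table["iou"].mean()) if n_truth else float("nan"),
        recall=float(len(matched) / n_truth) if n_truth else float("nan"),
        n_truth=n_truth,
        n_pred=len(pred.ids),
        per_organelle=table,
    )
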