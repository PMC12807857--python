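"""Daughter-cell asymmetric-inheritance score and classification.

For one mitotic pair, the cargo inherited by each daughter is its
integrated density (sum of voxel intensities of the cargo channel over the
daughter mask). With ``P1``/``P2`` the oriented integrated densities, the
asymmetry score is

    s = (P1 - P2) / (P1 + P2),    s in [-1, 1],

and a pair is classified asymmetric when ``|s|`` strictly exceeds the
threshold (default 0.2; ``s = 0.2`` corresponds exactly to a 1.5x
inheritance ratio and is classified symmetric).

Orientation: with a reference channel (e.g. CD8 or the old-mitochondria
label), P1 is the cargo density of the reference-high daughter and the
score is signed; without one, P1 is simply the larger cargo density, the
score is nonnegative and the negative branch of the classification rule is
unreachable by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import VoxelGrid

__all__ = [
    "PairRecord",
    "integrated_density",
    "orient_pair",
    "asymmetry_score",
    "classify_pair",
    "min_asymmetric_ratio",
    "measure_pair",
    "pair_report",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.2


@dataclass
class PairRecord:
    """Measured quantities of one mitotic daughter pair."""

    pair_id: str
    cargo_channel: str
    P1: float
    P2: float
    orientation_rule: str  # "reference-marker" | "larger-first"
    score: float  # NaN for degenerate pairs
    classification: str  # "asymmetric" | "symmetric" | "degenerate"
    threshold: float = DEFAULT_THRESHOLD
    group: str = ""
    extras: dict = field(default_factory=dict)


def integrated_density(grid: VoxelGrid, mask: np.ndarray, channel: str) -> float:
    """Sum of voxel intensities of ``channel`` over ``mask``."""
    ch = grid.channel(channel)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ch.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {ch.shape}")
    if not mask.any():
        warnings.warn("integrated density over an empty mask is 0", stacklevel=2)
        return 0.0
    return float(ch[mask].sum())


def orient_pair(
    grid: VoxelGrid,
    masks: tuple[np.ndarray, np.ndarray],
    cargo_channel: str,
    reference_channel: str | None = None,
) -> tuple[float, float, str]:
    """Order the two daughters' cargo densities into (P1, P2).

    With a reference channel, P1 belongs to the reference-high daughter
    (the score may then be negative); a reference tie falls back to
    larger-first with a log note. Without a reference, P1 = max(Pa, Pb).
    """
    ma, mb = masks
    if np.logical_and(ma, mb).any():
        raise ValueError("daughter masks must be disjoint")
    pa = integrated_density(grid, ma, cargo_channel)
    pb = integrated_density(grid, mb, cargo_channel)
    if reference_channel is not None:
        ra = integrated_density(grid, ma, reference_channel)
        rb = integrated_density(grid, mb, reference_channel)
        if ra > rb:
            return pa, pb, "reference-marker"
        if rb > ra:
            return pb, pa, "reference-marker"
        logger.info("reference densities tied; falling back to larger-first")
    return max(pa, pb), min(pa, pb), "larger-first"


def asymmetry_score(P1: float, P2: float) -> float:
    """The asymmetric-inheritance score ``(P1 - P2) / (P1 + P2)``."""
    if P1 < 0 or P2 < 0:
        raise ValueError("integrated densities must be nonnegative")
    total = P1 + P2
    if total == 0:
        raise ValueError("degenerate pair: P1 + P2 = 0 has no defined score")
    return (P1 - P2) / total


def classify_pair(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """"asymmetric" iff the score strictly exceeds +/- threshold."""
    if not np.isfinite(score):
        return "degenerate"
    return "asymmetric" if (score > threshold or score < -threshold) else "symmetric"


def min_asymmetric_ratio(threshold: float = DEFAULT_THRESHOLD) -> float:
    """Smallest P1/P2 ratio classified asymmetric at the given threshold.

    Inverting ``s = (r - 1)/(r + 1)`` gives ``r = (1 + s)/(1 - s)``; at the
    default threshold 0.2 this is a 1.5x inheritance ratio.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    return (1 + threshold) / (1 - threshold)


def measure_pair(
    grid: VoxelGrid,
    masks: tuple[np.ndarray, np.ndarray],
    cargo_channel: str,
    reference_channel: str | None = None,
    pair_id: str = "pair",
    threshold: float = DEFAULT_THRESHOLD,
    group: str = "",
    cargo_intensity_threshold: float | str | None = None,
) -> PairRecord:
    """Measure, orient, score and classify one daughter pair.

    ``cargo_intensity_threshold`` emulates the per-fluorophore quantification
    threshold of confocal analyses: cargo voxels at or below it are excluded
    from the integrated density (otherwise diffuse background inside the
    large daughter masks dilutes the score toward 0). Pass a number, or
    ``"otsu"`` to derive it from the cargo channel's own histogram (top
    multi-Otsu threshold, 3 classes: background / halo / signal, matching
    the segmentation default). Orientation by the reference channel always
    uses the full daughter masks.
    """
    if cargo_intensity_threshold is not None:
        from .segmentation import multi_otsu_thresholds

        ch = grid.channel(cargo_channel)
        if cargo_intensity_threshold == "otsu":
            thr = float(multi_otsu_thresholds(ch, classes=3)[-1])
        else:
            thr = float(cargo_intensity_threshold)
        cargo_masks = tuple(np.asarray(m, dtype=bool) & (ch > thr) for m in masks)
    else:
        cargo_masks = masks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask warnings become degenerate pairs
        if reference_channel is not None:
            ra = integrated_density(grid, masks[0], reference_channel)
            rb = integrated_density(grid, masks[1], reference_channel)
            pa = integrated_density(grid, cargo_masks[0], cargo_channel)
            pb = integrated_density(grid, cargo_masks[1], cargo_channel)
            if ra != rb:
                p1, p2 = (pa, pb) if ra > rb else (pb, pa)
                rule = "reference-marker"
            else:
                logger.info("reference densities tied; falling back to larger-first")
                p1, p2, rule = max(pa, pb), min(pa, pb), "larger-first"
        else:
            p1, p2, rule = orient_pair(grid, cargo_masks, cargo_channel, None)
    if p1 + p2 == 0:
        return PairRecord(
            pair_id=pair_id, cargo_channel=cargo_channel, P1=p1, P2=p2,
            orientation_rule=rule, score=float("nan"),
            classification="degenerate", threshold=threshold, group=group,
        )
    s = asymmetry_score(p1, p2)
    return PairRecord(
        pair_id=pair_id, cargo_channel=cargo_channel, P1=p1, P2=p2,
        orientation_rule=rule, score=s,
        classification=classify_pair(s, threshold), threshold=threshold,
        group=group,
    )


def pair_report(pairs: list[PairRecord]) -> pd.DataFrame:
    """Per-group summary: asymmetric fraction, mean score, dispersion.

    Degenerate pairs are counted separately and excluded from the fraction
    and moments. Raises if every pair is degenerate.
    """
    if not pairs:
        raise ValueError("no pairs to report")
    df = pd.DataFrame(
        {
            "group": [p.group for p in pairs],
            "score": [p.score for p in pairs],
            "classification": [p.classification for p in pairs],
        }
    )
    if (df["classification"] == "degenerate").all():
        raise ValueError("all pairs are degenerate; nothing to summarize")
    rows = []
    for group, sub in df.groupby("group", sort=True):
        ok = sub[sub["classification"] != "degenerate"]
        scores = ok["score"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n_pairs": int(len(ok)),
                "n_degenerate": int(len(sub) - len(ok)),
                "fraction_asymmetric": float(
                    (ok["classification"] == "asymmetric").mean()
                ),
                "mean_score": float(scores.mean()),
                "sem_score": float(
                    scores.std(ddof=1) / np.sqrt(len(scores))
                ) if len(scores) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
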