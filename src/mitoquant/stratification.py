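"""Age-label (SnapTag) intensity stratification of organelles.

Organelles are binned into lo / mid / hi strata from two reference
thresholds derived from the cell classes themselves:

* ``t_lo`` — the maximum mean age-label intensity among organelles of
  lo-class cells (cells that carry only dim, post-mitotic label);
* ``t_hi`` — the 75th percentile (linear interpolation between order
  statistics) of mean age-label intensity among organelles of hi-class
  cells.

Organelles of lo-class cells are "lo" unconditionally. Within hi-class
cells: intensity <= t_lo -> "lo"; t_lo < intensity <= t_hi -> "mid";
intensity > t_hi -> "hi" (boundaries read strictly from the defining
phrases "below the maximum" / "above the 75th percentile").

The reference population is the current dataset; a saved
:class:`IntensityStrata` can be re-applied to new data for
cross-experiment comparability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["IntensityStrata", "compute_strata_thresholds", "assign_strata"]

logger = logging.getLogger(__name__)

LO_CELL = "lo-cell"
HI_CELL = "hi-cell"


@dataclass
class IntensityStrata:
    """The two stratification thresholds and their reference counts.

    ``percentile_method`` records the interpolation convention used for
    ``t_hi`` (linear interpolation between closest order statistics).
    ``t_hi < t_lo`` is legal and simply leaves the mid stratum empty.
    """

    t_lo: float
    t_hi: float
    n_reference_lo: int
    n_reference_hi: int
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_lo) and np.isfinite(self.t_hi)):
            raise ValueError("thresholds must be finite")
        if min(self.n_reference_lo, self.n_reference_hi) < 1:
            raise ValueError("reference counts must be >= 1")
        if self.t_hi < self.t_lo:
            logger.info(
                "t_hi (%.4g) < t_lo (%.4g): the mid stratum is empty",
                self.t_hi, self.t_lo,
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IntensityStrata":
        return cls(**json.loads(text))


def compute_strata_thresholds(
    features: pd.DataFrame, intensity_column: str = "mean_snaptag"
) -> IntensityStrata:
    """Derive the lo/hi thresholds from a per-organelle feature table.

    ``features`` needs a ``cell_class`` column holding "lo-cell"/"hi-cell"
    and the mean age-label intensity column. Both classes must be present.
    """
    for cls_name in (LO_CELL, HI_CELL):
        if not (features["cell_class"] == cls_name).any():
            raise ValueError(
                f"no organelles from class {cls_name!r}: cannot derive thresholds"
            )
    lo_vals = features.loc[features["cell_class"] == LO_CELL, intensity_column]
    hi_vals = features.loc[features["cell_class"] == HI_CELL, intensity_column]
    return IntensityStrata(
        t_lo=float(lo_vals.max()),
        t_hi=float(np.percentile(hi_vals.to_numpy(dtype=float), 75, method="linear")),
        n_reference_lo=int(len(lo_vals)),
        n_reference_hi=int(len(hi_vals)),
    )


def assign_strata(
    features: pd.DataFrame,
    strata: IntensityStrata,
    intensity_column: str = "mean_snaptag",
) -> pd.DataFrame:
    """Return a copy of ``features`` with a ``stratum`` column added."""
    out = features.copy()
    intensity = out[intensity_column].to_numpy(dtype=float)
    stratum = np.where(
        intensity > strata.t_hi, "hi",
        np.where(intensity > strata.t_lo, "mid", "lo"),
    )
    stratum[(out["cell_class"] == LO_CELL).to_numpy()] = "lo"
    out["stratum"] = stratum
    return out
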