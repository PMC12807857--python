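"""In-memory containers for multi-channel volumes and labelled segmentations.

Axis convention throughout the package: intensity data are indexed
``(channel, z, y, x)`` and label volumes ``(z, y, x)``, with physical voxel
spacing given per spatial axis in micrometres as ``(z, y, x)``. Coordinates
in any exported table are 0-based voxel indices in this axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["VoxelGrid", "LabelMap"]


@dataclass
class VoxelGrid:
    """A multi-channel 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    data:
        Nonnegative float array of shape ``(n_channels, nz, ny, nx)``.
    spacing_um:
        Physical voxel spacing ``(z, y, x)`` in micrometres.
    channel_names:
        One unique name per channel (e.g. ``"tom20"``, ``"snaptag"``).
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (channel, z, y, x) data, got ndim={self.data.ndim}"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names not unique: {self.channel_names}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.spacing_um
        return abs(z - y) < 1e-9 and abs(y - x) < 1e-9

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass
class LabelMap:
    """Integer-labelled 3D volume of segmented organelles.

    0 is background. Label ids are not required to be contiguous (the size
    filter removes ids without renumbering) but each id is one connected
    component at the stated connectivity. ``provenance`` is the ordered list
    of processing stages (name + parameters) that produced the map.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    connectivity: int = 26
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("negative label ids are not allowed")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of foreground label ids present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def sizes(self) -> dict[int, int]:
        """Voxel count per label id."""
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}

    def mask(self, label: int) -> np.ndarray:
        if label not in self.ids:
            raise KeyError(f"label {label} not present")
        return self.labels == label

    def with_stage(self, name: str, **params) -> "LabelMap":
        """Return self after appending a provenance entry (mutating helper)."""
        self.provenance.append({"stage": name, **params})
        return self


def connectivity_rank(connectivity: int) -> int:
    """Map 6/18/26 voxel connectivity to scikit-image's 1/2/3 rank convention."""
    return {6: 1, 18: 2, 26: 3}[connectivity]
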