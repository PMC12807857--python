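"""Reading and writing stacks, label maps and result tables.

Stacks are OME-TIFF with channel names and physical voxel spacing in the
metadata; label maps are 16-bit TIFF with a provenance JSON sidecar; tables
are CSV. Coordinates in all outputs are 0-based voxel indices on the
isotropic grid, axis order (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import LabelMap, VoxelGrid

__all__ = [
    "write_stack",
    "read_stack",
    "write_labelmap",
    "read_labelmap",
    "write_table",
]


def write_stack(path: str | Path, grid: VoxelGrid) -> Path:
    """Write a grid as OME-TIFF with spacing and channel-name metadata."""
    path = Path(path)
    sz, sy, sx = grid.spacing_um
    tifffile.imwrite(
        path,
        grid.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": sz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sx, "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(grid.channel_names)},
        },
    )
    return path


def read_stack(
    path: str | Path,
    spacing_um: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> VoxelGrid:
    """Read a TIFF/OME-TIFF stack into a VoxelGrid.

    Spacing and channel names come from the OME metadata; either can be
    overridden (and must be supplied when the metadata lacks them). 2D
    images are rejected: the pipeline is strictly volumetric.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_spacing = None
        meta_channels = None
        if tif.ome_metadata:
            ome = tifffile.xml2dict(tif.ome_metadata)
            pixels = ome.get("OME", {}).get("Image", {})
            if isinstance(pixels, list):
                pixels = pixels[0]
            pixels = pixels.get("Pixels", {})
            if all(f"PhysicalSize{a}" in pixels for a in "ZYX"):
                meta_spacing = tuple(
                    float(pixels[f"PhysicalSize{a}"]) for a in "ZYX"
                )
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            names = [c.get("Name") for c in chans if isinstance(c, dict)]
            if names and all(names):
                meta_channels = tuple(names)
    if data.ndim == 2:
        raise ValueError(
            f"{path} is a 2D image; the pipeline requires 3D z-stacks"
        )
    if data.ndim == 3:
        data = data[None]  # single channel
    if data.ndim != 4:
        raise ValueError(f"cannot interpret {path} with shape {data.shape}")
    spacing = spacing_um or meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel-spacing metadata; pass spacing_um explicitly"
        )
    names = channel_names or meta_channels \
        or tuple(f"channel{i}" for i in range(data.shape[0]))
    return VoxelGrid(
        data.astype(np.float64), spacing_um=spacing, channel_names=names
    )


def write_labelmap(path: str | Path, labelmap: LabelMap) -> Path:
    """Write labels as 16-bit TIFF plus a provenance JSON sidecar."""
    path = Path(path)
    if labelmap.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labelmap.labels.astype(np.uint16),
                     photometric="minisblack")
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "spacing_um": list(labelmap.spacing_um),
                "connectivity": labelmap.connectivity,
                "axes": "ZYX (0-based voxel indices)",
                "provenance": labelmap.provenance,
            },
            indent=2,
        )
    )
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    sidecar = path.with_suffix(".provenance.json")
    meta = json.loads(sidecar.read_text())
    return LabelMap(
        labels,
        spacing_um=tuple(meta["spacing_um"]),
        connectivity=int(meta["connectivity"]),
        provenance=list(meta["provenance"]),
    )


def write_table(path: str | Path, table: pd.DataFrame, header_note: str = "") -> Path:
    """CSV with a commented header noting axis order and units."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# mitoquant output; coordinates are 0-based voxel indices, "
                 "axis order (z, y, x); lengths in micrometres\n")
        if header_note:
            fh.write(f"# {header_note}\n")
        table.to_csv(fh, index=False)
    return path
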