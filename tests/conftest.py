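"""Shared fixtures: synthetic scenes, segmentations and phantom shapes.

Expensive artifacts (scenes, segmentations, populations) are session-scoped
so unit and end-to-end tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mitoquant.grids import LabelMap, VoxelGrid
from mitoquant.morphometry import compute_features
from mitoquant.segmentation import SegmentationConfig, resample_isotropic, segment_stack
from mitoquant.synthetic import (
    IntensityModel,
    PopulationScenes,
    SceneParams,
    make_cell_volume,
    make_population,
)

SCENE_SEED = 7
POPULATION_SEED = 42


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic cell scene (grid, truth) at a fixed seed."""
    params = SceneParams(seed=SCENE_SEED)
    grid, truth = make_cell_volume(params)
    return grid, truth, params


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """Default scene run through the full default segmentation stack."""
    grid, truth, _ = default_scene
    labelmap, iso = segment_stack(grid, SegmentationConfig())
    return labelmap, iso, truth


@pytest.fixture(scope="session")
def population() -> PopulationScenes:
    return make_population(4, 4, intensity_model=IntensityModel(), seed=POPULATION_SEED)


def truth_features(population: PopulationScenes) -> pd.DataFrame:
    """Per-organelle features measured on the truth label maps.

    The truth maps live on the anisotropic acquisition grid; they are
    nearest-neighbour resampled onto the isotropic grid so intensity
    features are measured exactly where the pipeline measures them.
    """
    rows = []
    for cell in population.cells:
        iso = resample_isotropic(cell.grid)
        t = cell.truth.label_map.labels
        factors = tuple(p / q for p, q in zip(iso.shape_zyx, t.shape))
        tl = ndimage.zoom(t, zoom=factors, order=0, mode="nearest", grid_mode=True)
        tl = tl[tuple(slice(0, n) for n in iso.shape_zyx)]
        lm = LabelMap(tl.astype(np.int32), spacing_um=iso.spacing_um)
        feats = compute_features(
            lm, iso,
            cell_ids={int(lab): cell.cell_id for lab in lm.ids},
            cell_classes={cell.cell_id: cell.cell_class},
        )
        planted = cell.truth.records.set_index("organelle_id")["stratum"]
        feats["planted_stratum"] = planted.loc[feats["organelle_id"]].to_numpy()
        rows.append(feats)
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def population_features(population) -> pd.DataFrame:
    return truth_features(population)


def digitized_sphere(radius_vox: int, spacing_um: float = 0.1,
                     value: float = 3.0) -> tuple[LabelMap, VoxelGrid]:
    """A solid digitized sphere as (label map, uniform-intensity grid)."""
    n = radius_vox + 5
    z, y, x = np.ogrid[: 2 * n, : 2 * n, : 2 * n]
    mask = (z - n) ** 2 + (y - n) ** 2 + (x - n) ** 2 <= radius_vox**2
    lm = LabelMap(mask.astype(np.int32), spacing_um=(spacing_um,) * 3)
    grid = VoxelGrid(
        np.full((1, *mask.shape), value), (spacing_um,) * 3, ("c",)
    )
    return lm, grid


def digitized_capsule(radius_vox: int, length_vox: int,
                      spacing_um: float = 0.1) -> tuple[LabelMap, VoxelGrid]:
    """A solid digitized capsule (cylinder + hemispherical caps) along x."""
    n = radius_vox + 5
    nx = length_vox + 2 * radius_vox + 10
    z, y, x = np.ogrid[: 2 * n, : 2 * n, :nx]
    x0 = 5 + radius_vox
    seg = np.clip(x - x0, 0, length_vox)
    mask = (z - n) ** 2 + (y - n) ** 2 + (x - x0 - seg) ** 2 <= radius_vox**2
    lm = LabelMap(mask.astype(np.int32), spacing_um=(spacing_um,) * 3)
    grid = VoxelGrid(np.ones((1, *mask.shape)), (spacing_um,) * 3, ("c",))
    return lm, grid
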