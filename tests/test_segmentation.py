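"""Segmentation stack: resampling, fusion, thresholds, cleanup, size filter."""

import numpy as np
import pytest
from skimage.filters import threshold_multiotsu

from mitoquant.grids import LabelMap, VoxelGrid
from mitoquant.segmentation import (
    SegmentationConfig,
    binarize_and_clean,
    enhance_outlines,
    filter_small,
    fuse_channels,
    label_components,
    multi_otsu_thresholds,
    resample_isotropic,
)
from mitoquant.validation import score_segmentation


def _grid(data, spacing=(0.13, 0.0433, 0.0433), names=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        data = data[None]
    names = names or tuple(f"c{i}" for i in range(data.shape[0]))
    return VoxelGrid(data, spacing, names)


# ---------------------------------------------------------------- resampling

def test_resample_constant_volume_stays_constant():
    g = _grid(np.full((6, 20, 20), 7.0))
    iso = resample_isotropic(g)
    assert iso.spacing_um == (0.0433,) * 3
    np.testing.assert_allclose(iso.data, 7.0, rtol=1e-6)


def test_resample_preserves_physical_extent():
    g = _grid(np.zeros((10, 30, 30)), spacing=(0.13, 0.043, 0.043))
    iso = resample_isotropic(g, 0.043)
    for ax in range(3):
        before = g.data.shape[1 + ax] * g.spacing_um[ax]
        after = iso.data.shape[1 + ax] * iso.spacing_um[ax]
        assert abs(before - after) <= g.spacing_um[ax] + 1e-9


def test_resample_preserves_blob_total_intensity():
    """Physical integral of a smooth Gaussian blob is conserved within 2%."""
    z, y, x = np.mgrid[:12, :36, :36].astype(float)
    blob = np.exp(-(((z - 6) * 0.13) ** 2 + ((y - 18) * 0.0433) ** 2
                    + ((x - 18) * 0.0433) ** 2) / (2 * 0.3**2))
    g = _grid(blob)
    iso = resample_isotropic(g)
    before = g.data.sum() * g.voxel_volume_um3
    after = iso.data.sum() * iso.voxel_volume_um3
    assert after == pytest.approx(before, rel=0.02)


def test_resample_rejects_bad_target():
    g = _grid(np.zeros((4, 8, 8)))
    with pytest.raises(ValueError):
        resample_isotropic(g, -0.1)
    with pytest.raises(ValueError):
        resample_isotropic(g, 1.0)  # coarser than input


# ------------------------------------------------------------------- fusion

def test_fuse_single_channel_is_minmax_normalization():
    vol = np.zeros((4, 5, 5))
    vol[2, 2, 2] = 10.0
    vol += 2.0
    fused = fuse_channels(_grid(vol))
    assert fused.min() == 0.0 and fused.max() == 1.0
    assert fused[2, 2, 2] == 1.0


def test_fuse_identical_channels_idempotent():
    vol = np.random.default_rng(0).random((4, 6, 6))
    two = fuse_channels(_grid(np.stack([vol, vol])))
    one = fuse_channels(_grid(vol))
    np.testing.assert_allclose(two, one)


def test_fused_support_is_union_of_channel_supports():
    """An organelle present only in the age channel still appears fused."""
    a = np.zeros((4, 8, 8))
    b = np.zeros((4, 8, 8))
    a[1, 1:3, 1:3] = 5.0
    b[2, 5:7, 5:7] = 7.0
    fused = fuse_channels(_grid(np.stack([a, b])))
    assert (fused[1, 1:3, 1:3] == 1.0).all()
    assert (fused[2, 5:7, 5:7] == 1.0).all()


def test_fuse_unknown_channel_rejected():
    with pytest.raises(KeyError):
        fuse_channels(_grid(np.zeros((4, 5, 5))), channels=("nope",))


# ----------------------------------------------------------------- outlines

def test_outline_enhancement_alpha_zero_is_identity():
    vol = np.random.default_rng(1).random((6, 10, 10))
    np.testing.assert_array_equal(enhance_outlines(vol, 0.1, 0.0, 0.05), vol)


def test_outline_enhancement_constant_stays_constant():
    vol = np.full((6, 10, 10), 0.4)
    out = enhance_outlines(vol, 0.1, 0.5, 0.05)
    np.testing.assert_allclose(out, 0.4)


def test_outline_term_peaks_on_step_edge():
    """For a step along x, the added gradient term is maximal on the edge."""
    vol = np.zeros((8, 8, 24))
    vol[:, :, 12:] = 1.0
    out = enhance_outlines(vol, 0.1, 1.0, 0.05)
    added = out - (vol - vol.min()) / (vol.max() - vol.min())
    profile = added.mean(axis=(0, 1))
    peak = np.argmax(np.abs(np.diff(vol.mean(axis=(0, 1))))) + 1  # edge plane
    assert abs(int(np.argmax(profile)) - peak) <= 1
    with pytest.raises(ValueError):
        enhance_outlines(vol, -0.1, 0.5, 0.05)


# --------------------------------------------------------------- multi-Otsu

def canonical_cuts(cuts, hist):
    """Map each cut bin to the last nonempty bin at or before it.

    Cuts that differ only across a run of empty bins induce the same class
    partition (identical between-class variance up to float roundoff).
    """
    nonempty = np.nonzero(hist)[0]
    return tuple(int(nonempty[nonempty <= c].max()) for c in cuts)


def test_bimodal_two_values_threshold_strictly_between():
    vol = np.array([0.0] * 1000 + [10.0] * 1000)
    (t,) = multi_otsu_thresholds(vol, classes=2)
    assert 0.0 < t < 10.0


def brute_force_otsu(vol, classes, nbins):
    """Independent oracle: direct search maximizing between-class variance."""
    import itertools

    hist, edges = np.histogram(vol, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best, best_var = None, -np.inf
    for cuts in itertools.combinations(range(nbins - 1), classes - 1):
        bounds = (0, *[c + 1 for c in cuts], nbins)
        var = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            w = hist[a:b].sum()
            if w:
                mu = (hist[a:b] * centers[a:b]).sum() / w
                var += (w / total) * mu * mu
        if var > best_var + 1e-12:
            best_var, best = var, cuts
    return best


@pytest.mark.parametrize("classes", [2, 3])
def test_multi_otsu_matches_exhaustive_search(classes):
    """Implementation cuts equal an independent exhaustive search on a
    64-bin histogram (three well-separated modes)."""
    rng = np.random.default_rng(4)
    vol = np.concatenate(
        [rng.normal(10, 2, 4000), rng.normal(50, 4, 3000), rng.normal(120, 6, 3000)]
    )
    nbins = 64
    thresholds = multi_otsu_thresholds(vol, classes, nbins)
    hist, edges = np.histogram(vol, bins=nbins)
    mine = [int(np.searchsorted(edges, t)) - 1 for t in thresholds]
    assert canonical_cuts(mine, hist) == canonical_cuts(
        brute_force_otsu(vol, classes, nbins), hist
    )
    if classes == 3:
        # thresholds fall between adjacent mode pairs
        assert 10 < thresholds[0] < 50 < thresholds[1] < 120


@pytest.mark.parametrize("classes", [2, 3])
def test_multi_otsu_agrees_with_skimage(classes):
    """Cross-check against scikit-image's implementation at cut-bin level
    (scikit-image reports bin centers; we report bin edges)."""
    rng = np.random.default_rng(8)
    vol = np.concatenate(
        [rng.normal(5, 1, 5000), rng.normal(30, 3, 2000), rng.normal(90, 5, 1000)]
    )
    nbins = 64
    hist, edges = np.histogram(vol, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    mine = [int(np.searchsorted(edges, t)) - 1
            for t in multi_otsu_thresholds(vol, classes, nbins)]
    sk = [int(np.searchsorted(centers, t))
          for t in threshold_multiotsu(vol, classes=classes, nbins=nbins)]
    assert canonical_cuts(mine, hist) == canonical_cuts(sk, hist)


def test_multi_otsu_needs_enough_distinct_values():
    with pytest.raises(ValueError):
        multi_otsu_thresholds(np.zeros(100), classes=2)


# ------------------------------------------------------------------ cleanup

def _sphere_mask(shape, center, r):
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2 <= r * r


def test_cleanup_fills_interior_hole():
    vol = _sphere_mask((21, 21, 21), (10, 10, 10), 6).astype(float)
    vol[10, 10, 10] = 0.0  # one interior hole voxel
    cfg = SegmentationConfig()
    mask = binarize_and_clean(vol, np.array([0.5]), cfg)
    assert mask[10, 10, 10]


def test_erosion_separates_kissing_spheres():
    """Two spheres touching at one voxel are split by the final erosion."""
    from skimage.measure import label as sklabel

    shape = (25, 25, 45)
    a = _sphere_mask(shape, (12, 12, 12), 8)
    b = _sphere_mask(shape, (12, 12, 29), 8)
    vol = (a | b).astype(float)
    assert sklabel(vol > 0.5, connectivity=3).max() == 1  # touching
    cfg = SegmentationConfig(morph_ops=(("erosion", 1),))
    mask = binarize_and_clean(vol, np.array([0.5]), cfg)
    assert sklabel(mask, connectivity=3).max() == 2


def test_cleanup_empty_input_warns_not_raises():
    cfg = SegmentationConfig()
    with pytest.warns(UserWarning):
        mask = binarize_and_clean(np.zeros((8, 8, 8)), np.array([0.5]), cfg)
    assert not mask.any()


# ----------------------------------------------------------------- labeling

def test_label_components_empty_and_disjoint():
    spacing = (0.05,) * 3
    empty = label_components(np.zeros((6, 6, 6), bool), spacing)
    assert len(empty.ids) == 0
    two = np.zeros((10, 10, 30), bool)
    two |= _sphere_mask(two.shape, (5, 5, 6), 3)
    two |= _sphere_mask(two.shape, (5, 5, 22), 3)
    assert len(label_components(two, spacing).ids) == 2


def test_diagonal_chain_connectivity_dependence():
    """A diagonal voxel chain is one component at 26-connectivity but
    falls apart at 6-connectivity."""
    mask = np.zeros((3, 3, 3), bool)
    mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 2, 2] = True
    spacing = (0.05,) * 3
    assert len(label_components(mask, spacing, connectivity=26).ids) == 1
    assert len(label_components(mask, spacing, connectivity=6).ids) == 3


# -------------------------------------------------------------- size filter

def _labelmap_with_sizes(sizes):
    """Disjoint rectangular labels with exactly the requested voxel counts."""
    width = 12
    arr = np.zeros((10, 12, width * len(sizes)), dtype=np.int32)
    for i, size in enumerate(sizes):
        nz = size // (10 * 10) + 1
        flat = np.zeros(10 * 10 * nz, dtype=np.int32)
        flat[:size] = i + 1
        arr[:, :10, i * width : i * width + nz] = flat.reshape(10, 10, nz)
    return LabelMap(arr, spacing_um=(0.05,) * 3)


def test_filter_small_strict_boundary():
    lm = _labelmap_with_sizes([100, 499, 500, 800])
    out = filter_small(lm, min_voxels=500)
    assert set(out.ids.tolist()) == {3, 4}  # 500 kept, 499 removed
    sizes = out.sizes()
    assert sizes[3] == 500 and sizes[4] == 800


def test_filter_small_min1_is_identity():
    lm = _labelmap_with_sizes([7, 30])
    out = filter_small(lm, min_voxels=1)
    np.testing.assert_array_equal(out.labels, lm.labels)


# ------------------------------------------------- end-to-end on synthetics

def test_default_scene_segmentation_quality(segmented_scene):
    """On the default noise-level scene: mean per-organelle IoU >= 0.7 and
    component recall >= 0.9 against ground truth."""
    labelmap, _, truth = segmented_scene
    score = score_segmentation(truth.label_map, labelmap)
    assert score.mean_iou >= 0.7
    assert score.recall >= 0.9


def test_provenance_records_all_stages(segmented_scene):
    labelmap, _, _ = segmented_scene
    stages = [p["stage"] for p in labelmap.provenance]
    assert stages == [
        "resample_isotropic", "fuse_channels", "enhance_outlines",
        "multi_otsu", "binarize_and_clean", "label", "filter_small",
    ]


def test_adding_organelle_does_not_decrease_component_count():
    """Pipeline monotonicity on noise-free phantoms: one more large, bright
    organelle never lowers the surviving component count."""
    from mitoquant.synthetic import NoiseModel, SceneParams, make_cell_volume
    from mitoquant.segmentation import segment_stack

    counts = []
    for n in (4, 5):
        params = SceneParams(
            n_organelles=n, noise=NoiseModel(False, 0.0, 0.0), seed=21
        )
        grid, _ = make_cell_volume(params)
        labelmap, _ = segment_stack(grid)
        counts.append(len(labelmap.ids))
    assert counts[1] >= counts[0]
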