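"""Morphometry: closed-form shapes, invariants, scaling, embedding, KDE."""

import numpy as np
import pandas as pd
import pytest

from conftest import digitized_capsule, digitized_sphere

from mitoquant.grids import LabelMap, VoxelGrid
from mitoquant.morphometry import (
    GEOMETRIC_FEATURES,
    compute_features,
    embed_features,
    kde_density,
    standardize_features,
    surface_area,
)


@pytest.fixture(scope="module")
def sphere_features():
    lm, grid = digitized_sphere(10, spacing_um=0.1, value=3.0)
    return compute_features(lm, grid)


@pytest.fixture(scope="module")
def capsule_features():
    lm, grid = digitized_capsule(10, 100, spacing_um=0.1)  # length 10 r
    return compute_features(lm, grid)


def test_sphere_surface_area_within_5pct():
    lm, _ = digitized_sphere(10, spacing_um=0.1)
    area = surface_area(lm, 1)
    assert area == pytest.approx(4 * np.pi * 1.0**2, rel=0.05)


def test_surface_area_missing_label_raises():
    lm, _ = digitized_sphere(5)
    with pytest.raises(KeyError):
        surface_area(lm, 99)


def test_single_voxel_has_positive_finite_area():
    arr = np.zeros((5, 5, 5), dtype=np.int32)
    arr[2, 2, 2] = 1
    area = surface_area(LabelMap(arr, (0.1,) * 3), 1)
    assert np.isfinite(area) and area > 0


def test_surface_area_translation_invariant():
    arr = np.zeros((30, 30, 40), dtype=np.int32)
    z, y, x = np.ogrid[:30, :30, :40]
    arr[(z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 36] = 1
    shifted = np.roll(arr, (3, 5, 8), axis=(0, 1, 2))
    lm1 = LabelMap(arr, (0.1,) * 3)
    lm2 = LabelMap(shifted, (0.1,) * 3)
    assert surface_area(lm1, 1) == pytest.approx(surface_area(lm2, 1), rel=1e-9)


def test_sphere_closed_forms(sphere_features):
    """Digitized sphere: psi in [0.9, 1], MCI in [1, 1.2], roundness and
    compactness near 1."""
    f = sphere_features.iloc[0]
    assert 0.9 <= f["sphericity"] <= 1.0
    assert 1.0 <= f["complexity"] <= 1.2
    assert f["roundness"] > 0.95
    assert f["compactness"] > 0.9
    assert f["volume_um3"] == pytest.approx(4 / 3 * np.pi * 1.0**3, rel=0.01)


def test_capsule_vs_sphere_ordering(sphere_features, capsule_features):
    """A 10r-long capsule is less spherical, less round and more complex
    than the sphere."""
    s, c = sphere_features.iloc[0], capsule_features.iloc[0]
    assert c["sphericity"] < s["sphericity"]
    assert c["roundness"] < s["roundness"]
    assert c["complexity"] > s["complexity"]
    # capsule closed forms: V = pi r^2 L + 4/3 pi r^3, SA = 2 pi r L + 4 pi r^2
    V = np.pi * 1.0**2 * 10.0 + 4 / 3 * np.pi
    SA = 2 * np.pi * 1.0 * 10.0 + 4 * np.pi
    psi_true = np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / SA
    assert c["sphericity"] == pytest.approx(psi_true, rel=0.06)


def test_complexity_times_sphericity_cubed_is_one(population_features):
    """MCI * psi^3 = 1 holds algebraically on every record."""
    prod = population_features["complexity"] * population_features["sphericity"] ** 3
    np.testing.assert_allclose(prod, 1.0, rtol=1e-9)


def test_psi_and_mci_scale_invariant():
    """Rescaling the voxel spacing leaves sphericity and complexity
    unchanged (V ~ s^3, SA ~ s^2)."""
    lm1, g1 = digitized_sphere(8, spacing_um=0.1)
    lm2, g2 = digitized_sphere(8, spacing_um=0.25)
    f1 = compute_features(lm1, g1).iloc[0]
    f2 = compute_features(lm2, g2).iloc[0]
    assert f1["sphericity"] == pytest.approx(f2["sphericity"], rel=1e-9)
    assert f1["complexity"] == pytest.approx(f2["complexity"], rel=1e-9)
    assert f2["volume_um3"] == pytest.approx(f1["volume_um3"] * 2.5**3, rel=1e-9)


def test_uniform_intensity_mean_and_integrated(sphere_features):
    f = sphere_features.iloc[0]
    assert f["mean_c"] == pytest.approx(3.0)
    assert f["integrated_c"] == pytest.approx(3.0 * f["voxel_count"])


def test_mean_equals_integrated_over_count(population_features):
    np.testing.assert_allclose(
        population_features["mean_snaptag"],
        population_features["integrated_snaptag"]
        / population_features["voxel_count"],
        rtol=1e-12,
    )


def test_features_permutation_invariant_over_label_ids():
    lm, grid = digitized_sphere(6, spacing_um=0.1)
    arr = lm.labels.copy()
    arr2 = np.where(arr == 1, 5, 0).astype(np.int32)
    f1 = compute_features(LabelMap(arr, lm.spacing_um), grid)
    f2 = compute_features(LabelMap(arr2, lm.spacing_um), grid)
    for col in GEOMETRIC_FEATURES:
        assert f1[col].iloc[0] == pytest.approx(f2[col].iloc[0], rel=1e-12)


def test_geometry_mismatch_rejected():
    lm, _ = digitized_sphere(5)
    other = VoxelGrid(np.zeros((1, 4, 4, 4)), (0.1,) * 3, ("c",))
    with pytest.raises(ValueError):
        compute_features(lm, other)


def test_tubule_rich_cells_have_higher_complexity():
    """Tubule-dominated synthetic cells average a higher complexity index
    than sphere-dominated ones."""
    from mitoquant.synthetic import NoiseModel, SceneParams, make_cell_volume
    from mitoquant.segmentation import resample_isotropic
    from scipy import ndimage

    means = {}
    for name, mix in (("spheres", 0.0), ("tubules", 1.0)):
        params = SceneParams(
            n_organelles=8, shape_mix=mix, seed=31,
            noise=NoiseModel(False, 0.0, 0.0),
        )
        grid, truth = make_cell_volume(params)
        iso = resample_isotropic(grid)
        t = truth.label_map.labels
        factors = tuple(p / q for p, q in zip(iso.shape_zyx, t.shape))
        tl = ndimage.zoom(t, zoom=factors, order=0, mode="nearest", grid_mode=True)
        lm = LabelMap(tl.astype(np.int32), spacing_um=iso.spacing_um)
        means[name] = compute_features(lm, iso)["complexity"].mean()
    assert means["tubules"] > means["spheres"]


# ---------------------------------------------------------- standardization

def test_standardize_zscores_and_roundtrip(population_features):
    mat, record = standardize_features(population_features)
    np.testing.assert_allclose(mat.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(mat.std(axis=0, ddof=0), 1.0, rtol=1e-9)
    # intensity columns are excluded by default
    assert not any(c.startswith(("mean_", "integrated_")) for c in mat.columns)
    # applying the record to held-out rows reproduces the transform
    held = population_features.iloc[:5]
    np.testing.assert_allclose(
        record.transform(held).to_numpy(), mat.iloc[:5].to_numpy(), rtol=1e-12
    )


def test_standardize_drops_zero_variance_column():
    df = pd.DataFrame(
        {
            "volume_um3": [1.0, 2.0, 3.0],
            "surface_area_um2": [5.0, 5.0, 5.0],
        }
    )
    mat, record = standardize_features(df, ("volume_um3", "surface_area_um2"))
    assert record.dropped == ("surface_area_um2",)
    assert list(mat.columns) == ["volume_um3"]
    with pytest.raises(ValueError):
        standardize_features(
            pd.DataFrame({"volume_um3": [1.0, 1.0]}), ("volume_um3",)
        )


# ---------------------------------------------------------------- embedding

@pytest.fixture(scope="module")
def two_family_embedding():
    rng = np.random.default_rng(0)
    fam = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(5, 1, (40, 5))])
    labels = np.r_[np.zeros(40), np.ones(40)]
    return embed_features(fam, seed=3), fam, labels


def test_embedding_deterministic_under_seed(two_family_embedding):
    coords, fam, _ = two_family_embedding
    np.testing.assert_array_equal(coords, embed_features(fam, seed=3))


def test_embedding_separates_shape_families(two_family_embedding):
    from sklearn.metrics import silhouette_score

    coords, _, labels = two_family_embedding
    assert silhouette_score(coords, labels) > 0


def test_embedding_handles_duplicated_points():
    mat = np.tile([[1.0, 2.0, 3.0]], (12, 1))
    with pytest.warns(UserWarning):
        coords = embed_features(mat, seed=0, n_neighbors=15)
    assert np.isfinite(coords).all()


# --------------------------------------------------------------------- KDE

def test_kde_integrates_to_one_and_mode_location():
    rng = np.random.default_rng(2)
    pts = rng.normal([2.0, -1.0], 0.1, (200, 2))
    grid = kde_density(pts)
    assert grid.total_mass() == pytest.approx(1.0, abs=0.01)
    iy, ix = np.unravel_index(np.argmax(grid.density), grid.density.shape)
    assert grid.x[ix] == pytest.approx(2.0, abs=0.1)
    assert grid.y[iy] == pytest.approx(-1.0, abs=0.1)


def test_kde_two_equal_clusters_two_equal_modes():
    """Mirror-symmetric twin clusters give two modes of equal height."""
    rng = np.random.default_rng(3)
    cluster = rng.normal([3, 0], 0.2, (300, 2))
    mirrored = cluster * [-1, 1]
    grid = kde_density(np.vstack([cluster, mirrored]))
    mid = grid.density.shape[1] // 2
    left = grid.density[:, :mid].max()
    right = grid.density[:, mid:].max()
    assert left == pytest.approx(right, rel=0.05)
    assert left > grid.density[:, mid - 2 : mid + 2].max()  # two separate modes


def test_kde_rejects_bad_bandwidth():
    pts = np.random.default_rng(0).random((10, 2))
    with pytest.raises(ValueError):
        kde_density(pts, bandwidth=-1.0)
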