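"""Ground-truthed synthetic confocal scenes of mitochondria in small cells.

The generator emulates the data the analysis pipeline expects: anisotropic
two-channel z-stacks of a small lymphocyte whose mitochondria are tubules
(capsules: cylinders with hemispherical caps) or puncta (spheres), carrying

* a structural channel in which every organelle is labelled (a Tom20-like
  pan-mitochondrial marker), and
* an age channel with a two-component intensity mixture (bright "old",
  i.e. pre-mitotic, organelles vs dim "young" post-mitotic ones).

Images are rendered as photon rates on the voxel grid, blurred with a
separable Gaussian PSF, then Poisson-sampled with additive Gaussian read
noise. The noise-free truth (label map + per-organelle records) is kept so
segmentation, morphometry and stratification can be scored against it.

Also provided: mitotic daughter-cell pairs with a controllable cargo
partition fraction ``f`` (noise-free asymmetry score ``2 f - 1``), and
two-class cell populations for testing the lo/mid/hi age-label
stratification rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import LabelMap, VoxelGrid

__all__ = [
    "SceneParams",
    "NoiseModel",
    "GroundTruth",
    "CapacityError",
    "make_cell_volume",
    "make_daughter_pair",
    "make_population",
    "IntensityModel",
    "PopulationScenes",
    "CellScene",
    "DaughterPair",
]

STRUCTURAL_CHANNEL = "tom20"
AGE_CHANNEL = "snaptag"
CARGO_CHANNEL = "cargo"
REFERENCE_CHANNEL = "reference"


class CapacityError(RuntimeError):
    """Raised when organelles cannot be placed without overlap."""


@dataclass
class NoiseModel:
    """Photon-counting noise: Poisson shot noise plus Gaussian read noise."""

    poisson: bool = True
    read_noise_sd: float = 2.0
    background: float = 5.0

    def apply(self, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        img = rates + self.background
        if self.poisson:
            img = rng.poisson(img).astype(np.float64)
        if self.read_noise_sd > 0:
            img = img + rng.normal(0.0, self.read_noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)


@dataclass
class SceneParams:
    """Parameters of one synthetic cell scene.

    Defaults describe a just-divided murine CD8+ T cell imaged on a confocal
    system with 0.13 um z-steps and ~3x finer xy sampling: a flattened
    ellipsoidal cell of ~5 um diameter containing a dozen organelles with
    tubule radius ~0.3 um, imaged with a near-diffraction-limited PSF.
    """

    n_organelles: int = 12
    shape_mix: float = 0.6  # fraction of tubules (rest are spheroids)
    radius_um: float = 0.3
    tubule_length_um: tuple[float, float] = (0.8, 2.2)  # cylinder-part length range
    old_fraction: float = 0.5
    intensity_old: float = 500.0  # age-channel photon rate of old organelles
    intensity_young: float = 60.0
    structural_intensity: float = 300.0
    psf_sigma_um: tuple[float, float, float] = (0.15, 0.06, 0.06)
    spacing_um: tuple[float, float, float] = (0.13, 0.0433, 0.0433)
    cell_radii_um: tuple[float, float, float] = (1.7, 2.4, 2.4)  # ellipsoid semi-axes
    noise: NoiseModel = field(default_factory=NoiseModel)
    clearance_um: float = 0.25  # minimum gap between organelle surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        for name in ("shape_mix", "old_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        lo, hi = self.tubule_length_um
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad tubule_length_um range {self.tubule_length_um}")
        if min(self.intensity_old, self.intensity_young) < 0:
            raise ValueError("intensities must be nonnegative")
        sz, sy, sx = self.spacing_um
        if min(self.spacing_um) <= 0:
            raise ValueError("spacing must be positive")
        if sz < max(sy, sx) - 1e-12:
            raise ValueError("z spacing must be >= xy spacing (anisotropic stacks)")
        if any(r <= 0 for r in self.cell_radii_um):
            raise ValueError("cell radii must be positive")


@dataclass
class GroundTruth:
    """Noise-free truth of a synthetic scene.

    ``records`` has one row per organelle (id, geometry, age class, true
    analytic volume, voxel count, per-channel emitted rates). For daughter
    pairs, ``partition_fraction`` stores the planted cargo fraction ``f``
    going to daughter 1 and ``degenerate`` flags zero-cargo pairs.
    """

    label_map: LabelMap
    records: pd.DataFrame
    partition_fraction: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        ids_map = set(int(i) for i in self.label_map.ids)
        ids_rec = set(int(i) for i in self.records.get("organelle_id", []))
        if ids_map != ids_rec:
            raise ValueError("truth record ids do not match the truth label map")
        n_fg = int((self.label_map.labels > 0).sum())
        n_rec = int(self.records["voxel_count"].sum()) if len(self.records) else 0
        if n_fg != n_rec:
            raise ValueError("per-organelle voxel counts do not sum to foreground size")


@dataclass
class CellScene:
    cell_id: str
    cell_class: str  # "lo-cell" | "hi-cell"
    grid: VoxelGrid
    truth: GroundTruth


@dataclass
class PopulationScenes:
    cells: list[CellScene]

    def truth_table(self) -> pd.DataFrame:
        """Concatenated per-organelle truth records with cell id/class."""
        frames = []
        for c in self.cells:
            df = c.truth.records.copy()
            df.insert(0, "cell_id", c.cell_id)
            df.insert(1, "cell_class", c.cell_class)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class DaughterPair:
    grid: VoxelGrid
    daughter_masks: tuple[np.ndarray, np.ndarray]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry helpers


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments p1-q1 and p2-q2."""
    # standard clamped closest-point computation
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _capsule_mask(shape, spacing, p, q, radius) -> tuple[np.ndarray, tuple]:
    """Boolean mask of a capsule (segment p-q dilated by radius), in a bbox.

    Returns (mask within bbox, bbox slices). ``p``/``q`` in um, axis (z,y,x).
    """
    spacing = np.asarray(spacing)
    lo_um = np.minimum(p, q) - radius
    hi_um = np.maximum(p, q) + radius
    lo = np.maximum(np.floor(lo_um / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(hi_um / spacing).astype(int) + 2, shape)
    if np.any(hi <= lo):
        return np.zeros((0, 0, 0), dtype=bool), tuple(slice(0, 0) for _ in range(3))
    coords = np.meshgrid(
        *[(np.arange(lo[i], hi[i]) + 0.5) * spacing[i] for i in range(3)],
        indexing="ij",
    )
    pts = np.stack(coords, axis=-1)  # (...,3) voxel centres in um
    d = q - p
    dd = float(d @ d)
    if dd < 1e-18:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(((pts - p) @ d) / dd, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    slices = tuple(slice(int(lo[i]), int(hi[i])) for i in range(3))
    return dist <= radius, slices


def _capsule_volume(radius: float, length: float) -> float:
    """Analytic volume of a capsule; length is the cylinder part (0 = sphere)."""
    return np.pi * radius**2 * length + 4.0 / 3.0 * np.pi * radius**3


# ---------------------------------------------------------------------------
# scene generation


def _place_organelles(params: SceneParams, rng: np.random.Generator,
                      strata: Sequence[str] | None = None) -> list[dict]:
    """Sample non-overlapping capsule/sphere placements inside the cell."""
    placements: list[dict] = []
    cell_r = np.asarray(params.cell_radii_um)
    max_tries = 200 * max(params.n_organelles, 1)
    tries = 0
    n_tubules = int(round(params.shape_mix * params.n_organelles))
    n_old = int(round(params.old_fraction * params.n_organelles))
    for i in range(params.n_organelles):
        kind = "tubule" if i < n_tubules else "sphere"
        age = "old" if i < n_old else "young"
        while True:
            tries += 1
            if tries > max_tries:
                raise CapacityError(
                    f"could not place {params.n_organelles} organelles of radius "
                    f"{params.radius_um} um in the cell after {max_tries} attempts; "
                    "reduce n_organelles or organelle size"
                )
            if kind == "tubule":
                length = rng.uniform(*params.tubule_length_um)
            else:
                length = 0.0
            # random orientation; endpoints of the cylinder axis
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            half = 0.5 * length * u
            # centre sampled uniformly in the ellipsoid; accept only if both
            # endpoints, dilated by the radius, stay inside the cell
            w = rng.normal(size=3)
            w /= np.linalg.norm(w)
            rad = rng.uniform() ** (1.0 / 3.0)
            center = w * rad * cell_r
            p, q = center - half, center + half
            inner = np.maximum(cell_r - params.radius_um, 1e-6)
            if any(np.sum((e / inner) ** 2) > 1.0 for e in (p, q)):
                continue
            ok = True
            for other in placements:
                dmin = _segment_distance(p, q, other["p"], other["q"])
                if dmin < 2 * params.radius_um + params.clearance_um:
                    ok = False
                    break
            if ok:
                break
        placements.append(
            {
                "organelle_id": i + 1,
                "kind": kind,
                "age_class": age,
                "stratum": strata[i] if strata is not None else None,
                "p": p,
                "q": q,
                "radius_um": params.radius_um,
                "length_um": length,
            }
        )
    return placements


def _render_scene(
    params: SceneParams,
    placements: list[dict],
    age_rates: Sequence[float],
    rng: np.random.Generator,
) -> tuple[VoxelGrid, LabelMap, pd.DataFrame]:
    """Rasterize placements, blur, add noise; return grid + truth."""
    spacing = np.asarray(params.spacing_um)
    margin_um = params.radius_um + 4 * max(params.psf_sigma_um)
    extent = 2 * (np.asarray(params.cell_radii_um) + margin_um)
    shape = tuple(int(np.ceil(extent[i] / spacing[i])) for i in range(3))
    offset = extent / 2.0  # cell centre in um

    labels = np.zeros(shape, dtype=np.int32)
    structural = np.zeros(shape, dtype=np.float64)
    age = np.zeros(shape, dtype=np.float64)
    records = []
    for plc, rate in zip(placements, age_rates):
        mask, slc = _capsule_mask(
            shape, spacing, plc["p"] + offset, plc["q"] + offset, plc["radius_um"]
        )
        labels[slc][mask] = plc["organelle_id"]
        structural[slc][mask] += params.structural_intensity
        age[slc][mask] += rate
        records.append(
            {
                "organelle_id": plc["organelle_id"],
                "kind": plc["kind"],
                "age_class": plc["age_class"],
                "stratum": plc["stratum"],
                "true_volume_um3": _capsule_volume(plc["radius_um"], plc["length_um"]),
                "voxel_count": int(mask.sum()),
                "radius_um": plc["radius_um"],
                "length_um": plc["length_um"],
                "structural_rate": params.structural_intensity,
                "age_rate": rate,
                "center_z_um": float((plc["p"][0] + plc["q"][0]) / 2 + offset[0]),
                "center_y_um": float((plc["p"][1] + plc["q"][1]) / 2 + offset[1]),
                "center_x_um": float((plc["p"][2] + plc["q"][2]) / 2 + offset[2]),
            }
        )
    columns = [
        "organelle_id", "kind", "age_class", "stratum", "true_volume_um3",
        "voxel_count", "radius_um", "length_um", "structural_rate", "age_rate",
        "center_z_um", "center_y_um", "center_x_um",
    ]
    records_df = pd.DataFrame(records, columns=columns)

    sigma_vox = tuple(params.psf_sigma_um[i] / spacing[i] for i in range(3))
    channels = []
    for rates in (structural, age):
        blurred = gaussian_filter(rates, sigma=sigma_vox)
        channels.append(params.noise.apply(blurred, rng))
    grid = VoxelGrid(
        np.stack(channels),
        spacing_um=params.spacing_um,
        channel_names=(STRUCTURAL_CHANNEL, AGE_CHANNEL),
    )
    label_map = LabelMap(
        labels,
        spacing_um=params.spacing_um,
        connectivity=26,
        provenance=[{"stage": "synthetic_truth", "seed": params.seed}],
    )
    return grid, label_map, records_df


def make_cell_volume(params: SceneParams) -> tuple[VoxelGrid, GroundTruth]:
    """Generate one two-channel cell scene and its ground truth.

    Old organelles carry the bright age-label rate ``intensity_old``; young
    ones the dim ``intensity_young``. Identical parameters (including seed)
    give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    placements = _place_organelles(params, rng)
    age_rates = [
        params.intensity_old if p["age_class"] == "old" else params.intensity_young
        for p in placements
    ]
    grid, label_map, records = _render_scene(params, placements, age_rates, rng)
    return grid, GroundTruth(label_map=label_map, records=records)


# ---------------------------------------------------------------------------
# daughter pairs


def make_daughter_pair(
    f: float,
    total_cargo: float = 2.0e5,
    noise: NoiseModel | None = None,
    seed: int = 0,
    daughter_radius_um: float = 2.2,
    bridge_um: float = 0.8,
    spacing_um: tuple[float, float, float] = (0.13, 0.0433, 0.0433),
    n_puncta: int = 8,
    psf_sigma_um: tuple[float, float, float] = (0.15, 0.06, 0.06),
) -> DaughterPair:
    """Simulate a late-anaphase daughter pair with planted cargo partition ``f``.

    Two spherical daughters separated by a thin cytokinetic bridge (excluded
    from both masks) contain punctate cargo; the expected integrated density
    in daughter 1 is ``f * total_cargo``, so the noise-free asymmetry score
    is ``2 f - 1``. A reference channel is brighter in daughter 1 so that
    reference-based orientation is well defined.

    ``total_cargo == 0`` is allowed and flagged degenerate in the truth.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"partition fraction must be in [0, 1], got {f}")
    if total_cargo < 0:
        raise ValueError("total_cargo must be nonnegative")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing_um)
    R = daughter_radius_um
    margin = R + 4 * max(psf_sigma_um)
    # daughters along x: centres at -(R + bridge/2) and +(R + bridge/2)
    half_x = 2 * R + bridge_um / 2.0 + margin - R  # centre-to-edge along x
    extent = np.array([2 * margin, 2 * margin, 2 * half_x])
    shape = tuple(int(np.ceil(extent[i] / spacing[i])) for i in range(3))
    offset = extent / 2.0
    centers = [
        np.array([0.0, 0.0, -(R + bridge_um / 2.0)]),
        np.array([0.0, 0.0, +(R + bridge_um / 2.0)]),
    ]

    coords = np.meshgrid(
        *[(np.arange(shape[i]) + 0.5) * spacing[i] - offset[i] for i in range(3)],
        indexing="ij",
    )
    pts = np.stack(coords, axis=-1)
    masks = tuple(np.linalg.norm(pts - c, axis=-1) <= R for c in centers)

    cargo = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    records = []
    shares = [f, 1.0 - f]
    punctum_r = 0.22
    # organelles partition by number, not by brightness: every punctum
    # carries the same emitted mass, and each daughter's fractional
    # remainder becomes one proportionally dimmer punctum, so the expected
    # integrated density in daughter 1 is exactly f * total_cargo
    unit_mass = total_cargo / n_puncta if n_puncta else 0.0
    oid = 0
    for d, (center, share) in enumerate(zip(centers, shares)):
        units = share * n_puncta
        n_full = int(np.floor(units + 1e-9))
        frac = units - n_full
        masses = [unit_mass] * n_full
        if frac > 1e-9:
            masses.append(frac * unit_mass)
        placed: list[np.ndarray] = []
        for emitted in masses:
            oid += 1
            # puncta kept well inside the daughter so PSF leakage out of the
            # mask stays below voxelization tolerance; non-overlapping so the
            # truth label map stays consistent
            for _ in range(1000):
                w = rng.normal(size=3)
                w /= np.linalg.norm(w)
                rad = rng.uniform() ** (1.0 / 3.0) * (
                    R - punctum_r - 3 * max(psf_sigma_um)
                )
                c = center + w * rad
                if all(np.linalg.norm(c - o) > 2 * punctum_r + 0.1 for o in placed):
                    break
            else:
                raise CapacityError("could not place non-overlapping cargo puncta")
            placed.append(c)
            mask, slc = _capsule_mask(shape, spacing, c + offset, c + offset, punctum_r)
            nvox = int(mask.sum())
            if nvox > 0:
                cargo[slc][mask] += emitted / nvox
                labels[slc][mask] = oid
            records.append(
                {
                    "organelle_id": oid,
                    "kind": "sphere",
                    "age_class": "old",
                    "stratum": None,
                    "daughter": d + 1,
                    "true_volume_um3": _capsule_volume(punctum_r, 0.0),
                    "voxel_count": nvox,
                    "emitted_cargo": emitted,
                }
            )

    sigma_vox = tuple(psf_sigma_um[i] / spacing[i] for i in range(3))
    cargo_img = noise.apply(gaussian_filter(cargo, sigma=sigma_vox), rng)
    reference = np.zeros(shape, dtype=np.float64)
    reference[masks[0]] = 100.0  # daughter 1 is the reference-high daughter
    reference[masks[1]] = 40.0
    reference = noise.apply(gaussian_filter(reference, sigma=sigma_vox), rng)

    grid = VoxelGrid(
        np.stack([cargo_img, reference]),
        spacing_um=tuple(spacing),
        channel_names=(CARGO_CHANNEL, REFERENCE_CHANNEL),
    )
    label_map = LabelMap(
        labels, spacing_um=tuple(spacing), connectivity=26,
        provenance=[{"stage": "synthetic_pair_truth", "seed": seed, "f": f}],
    )
    records_df = pd.DataFrame(records)
    truth = GroundTruth(
        label_map=label_map,
        records=records_df,
        partition_fraction=f,
        degenerate=(total_cargo == 0),
    )
    return DaughterPair(grid=grid, daughter_masks=masks, truth=truth)


# ---------------------------------------------------------------------------
# two-class populations for stratification


@dataclass
class IntensityModel:
    """Planted age-label intensity components for population scenes.

    Means are photon rates of the lo / mid / hi components; draws are
    normal with coefficient of variation ``cv``. ``hi_weights`` are the
    per-cell organelle counts drawn from each component in hi-class cells;
    the hi share is kept near one quarter so the planted components line up
    with the 75th-percentile stratification rule.
    """

    lo_mean: float = 60.0
    mid_mean: float = 400.0
    hi_mean: float = 1600.0
    cv: float = 0.12
    hi_counts: tuple[int, int, int] = (5, 4, 3)  # lo/mid/hi organelles per hi cell

    def draw(self, stratum: str, rng: np.random.Generator) -> float:
        mean = {"lo": self.lo_mean, "mid": self.mid_mean, "hi": self.hi_mean}[stratum]
        return float(max(rng.normal(mean, self.cv * mean), 0.0))


def make_population(
    n_lo_cells: int,
    n_hi_cells: int,
    intensity_model: IntensityModel | None = None,
    seed: int = 0,
    scene_params: SceneParams | None = None,
) -> PopulationScenes:
    """Generate a two-class cell population with planted age-label strata.

    lo-class cells contain only dim-component organelles; hi-class cells mix
    the three components per ``IntensityModel.hi_counts``. The planted
    stratum of every organelle is recorded in the truth so stratification
    recovery can be scored.
    """
    if n_lo_cells < 1 or n_hi_cells < 0:
        raise ValueError("need n_lo_cells >= 1 and n_hi_cells >= 0")
    model = intensity_model if intensity_model is not None else IntensityModel()
    base = scene_params if scene_params is not None else SceneParams()
    rng = np.random.default_rng(seed)
    cells: list[CellScene] = []

    def build(cell_id: str, cell_class: str, strata: list[str]) -> CellScene:
        params = dataclasses.replace(
            base,
            n_organelles=len(strata),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cell_rng = np.random.default_rng(params.seed)
        placements = _place_organelles(params, cell_rng, strata=strata)
        rates = [model.draw(s, cell_rng) for s in strata]
        grid, label_map, records = _render_scene(params, placements, rates, cell_rng)
        return CellScene(
            cell_id=cell_id,
            cell_class=cell_class,
            grid=grid,
            truth=GroundTruth(label_map=label_map, records=records),
        )

    n_per_lo_cell = sum(model.hi_counts)
    for i in range(n_lo_cells):
        cells.append(build(f"lo{i:02d}", "lo-cell", ["lo"] * n_per_lo_cell))
    hi_strata = ["lo"] * model.hi_counts[0] + ["mid"] * model.hi_counts[1] \
        + ["hi"] * model.hi_counts[2]
    for i in range(n_hi_cells):
        cells.append(build(f"hi{i:02d}", "hi-cell", hi_strata))
    return PopulationScenes(cells=cells)
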