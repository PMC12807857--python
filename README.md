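# mitoquant

Quantitative analysis of mitochondrial inheritance and architecture in
dividing CD8+ T cells.

When an activated T cell divides, its two daughters can inherit unequal
shares of cellular cargo — in particular old (pre-mitotic) mitochondria —
and that asymmetry correlates with diverging effector/memory fates.
`mitoquant` implements the computational side of that analysis for
researchers working with multi-channel confocal z-stacks and label-free
proteomics of small lymphocytes:

* **3D per-organelle segmentation** of anisotropic two-channel stacks
  (a structural pan-mitochondrial marker such as Tom20 plus an organelle-age
  label): isotropic upscaling, channel fusion, outline boosting, multi-Otsu
  thresholding, morphological cleanup, connected-component labelling and a
  500-voxel noise filter.
* **Morphometry** per mitochondrion: volume `V`, marching-cubes surface area
  `SA`, sphericity `ψ = π^{1/3}(6V)^{2/3}/SA`, complexity index
  `MCI = SA³/(36πV²) = ψ⁻³` (1 for a sphere, larger for tubular or branched
  organelles), roundness, solidity, per-channel mean and integrated
  intensity, plus standardized feature matrices, UMAP embeddings and
  Gaussian-KDE density maps.
* **Age-label stratification** of organelles into lo / mid / hi strata from
  two reference thresholds: the maximum organelle intensity of label-low
  cells and the 75th percentile (linear interpolation) of label-high cells.
* **Asymmetric-inheritance scoring** of mitotic daughter pairs: the score
  `s = (P1 − P2)/(P1 + P2)` on daughter integrated densities, oriented by a
  reference channel or larger-first; `|s| > 0.2` (equivalently a >1.5×
  inheritance ratio) is classified asymmetric.
* **Proteomic-ruler copy numbers** (histone-calibrated: summed histone mass
  per cell equals the DNA mass) and the differential-inheritance filter
  (`p < 0.05` from a Welch t-test on log2 intensities, fold change > 1.5 or
  < 1/1.5).
* **Group statistics**: Welch t-test and the Kruskal–Wallis/Dunn pairwise
  post hoc test with Bonferroni correction.

Because real imaging and MS data are large and slow to obtain, the package
ships a first-class **synthetic-imaging module** that generates
ground-truthed confocal scenes (capsule/sphere organelles, two-component
age-label mixture, Gaussian PSF, Poisson + read noise, 0.13 µm z-steps with
3× finer xy sampling), mitotic daughter pairs with a controllable cargo
partition fraction `f` (truth score `2f − 1`), and MS intensity tables with
planted effects. Every pipeline stage is validated against this ground
truth.

## Worked example

```python
from mitoquant import SceneParams, make_cell_volume, segment_stack, compute_features
from mitoquant.synthetic import make_daughter_pair, CARGO_CHANNEL, REFERENCE_CHANNEL
from mitoquant.asymmetry import measure_pair

# a synthetic T cell with 12 mitochondria, segmented end to end
grid, truth = make_cell_volume(SceneParams(seed=7))
labelmap, iso = segment_stack(grid)
features = compute_features(labelmap, iso)
print(features[["organelle_id", "volume_um3", "sphericity", "complexity",
                "mean_snaptag"]].head(4).round(3))

# a mitotic daughter pair planted with 75% of the cargo in daughter 1
pair = make_daughter_pair(0.75, seed=1)
rec = measure_pair(pair.grid, pair.daughter_masks, CARGO_CHANNEL,
                   REFERENCE_CHANNEL, cargo_intensity_threshold="otsu")
print(f"P1={rec.P1:.0f} P2={rec.P2:.0f} score={rec.score:.3f} "
      f"-> {rec.classification}")
```

prints

```
 organelle_id  volume_um3  sphericity  complexity  mean_snaptag
            1       0.522       0.762       2.264       358.402
            2       0.486       0.783       2.087       359.526
            3       0.723       0.709       2.812       356.956
            4       0.086       0.948       1.175        46.453
P1=110929 P2=37399 score=0.496 -> asymmetric
```

All 12 planted organelles are recovered; tubules carry complexity well
above 1 while the small spheroid (organelle 4) sits near the spherical
limit, and the bright age label (~360 photon counts vs ~46) separates old
from young organelles. The measured pair score 0.496 recovers the planted
`2f − 1 = 0.5` and exceeds the 0.2 threshold, so the pair is called
asymmetric.

## Command line

```sh
mitoquant simulate --out scene/ --seed 7
mitoquant segment scene/stack.ome.tif --out seg/
mitoquant features scene/stack.ome.tif seg/labels.tif --out feats/
mitoquant stratify feats/features.csv --out strata/
mitoquant asymmetry pairs_manifest.csv --out asym/
mitoquant diffprot proteins.csv --group-a a1,a2 --group-b b1,b2 --out dp/
mitoquant run-all --out run/ --seed 7        # full synthetic-population run
```

Every run writes its fully resolved configuration and provenance sidecars
next to its outputs, and re-running with the same seeds reproduces all
numeric outputs bit for bit.

## Layout

| module | contents |
| --- | --- |
| `mitoquant.synthetic` | ground-truthed scene / pair / population generators |
| `mitoquant.segmentation` | isotropic resampling → fusion → outline boost → multi-Otsu → cleanup → label → size filter |
| `mitoquant.morphometry` | per-organelle features, standardization, UMAP, KDE |
| `mitoquant.stratification` | lo/mid/hi age-label strata |
| `mitoquant.asymmetry` | integrated densities, pair orientation, score, report |
| `mitoquant.stats` | Welch t, Dunn/Bonferroni, percentile |
| `mitoquant.proteomics` | histone ruler copy numbers, differential filter |
| `mitoquant.io`, `.config`, `.pipeline`, `.cli` | formats, run configuration, orchestration |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
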