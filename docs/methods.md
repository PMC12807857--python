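# Methods

This note records the models, conventions and numerical choices behind
`mitoquant`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not establish.

## Synthetic imaging model

The generator (`mitoquant.synthetic`) emulates confocal z-stacks of small
just-divided lymphocytes (ellipsoidal cell, default semi-axes
1.7 × 2.4 × 2.4 µm). Mitochondria are capsules (cylinders with
hemispherical caps) for tubular organelles and spheres for puncta, placed
by rejection sampling with a minimum surface-to-surface clearance
(0.25 µm) inside the cell; an explicit capacity error is raised when a
requested scene cannot be placed. Two channels are rendered: a structural
channel in which every organelle emits (a Tom20-like pan-mitochondrial
marker) and an age channel with a two-component intensity mixture — bright
"old" (pre-mitotic) organelles, default 500 photons/voxel, versus dim
"young" ones, default 60, an ~8× labelling contrast typical of sequential
covalent labelling.

The imaging forward model is deliberately minimal: per-channel separable
Gaussian PSF (default σ = 0.15 µm axially, 0.06 µm laterally,
near-diffraction-limited), then Poisson shot noise plus additive Gaussian
read noise (sd 2) on a uniform background (5 photons). Voxel spacing
defaults to 0.13 µm z-steps with 3× finer xy sampling (0.0433 µm);
the z spacing is the acquisition convention the pipeline is designed for,
while the xy spacing is a configurable instrument property. All randomness
flows from one `numpy` Generator seeded per scene, so identical parameters
give bit-identical stacks.

What the generator does **not** model: spatially varying or non-Gaussian
PSFs, depth-dependent aberration, photobleaching, stage drift, organelle
motion, autofluorescence structure, or fused networks whose branches
touch. Passing the synthetic validation therefore demonstrates that the
pipeline's logic and numerics are correct under a fair forward model — not
that it will reach the same IoU on any particular microscope's data.

### Daughter pairs

Mitotic pairs are two spherical daughters (radius 2.2 µm) separated by a
cytokinetic bridge (0.8 µm, excluded from both masks). Cargo partitions by
organelle **number** at constant per-organelle brightness: each of 16
puncta carries the same emitted mass, the planted fraction `f` of units
goes to daughter 1, and each daughter's fractional remainder becomes one
proportionally dimmer punctum. This matches how organelles actually
partition (as discrete units) and keeps any intensity threshold acting
identically on both daughters; partitioning by scaling brightness instead
would interact nonlinearly with thresholding. The expected integrated
density of daughter 1 is exactly `f × total_cargo`, so the truth score is
`2f − 1`. A reference channel is brighter in daughter 1, making
reference-based orientation (and hence signed scores) well defined.

### Populations for stratification

Two-class populations plant a three-component age-label mixture: lo-class
cells carry only the dim component, hi-class cells mix lo/mid/hi
components with per-cell counts 5/4/3 (hi share 3/12 = 25%, aligned with
the 75th-percentile stratification rule so the planted components are
recoverable rather than split mid-cluster). Component means 60/400/1600
photons with 12% CV give clearly separated but noisy clusters.

## Segmentation stack

Order and defaults (`SegmentationConfig`): isotropic upscaling to the
finest input spacing (trilinear, clamped at 0; `grid_mode` cell convention
so physical extent and smooth-signal integrals are preserved — order
configurable for fidelity to spline-based upscaling); fusion of the
structural and age channels as the voxelwise maximum of min–max-normalized
channels (an organelle bright in either channel enters the segmentation);
outline boosting `v + α·g` where `g` is the unit-normalized Gaussian
gradient magnitude (α = 0.5, σ = 0.1 µm) — the published pipelines this
emulates describe outline "feathering" without an algorithm, so this
explicit, provenance-recorded form is our stand-in; multi-Otsu
thresholding (k = 3: background / halo / organelle, foreground = top
class); morphological cleanup closing(r=1) → 3D hole fill → erosion(r=1)
with ball elements (clean first, split touching organelles last; order
configurable); 26-connectivity labelling; and removal of components
**strictly smaller than** 500 voxels, applied on the isotropic grid
(a 500-voxel component survives).

Multi-Otsu is implemented as an exhaustive search over histogram cut
positions maximizing between-class variance (ties broken toward the lowest
threshold set; returned thresholds are the histogram bin edges at the
cuts). Exhaustive search is exact and cheap at k ≤ 3 on ≤ 256-bin
histograms; the scikit-image implementation serves as an independent
cross-check in the tests.

Every `LabelMap` carries the ordered list of stages and parameters that
produced it; organelles are assigned to cells by majority vote over
supplied cell masks.

## Morphometry

With isotropic spacing `s` and per-label voxel count `n`:
`V = n·s³`; `SA` is the area of a marching-cubes mesh of the label mask.
The binary mask is Gaussian-smoothed (σ = 0.5 voxel) before meshing at the
0.5 level: meshing raw binary voxels overestimates areas by ~9% through
staircase artifacts, σ = 1 erodes curved surfaces by ~2%, and σ = 0.5
leaves a small (+2–4%), slightly positive residual, so digitized spheres
land just below ψ = 1 and just above MCI = 1 as they should.

* sphericity `ψ = π^{1/3}(6V)^{2/3}/SA` (isoperimetric; 1 for a sphere);
* complexity `MCI = SA³/(36πV²)`, the sphere-normalized complexity index —
  algebraically `ψ⁻³`, so `MCI·ψ³ = 1` holds identically on every record
  and both quantities are invariant under voxel-spacing rescaling. (The
  frequently quoted denominator `16π²` is not sphere-normalized — it gives
  9/4π ≈ 0.72 for a sphere — so the normalized form is used here.)
* roundness = equivalent-sphere diameter over the major principal-axis
  length `2√(5λ_max)` of the voxel-cloud covariance (the solid-ellipsoid
  convention; 1 for a sphere). There is no universal 3D roundness; this
  choice is documented rather than canonical.
* compactness = solidity, `V` over convex-hull volume — high for tight,
  unbranched architectures.
* intensity features (per-channel mean and integrated density) are always
  measured on the resampled **raw** channels over the label support, never
  on the fused/enhanced working volume; mean = integrated / voxel count by
  construction, with no background subtraction by default.

Standardization z-scores the geometric columns only (intensity columns are
excluded so embeddings are not biased by labelling brightness);
zero-variance columns are dropped with a log note and the scaling record
can be re-applied to held-out data. UMAP embeddings are pinned to a seed
and used for visualization only — no quantitative claim rests on them.
KDE density maps use Scott's-rule bandwidth by default and pad the grid by
five kernel widths so the density integrates to 1 over the grid within 1%.

## Age-label stratification

`t_lo` = maximum mean age-label intensity among organelles of lo-class
cells; `t_hi` = 75th percentile (linear interpolation between order
statistics — the convention is recorded in the output metadata) over **all**
hi-class organelles. Assignment: lo-cell organelles are "lo"
unconditionally; hi-cell organelles are "lo" when ≤ `t_lo`, "mid" when in
(`t_lo`, `t_hi`], "hi" when strictly above `t_hi` ("below the maximum" /
"above the percentile" read strictly). `t_hi < t_lo` is legal and leaves
the mid stratum empty, with a log note. The reference population is the
current dataset; a saved `IntensityStrata` JSON can be re-applied to new
data for cross-experiment comparability.

## Inheritance asymmetry

`s = (P1 − P2)/(P1 + P2)` on oriented daughter integrated densities.
With a reference channel, P1 is the cargo density of the reference-high
daughter and the score is signed; without one, P1 = max(Pa, Pb), the score
is nonnegative, and the `s < −0.2` branch of the classification rule is
unreachable by construction — the signed mode exists precisely so that
branch is meaningful. Classification is strict: `|s| > 0.2` is asymmetric,
`s = ±0.2` (exactly a 1.5× ratio) is symmetric. `P1 + P2 = 0` is a
degenerate pair: no score, reported separately.

`measure_pair` optionally applies a per-fluorophore intensity threshold to
the cargo channel before integration (a fixed value, or the top k = 3
multi-Otsu threshold), mirroring how confocal quantifications threshold
each channel: without it, the uniform background integrated over the large
daughter masks dilutes every score toward 0. `integrated_density` itself
remains the plain sum over a mask.

## Statistics

Welch's t-test: `t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ)` with
Welch–Satterthwaite degrees of freedom; both-constant samples degenerate
to p = 1 (equal means) or a flagged p = 0 (unequal). The Dunn post hoc
test ranks all observations jointly with midranks,
`z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − T/(12(N−1)))(1/nᵢ + 1/nⱼ))` with tie term
`T = Σ(t³ − t)`, two-sided normal p, Bonferroni-multiplied by the number
of comparisons actually performed. All-tied data degenerate to p = 1.
ANOVA-family tests used alongside these in practice are deliberately left
to standard libraries.

## Proteomic ruler

Per sample, the DNA mass per cell is
`m_DNA = genome_size × ploidy × mean bp molar mass / N_A` (defaults:
2.7 Gbp haploid mouse genome, diploid, 615.8771 g/mol/bp — declared
defaults, configurable); protein copies are
`(Iᵢ/ΣI_histone)·m_DNA·N_A/Mᵢ`. Summed histone mass per cell then equals
`m_DNA` identically, and copy numbers are invariant to global per-sample
intensity scaling and linear in ploidy. Histones are identified by a
caller-supplied flag, not by sequence analysis. The differential filter
works on log2 intensities (base is immaterial to the t-test), excludes
zeros as missing (never imputes), requires ≥ 2 quantified samples per
group (otherwise the protein is reported categorically as not testable),
and calls significance as `p < 0.05` AND fold change `> 1.5` or
`< 1/1.5` — the lower gate is implemented as exactly 1/1.5 so the filter
is symmetric under group swap (0.67 is that value rounded).

## Reproducibility and problem sizes

Every generator and the end-to-end pipeline are deterministic under a
fixed seed; each run writes its fully resolved configuration, a structured
log, and provenance sidecars next to its outputs. The validation suite
runs at deliberately modest problem sizes — one ~150³-voxel default scene
for segmentation scoring, a 4 + 4-cell population (96 organelles) for
stratification recovery, 10,000 simulated sample pairs for test
calibration — chosen as the smallest sizes at which the tested statistics
are stable.

## Known limitations

* The outline-boost ("feathering") stage is an explicit stand-in for an
  undocumented published step; its α/σ defaults are design choices.
* Whether the 500-voxel noise filter should count voxels before or after
  isotropization is ambiguous in the pipelines this follows; it is applied
  after (on the isotropic grid), where the threshold has a fixed physical
  meaning.
* Roundness and compactness have no universal 3D definitions; the chosen
  forms are documented above.
* The 75th-percentile stratification threshold is computed over all
  hi-class organelles (not only those above `t_lo`); both conventions are
  defensible and the choice is recorded.
* No network/graph topology, tracking, or fission–fusion event detection;
  no deconvolution; no 2D mode; pair daughter masks are supplied (from
  synthetic truth or manual annotation), not detected.
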