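# Methods

`somapeaks` locates and segments neuronal somas — in particular *touching*
somas — in 3D grayscale stacks from optical microscopy, and ships the
synthetic benchmark used to characterise that capability. This note records
the model, the parameters that matter, the numerical choices, and the known
limits.

## Problem and model

A soma appears as a roughly spherical, locally bright blob (radius ~3–10 µm)
on a background whose noise is Poisson counting noise, the norm for
photon-limited optical microscopy. Somas frequently touch, so per-blob
detectors (thresholding + connected components) under-segment, and seeded
methods (watershed, sphere fitting) depend on fragile initialisation. The
approach here is density-peak clustering over foreground voxels:

* **Local density ρ.** For a foreground voxel `p_i`,
  `ρ_i = (1/Z) Σ_j I(p_j) · K(p_i, p_j)` with a Gaussian kernel
  `K = exp(−‖p_i−p_j‖² / 2σ²) / (√(2π) σ)` restricted to the window
  `‖p_i−p_j‖ ≤ R = 2σ`. The sum runs over **all image voxels** inside the
  window (see "Design choices"); `Z` normalises the region maximum to 1.
* **Minimum distance δ.** The distance from `p_i` to the nearest voxel of
  strictly higher density within its connected region, divided by the region
  diameter; the region's density maximum gets δ = 1. Density ties are broken
  by voxel order, so the maximum is unique and the whole pipeline is
  deterministic.
* **Centre selection.** Soma centres combine high ρ and large δ, so they are
  isolated points in the (ρ, δ) plane. The plane is discretised into
  0.001-wide bins, the point histogram smoothed with an 11×11 Gaussian window
  (width 3 bins), and each point's *feature density* Λ read off at its bin,
  expressed as a fraction of the region's points. Candidates must satisfy
  `Λ ≤ thre_selective` **and** `δ · diameter ≥ R_min` (the minimum soma
  radius). Candidates closer than `R_min` to a stronger candidate are pruned
  by a descending-density traversal.
* **Segmentation.** Every remaining voxel joins the cluster of its nearest
  higher-density voxel, in descending-density passes; each cluster is one
  soma.

Foreground extraction precedes clustering. Each (sub-block of the) stack is
binarized against a smooth background image `C` (the intensity image clipped
at its Otsu threshold and averaged 10× with a 3×3 in-plane template):

```
foreground  ⇔  I > C + thre_binarization · √C
```

`√C` is the Poisson noise scale, so `thre_binarization` counts noise standard
deviations. Clean-up then depends on the data regime (below), and the
foreground is partitioned into 26-connected regions (neighbourhood = the
√3-radius sphere in index space), each processed independently — which also
keeps the δ search local and the runtime close to linear in stack volume.

## Synthetic phantoms

The generator reproduces the standard touching-pair benchmark: spherical
somas of radius 10 µm, background mean `I_b = 100` counts, every voxel an
independent Poisson draw with mean `I_o + I_b` inside the (union of the)
spheres and `I_b` outside. Contrast is set by `SNR = I_o/√(I_o + I_b)`;
`snr_to_intensity` inverts this (`I_o ≈ 10.5` at SNR 1, `80.6` at SNR 6).
The canonical series is 28 stacks: SNR ∈ {1, 2, 4, 6} × centre distance
d ∈ {2, 6, …, 26} µm, one centred pair per stack, displaced along x.

Choices the benchmark literature leaves open, fixed here once:

* stack 100³ voxels of 2×2×2 µm³ (the merged working resolution of
  whole-brain two-photon data);
* hard-sphere membership (voxel centre within the radius), no partial-volume
  blending, no PSF, no neurites or vessels;
* 16-bit integer counts; one RNG stream per stack derived from
  (seed, stack index), so any series element is reproducible in isolation.

What passing on these phantoms does **not** show: robustness to anisotropic
PSF blur, neurite clutter, or contrast inhomogeneity — real stacks have all
three. The block split/merge machinery and the erosion path address the
latter two but are only exercised on synthetic solids here.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `thre_binarization` | 2 (low contrast) / 6 (bright) | noise σ | foreground threshold above background |
| `T_start, T_step, T_max` | 9, 0.027, 11 | voxels | erosion neighbourhood-count schedule |
| `thre_erosion` | 0.1 % | — | erosion steady-state stopping rule |
| `despeckle_T`, passes | 4, 2 | voxels | light noise removal for porous masks |
| `min_region_voxels` | 52 | voxels | region floor ≈ 10 % of a 10-µm soma's volume |
| `sigma_um` (σ) | 4 | µm | density kernel width (≈ half a soma radius, window R = 2σ) |
| `R_min_um` | 8 (phantom preset) / 3 (experimental) | µm | minimum *estimated* soma radius |
| `thre_selective` | 10⁻² | — | feature-density ceiling for candidates |
| block / overlap | 200³ / 12 | voxels | sub-block layout for large stacks |
| match threshold | 8 | µm | detection-evaluation pairing radius |

`R_min` deserves a word: it is the minimum radius the segmentation itself
estimates for the data at hand. For the experimental regime (somas of 3–10 µm)
that is ≈3 µm. For the phantom study the somas are nominally 10 µm, but the
voxelized, binarization-limited clusters measure ≈7.5–8.5 µm by the
perimeter-distance estimator, so the phantom preset uses 8 µm. The value also
controls how close two reported centres may be; at 2-µm voxels it must exceed
the corner-diagonal lattice spacing (3.46 µm) by a healthy margin or the δ
condition stops discriminating.

## Two clean-up regimes

The binarized mask needs different repair depending on contrast:

* **Bright, solid foreground with thin clutter** (neurites, artifacts;
  `thre_binarization = 6`): the iterated erosion removes every foreground
  voxel whose 3×3×3 neighbourhood holds fewer than `T` foreground voxels,
  with `T` rising 9 → <11 in steps of 0.027, until both the voxel count and
  the 26-component count change by less than 0.1 % per pass. On solid bodies
  this shaves corners and dissolves tube-like structures while the bulk is
  stable.
* **Low contrast without clutter** (`thre_binarization = 2`, the phantom
  regime): the foreground inside a soma is *porous* — at SNR 1 only ~25 % of
  interior voxels exceed the threshold — and iterating the 9-of-27 erosion to
  its steady state provably empties such regions (the local fill is below the
  rule's stability point). Erosion is therefore off in this preset; instead a
  light despeckle (≥4 foreground in the 3×3×3 neighbourhood, two synchronous
  passes) removes the ~2–6 % background speckle, whose local fill is far
  below 4/27, while porous somas pass almost untouched. A region-size floor
  (~10 % of the smallest soma's volume) guards against rare large speckle
  clusters, which matter because the background fill sits near the
  26-connectivity percolation threshold.

## Design choices (where the design was genuinely open)

* **Density support.** The kernel sum for ρ is restricted only by distance,
  so the pipeline evaluates it over *all* voxels in the window (a truncated
  Gaussian convolution of the image, sampled at region voxels). The
  alternative — summing only the region's own points — makes ρ a statistic of
  a sparse, biased sample on porous masks and destroys low-SNR localization;
  both variants are implemented (`DensityConfig.support`), and the
  region-support variant is what the brute-force oracles test.
* **Normalisation of ρ (Z).** Set per region so max ρ = 1. This bounds the
  feature grid at 1001×1001 bins and makes `thre_selective` transferable
  across regions.
* **Λ as a fraction.** The smoothed feature histogram is divided by the
  number of region points. With raw counts every point's own bin already
  carries the kernel's central weight (≈0.02), which would exceed
  `thre_selective = 10⁻²` for every point and make the selection empty; as a
  fraction, an isolated point's Λ vanishes as 1/m while crowd bins stay
  large.
* **Ties and determinism.** All density ties (sorting, "strictly higher",
  the unique δ = 1 point) resolve by ascending voxel order. Erosion and
  despeckle passes are synchronous (decisions taken on the previous pass's
  mask), so results are traversal-order independent.
* **Background estimate.** Clipping at the Otsu threshold *flattens*
  everything above the background bulk, which keeps `C` background-like even
  inside low-contrast somas. On near-unimodal images the clip lands inside
  the background distribution and biases `C` low by a few counts (measured
  ≈95.5 for a Poisson-100 field), raising the background false-positive rate
  from the nominal ~2.3 % to ~6 %; the despeckle/size-floor stage absorbs
  this. Replicate-edge padding keeps `C` unbiased at block borders.
* **Block merging.** Each overlap is split in half, each half owned by the
  adjacent block (odd voxel to the earlier block); merging runs axis by axis
  and is exact when both blocks agree.
* **Pruning traversal.** "Not traversed" means not yet visited as the current
  point; already-deleted candidates are skipped as current but remain
  eligible as nearest neighbours. The alternative reading (exclude deleted
  points from the search) differs only in rare chains; the choice is frozen
  and tested.
* **Assignment fallback.** If a region's density maximum is not a centre, its
  chain can never inherit a label; such points (they occur only in degenerate
  configurations) take the label of the nearest labelled point rather than
  looping forever.
* **Centres at voxel positions.** Reported positions are voxel centres in µm;
  no sub-voxel refinement.
* **Evaluation matching.** One-to-one greedy pairing in ascending distance
  order with a *strict* 8-µm threshold; equivalent to optimal assignment on
  all but adversarial geometries (property-tested against brute force).

## Numerical notes

* Degenerate inputs: constant blocks are their own background (Otsu is
  skipped); empty masks yield empty region lists; a single-point region has
  ρ = δ = 1 and yields no candidate (its diameter is 0, and any region
  narrower than `R_min` is skipped outright — the δ condition cannot hold).
* The region diameter uses convex-hull vertices for >500 points with a
  brute-force fallback for degenerate (coplanar) sets.
* The erosion threshold schedule is capped at the largest scheduled value
  below `T_max`; fractional thresholds compare directly against integer
  neighbourhood counts.
* The stack-wide density field uses an FFT convolution with the truncated
  spherical kernel; values are clipped at 0 to remove FFT ringing.
* Problem sizes in the test-suite and acceptance experiments: 100³-voxel
  stacks, 10-seed panels per (SNR, d) condition (20 at the marginal
  d = 14 µm cells), and a 0.5–15 µm σ sweep on one fixed phantom. These
  match the benchmark's own design.

## Known limitations

* **d = 14 µm is the physical margin.** For overlapping uniform spheres at
  centre distance 14 µm the smoothed-density valley between the two lobes is
  at most ~1.5 % of the signal amplitude (and exactly zero for σ ≤ 2 µm,
  where the kernel fits inside the union and the field saturates flat).
  Splitting there relies on the valley biasing each lobe's sampled maximum;
  the per-realisation success rate is ~0.55 at SNR 1 and ~0.6–0.8 at
  SNR 2–6, so majority votes at d = 14 sit near their decision boundary,
  while d ≥ 18 splits in ≥90 % of realisations. Pairs at d ≤ 10 µm usually
  merge: the union is nearly concentric and its density has a single peak.
* **Effective σ range.** On the SNR 3, d = 14 phantom the sweep finds correct
  2-soma localization for σ ≈ 2.5–5.5 µm. Below that the field has no valley
  at all (saturation); above, the two lobes merge into one peak. Claims of a
  wider working range for this geometry are not reproducible under this
  phantom model.
* Morphometric radius is biased low on porous segmentations (perimeter
  voxels sit inside the true surface); overlap-measure inherits that bias.
* The experimental-regime path (blocks, erosion, `thre_binarization = 6`) is
  exercised on synthetic solids only; no real 2p-fMOST, Nissl or SIM volumes
  ship with the package.
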