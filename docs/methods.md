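# Methods

## Data model and conventions

A stack is a 3-D grid of non-negative intensities indexed `(z, y, x)`
with a physical voxel size per axis in µm; axis order is `(z, y, x)`
everywhere.  The default voxel size is `(1.0, 0.5, 0.5)` µm — a 1 µm
z-step over 0.5 µm in-plane pixels, the usual anisotropy of multiphoton
z-stacks of cleared tissue.  Coordinates are voxel-centre based and
0-based; all reported lengths, areas and volumes are physical (µm, µm²,
µm³).  Stacks are exchanged as multi-page TIFF with a JSON sidecar
carrying voxel size and sample metadata; the sidecar is authoritative
on re-read, with ImageJ-style TIFF tags as fallback.  Float stacks are
stored at float32.

## Synthetic scenes

The generator emulates the structures a segmentation pipeline must cope
with in cleared DRG/ScN tissue:

* **cells** — solid triaxial ellipsoids at uniform `cell_intensity`
  (default 150), semi-axes drawn per shape mode:
  `balanced` (3–5, 3.5–5.5, 4–6 µm, near-spherical resting
  morphology), `prolate` (2–3.5, 2–4, 8–14 µm, elongated M2-like) and
  `oblate` (2–3, 5–7, 6–9 µm, flattened M1-like), each uniformly
  distributed and sorted `a ≤ b ≤ c`;
* **neuron-scale blobs** — bright spheres of ≥ 7000 µm³ (soma-scale,
  far above any cell volume), removed downstream by the voxel-count
  ceiling;
* **speck artifacts** — spheres sized to render at or below
  `artifact_max_voxels` (default 10), removed by the voxel-count floor;
* **tissue envelope** — an ellipsoid at `background_intensity`
  (default 20) over a zero outside-tissue floor, default semi-axes 85%
  of the stack half-extent;
* **noise** — optional Poisson resampling of the clean image followed
  by Gaussian noise (default sd 4), clipped at zero.

None of these numbers come from a measured dataset (cell density,
macrophage volume and detector statistics are not published for this
preparation); they are plausible values at multiphoton resolution,
fixed once as the package's study conditions.  With cell intensity 150,
background 20 and noise sd 4, cells sit ~30 sd above the subtracted
background — clean by design, since the generator's purpose is
validating measurement code, not benchmarking detection limits.

Placement is rejection sampling: centroids uniform inside the tissue
envelope, the whole object required to fit inside the stack, and
overlap tested exactly at voxel level against an occupancy grid whose
stamped objects carry a 1-voxel dilation halo — accepted objects are
therefore never 26-adjacent and always label as distinct components.
Each object gets `max_place_attempts` (default 1000) tries before a
`PlacementError`.  Ground truth records each object's class, centroid,
semi-axes, orientation, analytic volume `(4/3)πabc` and rendered voxel
count; the scene seed fully determines both stack and truth.

Cohorts enumerate sex × condition × side × tissue with per-group
effects (a density multiplier applied to a Poisson-distributed expected
cell count, and a shape mode).  Per-sample seeds are spawned from the
base seed via `numpy.random.SeedSequence`, so cohorts are reproducible
and samples independent.  Ipsi- and contralateral samples of one animal
share an `animal_id`, which pairs them for ratio analysis.

What the generator does **not** emulate: irregular/ramified cell
shapes, intensity gradients with depth, optical PSF blur (a Gaussian
option exists but is off by default so volume/area oracles stay exact),
touching cells, motion or striping artifacts.  Passing tests therefore
demonstrate correctness of the measurement chain on compact cells with
known geometry, not detection performance on hard real data.

## Segmentation

Background subtraction is a large-scale Gaussian estimate (sigma in µm,
default 10, converted per-axis to voxels) subtracted and clipped at
zero; a flat field maps to exactly zero.  Foreground is
`intensity ≥ cell_threshold` (default 50) on the subtracted stack;
components are labeled with 26-connectivity by default and relabeled
contiguously.  The voxel-count filter (defaults 50–10 000 voxels, i.e.
12.5–2 500 µm³ at the default voxel volume of 0.25 µm³) removes specks
and neuron-scale bodies; survivors + removed_small + removed_large
always equals the input object count.  Tissue volume is the largest
connected component of `raw ≥ tissue_threshold` (default 10, between
the zero floor and the envelope's 20) times the voxel volume; using
only the largest component ignores lone noise voxels and debris.
Touching cells merge — no watershed splitting is attempted; at the cell
densities targeted here the generator guarantees separation, and on
real data merged pairs would surface as volume outliers.

## Morphometry

* **Volume**: voxel count × voxel volume.  Within 2% of the analytic
  ellipsoid volume for cell-sized objects at default resolution.
* **Surface area**: marching cubes at level 0.5 in physical
  coordinates.  Meshing the raw binary mask overestimates area ~9–13%
  (staircase artifact), which would push sphericity of a voxelized
  sphere to ~0.9; the mask is therefore smoothed with a 0.7-voxel
  Gaussian before meshing.  0.7 was chosen as the balance point between
  residual staircase error and erosion of thin features: sphere-area
  error then stays within ~1.5% for objects with smallest semi-axis
  ≥ 5 µm and within ~5% down to 2 µm.  Objects under 8 voxels cannot be
  meshed reliably and fall back to summed exposed voxel-face area,
  flagged `face_area_fallback`.
* **Sphericity**: `ψ = π^(1/3)(6V)^(2/3)/A`, the equal-volume sphere's
  area over the actual area; 1 for a sphere, < 1 otherwise.  Voxelized
  data may exceed 1 by discretization; values above 1.02 are flagged.
* **Ellipsoid fit**: second central moments of voxel centres in
  physical coordinates; for a uniform solid ellipsoid the principal
  second moment along axis *i* is `axis_i²/5`, so eigenvalues
  `λ₁ ≤ λ₂ ≤ λ₃` give `(a, b, c) = √(5λ)` and eigenvectors the
  orientation.  Moment-derived axes (rather than a bounding ellipsoid)
  are the standard choice and are rotation-invariant within ~5% on
  voxelized data.  Fits need ≥ 20 voxels (`too_few_voxels` flag
  otherwise); a degenerate smallest axis is floored at half the
  smallest voxel extent and flagged.
* **Ellipticities**: with sorted semi-axes `a ≤ b ≤ c`,
  `e_prolate = [2a²/(a²+b²)]·[1 − (a²+b²)/(2c²)]` and
  `e_oblate = [2b²/(b²+c²)]·[1 − 2a²/(b²+c²)]`.  The ordering
  convention is what makes both formulas 0 at the sphere and approach 1
  at their named extremes (one dominant long axis; one vanishing short
  axis); both lie in `[0, 1)` for all valid axes and vanish only at
  `a = b = c`.
* **Phenotype**: oblate-dominant (M1-like) if `e_oblate − e_prolate`
  exceeds the margin (default 0.05), prolate-dominant (M2-like) for the
  reverse, else indeterminate.  The margin is a tie band, not a
  biological threshold, and the label is strictly geometric.

## Quantification and statistics

Density is `n_cells / tissue_volume × 10⁶` (cells per 10⁶ µm³ — per
0.001 mm³), exact by construction.  Ipsi/contra count and mean-volume
ratios are computed per animal and tissue; a zero contralateral count
yields a flagged NaN, never infinity.  Volume histograms share fixed-
width bin edges across compared groups (default 20 bins over the pooled
range) and are normalized to relative frequencies.

Single comparisons use the two-sample t-test — Welch by default, since
equal variances cannot be assumed between e.g. injured and control
groups; the pooled-variance form is available.  Multi-group designs use
one-way or two-way (with interaction) ANOVA via OLS, followed by all
pairwise cell contrasts with Bonferroni adjustment; the family is
defined as all pairwise contrasts within one ANOVA.  Significance is
`adjusted p < α` (default 0.05).  A design cell with fewer than 2
observations raises an error naming the cell.  The degenerate case of
two zero-variance groups with equal means is reported as p = 1 rather
than NaN.

The pipeline's standard comparisons are: within the injured condition,
a two-way sex × side ANOVA on cell count per tissue (the recruitment
question), and across conditions a Welch t-test on per-sample mean
oblate ellipticity (the morphology-shift question).

## Validation problem sizes

The test suite validates at desk scale, chosen so the full suite runs
in a few minutes on one CPU: default scenes of 64×128×128 to 64×192×192
voxels (64×64–96×96 µm of tissue), parameter recovery on 50 voxelized
random ellipsoids (semi-axes 5–30 µm, random orientations, anisotropic
voxels), statistical calibration on 200 simulated replicates at
n = 6 per group, and an end-to-end cohort of 48 stacks (2×2×2 design ×
6 samples, DRG).  Full-scale 512×512×300+ stacks are supported by the
same code path.  The end-to-end cohort uses 6 samples per group — the
sample size at which the simulated statistics path has > 90% power for
a 3-SD shift — rather than the 3 typical of pilot imaging studies,
whose power depends on effect sizes that are not published.

## Known limitations

* Ellipsoid phantoms validate the measurement chain, not segmentation
  of irregular, ramified or touching cells.
* Surface area (hence sphericity) carries a resolution-dependent bias
  for objects only a few voxels thick; flags mark the fallback path.
* The M1/M2 phenotype label is geometric shorthand only.
* No reader for proprietary acquisition formats; convert to TIFF/OME
  first.
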