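# Methods

`pexsite` quantifies whether, and which, translation happens on the surface of
peroxisomes. It implements three independent measurements plus the synthetic
generators needed to validate each against known ground truth.

## 1. Ribosome exclusion-zone (REZ) profiling

### Model

A peroxisome is modeled as a sphere (center, radius, in pixels) with an
isotropic pixel calibration of 1.159 nm/px, the calibrated magnification of the
tomograms this scheme is designed for. Ribosomes are a list of 3D centroids,
one per particle; each is treated as a solid sphere of 9-px radius (~20 nm
diameter), the size at which ribosomes appear as uniform electron-dense bodies.

The density profile is computed on a voxel grid covering the analysis crop:

1. Each centroid is projected as a solid 9-px sphere (overlaps union; spheres
   are clipped to the membrane exterior).
2. The exterior of the sphere is partitioned into 20 concentric shells, 5 px
   thick. Shell *i* is the set of voxels whose distance to the membrane
   surface lies in ((i−1)·5, i·5] px. This is the band that repeated
   morphological dilation of the membrane mask with a 5-px spherical element
   traces out on the grid; we compute it from the analytic sphere distance
   (| |x−c| − R |) because for a spherical model that distance is exact,
   grid-free, and identical to the quantity used for the profile's x-axis.
3. Density in shell *i* is occupied voxels / shell voxels; the reported
   distance is the mean analytic surface distance over the shell's voxels
   (nm).

Per-organelle profiles are averaged arithmetically per shell (all profiles
must share the shell grid).

### REZ width estimator

The averaged profile shows depletion near the membrane rising to a cytosolic
plateau. The plateau is estimated as the mean density of the outermost 25% of
shells; the REZ width is the distance at which the linearly interpolated
profile first reaches 50% of the plateau (0 if the innermost shell already
exceeds it). For a step-like exclusion convolved with the symmetric
ribosome-projection kernel, the half-plateau crossing sits at the true
exclusion boundary; the estimator is therefore unbiased for hard exclusion
zones up to shell-discretization error (one shell, 5.795 nm). Because the
ramp of the convolved profile is slightly convex near its foot, the
interpolated crossing lands ~1–2 nm below the planted boundary in practice —
well inside the one-shell tolerance.

### Proximal ribosomes

A ribosome is proximal when its centroid-to-surface distance
(|x−c| − R) × 1.159 nm is strictly below 20 nm. Centroids falling inside
the sphere model (segmentation artifacts) are excluded from the count and
reported with a warning. Size association is summarized by the Pearson
correlation of proximal count vs radius (returned as 0 with a degenerate flag
when either variance is zero) and by group means for small (<100 nm diameter)
vs large organelles.

### Centroid segmentation

For volumes rather than point models: the ribosome probability map is
smoothed with a Gaussian (σ = 2 px — fixed so results are reproducible),
thresholded at 0.5, and touching blobs are split by a watershed on the
Euclidean distance transform, one marker per local maximum with minimum
separation of half the nominal blob diameter (9 px). Blobs below half the
nominal ribosome volume are discarded as debris.

## 2. Synthetic tomographic scenes

The generator emulates a cryo-section crop around one organelle:

- **Geometry.** Sphere at the origin; crop extends 100 px beyond the membrane
  surface in X/Y and spans a 172-px slab in Z (~200 nm nominal section
  thickness at 1.159 nm/px).
- **Cytosolic ribosomes.** Uniform in crop minus the exclusion ball
  (sphere radius + exclusion half-width), with a hard-core minimum
  inter-centroid spacing of one ribosome diameter (18 px) enforced by dart
  throwing with bounded retries. The number of points is Poisson with mean
  density × free volume (free volume computed analytically, including the
  slab truncation of the exclusion ball), so the mean count equals
  density × free volume exactly despite the hard core.
- **Exclusion zone.** Default half-width is one ribosome diameter,
  18 px × 1.159 = 20.86 nm: a solid 20-nm particle whose center cannot
  approach a hard wall closer than its own diameter produces exactly the
  observed ~20-nm depleted shell.
- **Planted proximal ribosomes.** Each scene receives a fixed number
  (default preset: 1–3 per organelle, drawn uniformly) of extra centroids at
  surface distance uniform in (0, 20 nm), isotropic direction, re-drawn until
  inside the crop; ground-truth labels accompany every scene.
- **Density calibration.** The cytosolic number density is a free parameter
  of the generator (it is not directly measurable from the source imagery);
  it was calibrated once to 2.0 × 10⁻⁵ px⁻³ so that default crops carry a
  few hundred ribosomes (the realistic 200–400 bracket for a 100-px crop),
  and frozen in the preset.
- **Ensemble preset.** 51 organelles per study, radii uniform in 25–100 nm
  (diameters ~50–200 nm, the observed peroxisome size range).

What the generator does **not** model: electron-optical image formation
(CTF, noise, missing wedge), non-spherical membranes, ribosome orientation,
and crowding agents other than the hard core. Passing tests therefore
demonstrate correctness of the measurement machinery on idealized point
clouds, not robustness to segmentation noise in real tomograms.

## 3. Proximity-specific ribosome-profiling enrichment

### Procedure

For each bait (membrane protein fused to the biotin ligase) there is a
matched pair of libraries: input (total footprints) and pulldown
(streptavidin-purified, organelle-proximal footprints). The pipeline:

1. **P-site assignment** — each footprint's P-site is 15 nt from its 3′ end
   toward the read 5′ direction: `psite = three_prime − 15` on the plus
   strand, `three_prime + 15` on the minus strand. Footprints whose P-site
   would be negative are dropped and counted. Footprint 3′ ends are 0-based
   internally (documented convention; GFF3 conversion happens at I/O).
2. **Countable CDS mask** — per gene, CDS positions minus any position
   covered by another same-strand CDS on the same chromosome
   (opposite-strand overlap does not exclude). Genes left with an empty mask
   are flagged.
3. **Counting and densities** — a P-site counts for a gene when it falls in
   the gene's countable mask on the gene's strand. Density is reads per
   million: `count × 10⁶ / library_size`, with library size = all retained
   mapped footprints in the sample. Because enrichment is a ratio of matched
   samples, any per-length factor cancels; a per-countable-position density
   is reported separately rather than baked into the ratio.
4. **Enrichment** — `log2(pulldown RPM / input RPM)` per gene. Filters
   (gene excluded from calling and normalization): fewer than 100 input
   CDS-mapping footprints, dubious annotation, mitochondrial gene, empty
   countable mask. Enrichments are additionally z-normalized (mean 0, SD 1
   over passing genes); genes are binned by decade of min(input, pulldown)
   counts for stratified QC only — bins play no role in calling. A passing
   gene with zero pulldown density carries a −∞ sentinel, excluded from
   normalization and reported.
5. **Calling** — a gene is called when its enrichment exceeds the cutoff
   (default raw log2 > 0.5). The default applies the cutoff to the *raw*
   log2 axis; `mode="normalized"` applies it to the z-scores instead. With
   multiple baits the final set is the intersection (dual-bait rule) or,
   optionally, the union. Two-organelle comparison classifies each shared
   gene as A-only / B-only / both / neither by per-side calling.

### Synthetic datasets

The generator lays out a toy genome (default 4,540 genes of 1,000-nt CDS —
about the size of a filtered yeast gene set — across 16 chromosomes plus a
mitochondrial one, 400-nt intergenic gaps, 5% of genes with a split CDS,
10% dubious, 1% mitochondrial). Per bait, input counts are
Poisson(1,000) per gene and pulldown counts Poisson(1,000 × 2^effect), with
40 planted genes at effect 2.0 and effect 0 elsewhere. Both samples are
padded with intergenic background footprints to one common library size
(1.3 × the larger expected total), so RPM normalization cancels exactly
between matched samples and the planted effect is identifiable; without a
fixed library size the ratio would absorb part of the effect (and would be
degenerate for a single gene). P-sites are drawn uniformly over the CDS and
3′ ends derived by inverting the assignment rule, so P-site assignment lands
inside the source CDS for 100% of gene footprints by construction.

## 4. Spot colocalization

Colocalization is organelle-centric: the percentage of peroxisome spots with
at least one mRNA spot within a distance threshold, per cell. The default
threshold is 300 nm — approximately the diffraction limit at which manual
counting of overlapping puncta operates — and is a parameter, not a measured
constant. Two baselines are supported: a control-transcript field analyzed
through the same estimator, and a within-field permutation baseline (mRNA
spots resampled uniformly in the cell mask; mean percent over permutations
with a 95% percentile interval and a one-sided permutation p-value).
Group comparisons use the unpaired two-sided t test or Mann–Whitney.

The generator draws, per cell (disk mask, radius 2.5 µm — a typical yeast
cell): 2 + Poisson(3) peroxisomes with 600-nm minimum separation placed
away from the cell edge, a Bernoulli(p) colocalized mRNA spot per peroxisome
at a Gaussian-jittered offset (σ = 50 nm), and Poisson(0.7) background mRNA
spots uniform in the cell. The PEX14 preset fixes p = 0.30. Background spots
make the estimator's expectation slightly exceed 100p (accidental capture,
~+1 percentage point at the defaults) — the same bias real FISH fields carry,
which is why the permutation baseline exists. A jitter large enough to throw
planted spots past the threshold triggers a warning (truth would be
unrecoverable by any distance criterion).

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is byte-deterministic given its seed, and stochastic CLI commands
  require an explicit `--seed`.
- Voxel grids anchor unit voxels at the crop's lower corner; lattice points,
  not voxel centers, are the sample points, and the test oracles enumerate
  the same lattice.
- Empty inputs are contracts, not crashes: empty footprint tables and gene
  lists flow through; a field with no peroxisomes yields a flagged
  (undefined) colocalization result; an empty shell (crop smaller than the
  shell stack) raises with an explanatory message, as does a zero plateau
  (no cytosolic ribosomes).
- Watershed marker ties are resolved by the deterministic ordering of
  `peak_local_max`; the smoothing σ is fixed at 2 px.
- Pixel anisotropy is unsupported (one isotropic calibration per dataset).

## Problem sizes

The validation suite and the reproduction script run the study-scale
configurations: 51 organelle scenes (REZ width, proximal counts), 100 scenes
for the count calibration, one dual-bait 4,540-gene dataset (~6 × 10⁶
footprints per sample), and 150 smFISH cells. A full run of the reproduction
script takes under two minutes on one CPU.

## Known limitations

- The REZ estimator assumes an approximately flat cytosolic plateau; profiles
  dominated by boundary truncation (organelle radius comparable to the
  section half-thickness) bias the plateau slightly downward, which the
  ratio-based crossing largely cancels.
- The enrichment caller implements threshold calling only; it does not model
  overdispersion or provide p-values, because the calling rule it reproduces
  is a fixed log2 cutoff with a dual-bait intersection.
- The colocalization criterion (center distance under a threshold) is an
  operationalization of by-eye overlap counting; pixel-overlap criteria are
  not implemented.
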