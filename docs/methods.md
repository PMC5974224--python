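# Methods

## Pipeline model

The pipeline treats one 4-channel confocal z-stack (DAPI, OX-42, GR,
GFAP; fixed acquisition order) as the unit of image processing and one
animal as the unit of statistical analysis. All voxel arithmetic is done
on the acquisition grid: the nucleus size gate and all reported volumes
are raw voxel counts (µm³ given alongside when a voxel size is
supplied), because the size gate that defines an analyzable nucleus is
itself stated in voxels. Default voxel geometry is 0.5 µm z-step and
0.2 µm xy pitch; the xy pitch is a configuration default, not a
constant, since only the z-step is fixed by the acquisition protocol.

### Thresholding

The intensity distribution of each channel yields a scalar noise
threshold, computed per image and never pooled across a cohort. The
default rule is Otsu's between-class-variance maximization, with
`percentile(p)` and `fixed(v)` overrides per channel. Binarization uses
a strict inequality (voxel true iff intensity > t) so fixed-threshold
runs are bit-exact; the threshold actually used is logged per image,
because the original thresholding rule for this kind of data is
typically manual/undocumented and reproducibility has to come from the
log. Otsu on a constant channel raises a degenerate-histogram error
rather than returning an arbitrary cut.

### Nucleus segmentation

Marker-controlled 3D watershed on the inverted Euclidean distance
transform of the DAPI mask. The distance transform is computed with the
physical voxel size (anisotropy-aware), smoothed with a Gaussian
(sigma = 1 voxel) to suppress voxelization maxima, and seeded from its
h-maxima. `h` (default 0.4 µm) sets split sensitivity: a single convex
nucleus has one smoothed maximum and is never split, while two nuclei
fused by a neck are split when the saddle depth exceeds `h`. 26-
connectivity is the package-wide convention for components and seeds.
The volume gate retains nuclei with `low ≤ volume ≤ high`, both bounds
inclusive (the stated "between 1000 and 1500 voxels" is ambiguous at
the boundaries; inclusive was chosen and is documented here), and
re-compacts labels. The filter is idempotent and order-independent.

### Classification and receptor partition

A nucleus is microglial iff every one of its voxels is OX-42-positive.
The strict subset test has no tolerance by default; a relaxation
fraction (`overlap_fraction < 1`) exists for sensitivity analysis and is
recorded in the run config. Nuclear GR content is
`|nucleus ∩ GR| / |nucleus|` on the binarized GR channel — the foci
detector is a separate descriptive output, not the colocalization
input, because the compartment subtraction is defined on total
colocalization volumes. Quartile bins are right-closed with Q1 closed
at zero: [0, .25], (.25, .5], (.5, .75], (.75, 1]; the conventional
labels ("0–25%", "25–50%") overlap at the boundaries, so a convention
had to be fixed — right-closed makes Q4 exactly the "more than 75%"
high-density class.

Soma volume is OX-42 signal inside the nucleus dilated by a Euclidean
ball of radius 3 on the voxel grid. The ball is anisotropy-naive by
design ("three pixels", not micrometres). The dilation mask includes
the nucleus footprint (a dilation of a set contains the set); an
exclude-nucleus option supports sensitivity analysis. Soma volume is
non-decreasing in the radius.

Non-nuclear glial GR is computed image-level as
`|GR ∩ glia| − |GR ∩ glia ∩ DAPI|`, with glia = OX-42 for microglia and
glia = GFAP for astrocytes. Restricting the subtraction to
glia-overlapping GR makes the result nonnegative and the partition
identity `|GR ∩ glia| = nuclear + non-nuclear` exact by construction.
A per-cell variant would also be defensible; image-level is the default
because the subtraction is defined on image totals, and per-animal
averaging happens afterwards either way. Astrocyte nuclear analysis is
deliberately not a validated path: GFAP does not reliably fill the cell
body, so GFAP participates only in channel volume and non-nuclear GR.

### Foci detection

Receptor puncta are above-threshold 26-connected regions partitioned by
watershed on inverted intensity, seeded from intensity h-maxima with
depth `local_max_tolerance`: secondary peaks shallower than the
tolerance merge into their parent focus, so each focus owns exactly one
retained maximum. Size bounds `[min_size, max_size]` apply after
splitting; brightness statistics (mean, peak) come from raw
intensities. The per-focus threshold is the channel threshold from
preprocessing (background-adaptive), not a per-focus Otsu.

### Statistics

All tests operate on per-animal summaries: measures are averaged within
each image (per-cell soma volumes first), then across an animal's
images. An animal with zero classified microglia gets a missing value —
not zero — for microglia-conditional measures.

* **Two-way ANOVA** (age × stress with interaction): Type-II sums of
  squares by default because realistic cohorts are mildly unbalanced;
  Type I/III selectable. A design with zero within-cell variance is
  flagged `degenerate` (null terms report F = 0, non-null terms F = ∞)
  instead of propagating 0/0. An empty design cell raises an error
  naming the cell. The generalized-mixed-model analysis sometimes
  paired with this design is underspecified (link, random effects) and
  is outside the validated surface; fixed-effects ANOVA on per-animal
  means is the implemented analog.
* **Mann–Whitney U**: reported as min(U_x, U_y). Exact enumeration
  p-value when both n ≤ 8 and the pooled sample is tie-free; otherwise
  the tie-corrected normal approximation with continuity correction.
* **Kruskal–Wallis H** with tie correction and chi-square p; all-tied
  data returns H = 0, p = 1 rather than an error.
* **Kolmogorov–Smirnov** two-sample D with the asymptotic p.
* **Pearson r** with the two-sided t-based p; pairs with a missing
  covariate (spine densities are not available for every animal) are
  dropped pairwise; zero variance raises an undefined-correlation
  error.
* **eCDF**: right-continuous step function ending at 1.

Rank statistics are invariant under strictly increasing transforms and
group relabeling (up to the documented U convention); both properties
are tested.

## Synthetic scene and cohort generator

The generator emulates the statistical structure the analysis assumes,
not microscopy physics:

* **Nuclei**: axis-aligned ellipsoids (z-flattened, slight in-plane
  eccentricity) whose radii are rejection-sampled until the voxelized
  volume lands in the requested range — this gives direct, exact
  control over the size-gate behaviour. Placement keeps any two nuclei
  more than `2·soma_thickness + 2` voxels apart, so soma shells never
  touch a foreign nucleus and noise-free classification is correct by
  construction; an overcrowded scene raises a placement error rather
  than silently dropping cells.
* **Microglia**: OX-42 painted over nucleus + soma shell (Euclidean
  dilation of thickness 2 voxels by default) + processes grown as
  persistent random walks from the soma surface until a per-cell voxel
  budget (default 1200) is painted. The budget is what group effect
  multipliers scale, so an injected arbor-volume ratio is recovered
  from ground truth essentially exactly.
* **Astrocytes**: GFAP star filaments radiating from the cell centre
  plus a soma shell; a configurable fraction of astrocytes
  (default 0.5) has GFAP covering the nucleus, the rest do not —
  reproducing the GFAP/DAPI colocalization failure mode of real tissue.
* **GR**: a nuclear fill fraction drawn per cell type (microglia use a
  bimodal mixture, mostly 0.8–1.0 with a nearly-empty minority,
  matching the all-or-nothing nuclear GR observation) applied to a
  random subset of nucleus voxels, plus Poisson-many cytoplasmic
  puncta (small blobs) placed in the soma/arbor region and never inside
  any nucleus. Compartment bookkeeping is exact: nuclear GR ⊆ nucleus,
  cytoplasmic GR ∩ any nucleus = ∅.
* **Optics and noise**: optional anisotropic Gaussian PSF (sigma larger
  in z), then Poisson noise on the scaled signal, then additive
  Gaussian read noise, clipped at zero. Each component is independently
  switchable so oracle tests can run on the clean signal. With PSF and
  noise off, binarizing any channel at half the signal amplitude
  recovers the true support exactly (coverage guarantee).
* **Cohorts**: up to six (age × stress) groups; per-animal seeds are
  spawned deterministically from the master seed, so the whole cohort
  is bit-reproducible while animals remain independent. The manifest
  records group labels, per-image seeds, injected multipliers and true
  per-image volumes for recovery tests.

What the generator does **not** emulate: realistic microglial branching
topology, intensity gradients within cells, chromatin texture,
bleed-through between channels, depth-dependent attenuation, or
digitization to integer bit depths (intensities are float). Passing
recovery tests therefore demonstrates the correctness of the voxel
arithmetic, segmentation and statistics under the generator's
assumptions — not robustness to every artifact of real tissue imaging.

The `soma` effect multiplier scales the shell thickness; because the
nucleus part of the soma region is unaffected, the realized soma-volume
effect is attenuated relative to the multiplier (the manifest records
the multiplier, ground truth records the realized volumes).

## Simulation sizes

Repeated-cohort calibrations (power of the age effect at an injected
1.4× process-volume multiplier, and type-I error under the null) use a
reduced scene — 16×64×64 stacks, three microglia with 150–250-voxel
nuclei and a 300-voxel process budget, noise on, PSF off — in a
2 (age) × 2 (stress) design with 10 animals per cell, 100 replicate
cohorts per condition. The reduced scene keeps thousands of stacks
cheap while preserving the measurement chain (Otsu threshold → channel
volume → per-animal mean → ANOVA age term). Microglial *total* volume
is measured through the thresholding stage directly since it does not
depend on nucleus segmentation.

## Known limitations

* The watershed `h` parameter trades over- against under-segmentation;
  the default (0.4 µm) is calibrated on synthetic ellipsoids and dense
  clumps of real nuclei may need tuning.
* Strict 100% overlap classification is brittle under a strong PSF
  (edge voxels blur below threshold); `overlap_fraction` exists for
  that regime but changes the operating definition and is always
  logged.
* Image-level non-nuclear GR attributes all glia-colocalized GR to the
  glial class of the mask, not to individual cells; per-cell
  attribution would require a cell-territory segmentation that the
  marker channels do not support.
* Pearson correlations against covariates assume one covariate row per
  animal; no hierarchical modeling of image-level variance is
  attempted.
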