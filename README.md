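# gliapipe

Automated 3D confocal image analysis of glial subtypes and
glucocorticoid-receptor (GR) compartmentalization, with group-comparison
statistics and a synthetic ground-truth cohort simulator.

## The problem

Chronic stress and aging remodel cells of the medial prefrontal cortex.
Quantifying how microglia and astrocytes respond requires, from
4-channel confocal z-stacks (DAPI, OX-42, GR, GFAP):

1. **Nucleus instance segmentation** — per-channel noise thresholding,
   3D watershed of the DAPI mask, and a nucleus size gate (volumes
   between 1000 and 1500 voxels retained, inclusive).
2. **Cell-type classification** — a nucleus is *microglial* iff its
   voxel set is completely covered (100% colocalization) by the
   thresholded OX-42 (anti-CD11b/c) mask. GFAP does not reliably fill
   astrocyte cell bodies, so astrocytes contribute only channel-volume
   and non-nuclear GR measures.
3. **Receptor compartment partition** — per cell, the nuclear GR
   fraction `|nucleus ∩ GR| / |nucleus|`, binned into quartiles
   (Q4 = ">75% of the nucleus", the "highly GR-dense" class); per
   image, the non-nuclear glial GR volume
   `|GR ∩ glia| − |GR ∩ glia ∩ DAPI|`.
4. **Soma volumetry** — OX-42 signal within a 3-voxel 3D dilation mask
   around each microglial nucleus.
5. **Group statistics** on per-animal means (the animal is the unit of
   analysis): two-way ANOVA (age × stress, Type-II SS), Mann–Whitney U,
   Kruskal–Wallis H, two-sample Kolmogorov–Smirnov D, Pearson r against
   external covariates (e.g. dendritic-spine densities), and eCDFs.

Because no image data are deposited for this kind of study, the package
ships a first-class synthetic generator (`gliapipe.synthetic`) that
renders 4-channel stacks with exact voxel ground truth — nuclei as
volume-controlled ellipsoids, microglial soma shells + random-walk
processes, astrocytic star filaments, GR split between nuclear fill and
cytoplasmic puncta, anisotropic Gaussian PSF and Poisson–Gaussian
noise — so every pipeline stage is verifiable against known truth.

## Worked example

Simulate a young-vs-aged cohort (4 animals per group) with a 1.4×
multiplier on aged microglial process volume, analyze it end to end,
and score recovery against the generator's truth:

```python
from gliapipe import SceneSpec, CohortDesign, PipelineConfig
from gliapipe.pipeline import simulate_and_analyze

design = CohortDesign(
    groups=(("young", "control"), ("aged", "control")),
    n_animals_per_group=4,
    effect_multipliers={("aged", "control"): {"arbor_volume": 1.4}},
    base_spec=SceneSpec(psf_sigma=None, seed=7),
    seed=7,
)
report, metrics = simulate_and_analyze(design, PipelineConfig())
print(report.animals[["animal_id", "age", "microglial_volume",
                      "n_microglia", "mean_soma_volume"]].round(1))
```

```
  animal_id    age  microglial_volume  n_microglia  mean_soma_volume
0      AC00   aged            19887.0          5.0            2495.6
1      AC01   aged            21127.0          5.0            2716.8
2      AC02   aged            20525.0          5.0            2598.4
3      AC03   aged            21327.0          5.0            2757.2
4      YC00  young            18469.0          5.0            2620.0
5      YC01  young            17895.0          5.0            2498.6
6      YC02  young            17631.0          5.0            2444.6
7      YC03  young            18321.0          5.0            2592.4

age effect on microglial volume: U = 0.0, p = 0.0286
classification accuracy: 1.000
measured aged/young volume ratio: 1.146
```

Every aged animal shows a larger total microglial (OX-42) volume than
every young animal — complete separation, hence U = 0 with the exact
two-sided p for n = 4 vs 4. Classification against ground truth is
perfect, and the measured volume ratio (1.146) is below the injected
process-volume multiplier (1.4) because nuclei and soma shells, which
the multiplier does not touch, contribute to total volume.

A `gliapipe` console command exposes the same stages
(`simulate`, `segment`, `all`, `stats`, `recover`) over TIFF stacks,
CSV manifests and YAML configs; see `gliapipe --help`.

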