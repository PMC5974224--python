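"""Synthetic 4-channel confocal cohort generator with voxel ground truth.

Emulates the acquisition geometry the pipeline expects (0.5 um z-step,
sub-micron xy pitch) and the statistical structure the analysis assumes:

* nuclei are voxelized ellipsoids whose volumes are rejection-sampled
  into a target voxel range, so the nucleus size gate can be exercised
  exactly;
* microglia carry a marker (OX-42) painted over nucleus + soma shell +
  random-walk processes, guaranteeing the 100%-colocalization
  classification rule holds on the noise-free truth;
* astrocytes carry star-shaped GFAP filaments that only cover their
  nucleus in a configurable fraction of cells, reproducing the
  GFAP/DAPI colocalization failure mode of real tissue;
* receptor (GR) signal is split between a nuclear fill fraction drawn
  per cell type and cytoplasmic puncta placed outside every nucleus;
* optional anisotropic Gaussian PSF, then Poisson + Gaussian noise.

Every placement is recorded in :class:`GroundTruth` before PSF/noise, so
each downstream stage can be validated against exact voxel sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import ManifestError, ParameterError, PlacementError
from .types import (
    AGE_LEVELS,
    CHANNELS,
    DEFAULT_VOXEL_SIZE,
    STRESS_LEVELS,
    ImageStack,
)

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "CohortDesign",
    "generate_stack",
    "generate_cohort",
]

CELL_TYPES = ("microglia", "astrocyte", "other")

#: Uniform mixture components (weight, low, high) for the nuclear GR fill
#: fraction per cell type. Microglial nuclei are bimodal — mostly highly
#: receptor-dense, occasionally nearly empty — matching the observed
#: all-or-nothing nuclear receptor distribution.
DEFAULT_GR_FILL: dict[str, tuple[tuple[float, float, float], ...]] = {
    "microglia": ((0.8, 0.8, 1.0), (0.2, 0.0, 0.1)),
    "astrocyte": ((1.0, 0.1, 0.4),),
    "other": ((1.0, 0.6, 1.0),),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic 4-channel stack.

    ``noise`` is ``(poisson_scale, gaussian_sd)``; either component set
    to 0/None disables it. ``psf_sigma`` is a per-axis Gaussian sigma in
    voxels (z, y, x); ``None`` or all-zero disables blurring. Identical
    spec + seed reproduces the stack bit-exactly.
    """

    stack_shape: tuple[int, int, int] = (20, 128, 128)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_microglia: int = 5
    n_astrocytes: int = 3
    n_other_nuclei: int = 6
    nucleus_volume_range: tuple[int, int] = (1000, 1500)
    other_volume_range: tuple[int, int] | None = None
    soma_thickness: float = 2.0
    arbor_extent: float = 10.0  # um, maximal process reach from the soma
    arbor_voxel_budget: int = 1200  # process voxels painted per microglial cell
    gr_nuclear_fill: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_GR_FILL)
    )
    gr_cytoplasmic_density: float = 8.0  # mean puncta per glial cell
    noise: tuple[float | None, float | None] = (1.0, 2.0)
    psf_sigma: tuple[float, float, float] | None = (0.6, 0.4, 0.4)
    signal_amplitude: float = 200.0
    gfap_nucleus_coverage: float = 0.5  # fraction of astrocyte nuclei GFAP covers
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stack_shape):
            raise ParameterError(f"stack_shape must be positive: {self.stack_shape}")
        lo, hi = self.nucleus_volume_range
        if lo > hi or lo <= 0:
            raise ParameterError(f"bad nucleus_volume_range {self.nucleus_volume_range}")
        if self.other_volume_range is not None:
            lo, hi = self.other_volume_range
            if lo > hi or lo <= 0:
                raise ParameterError(f"bad other_volume_range {self.other_volume_range}")
        if not 0.0 <= self.gfap_nucleus_coverage <= 1.0:
            raise ParameterError("gfap_nucleus_coverage must be in [0, 1]")
        for ctype, comps in self.gr_nuclear_fill.items():
            for comp in _fill_components(comps):
                w, lo, hi = comp
                if w < 0 or not (0 <= lo <= hi <= 1):
                    raise ParameterError(
                        f"bad GR fill component {comp} for {ctype!r}"
                    )
        if self.gr_cytoplasmic_density < 0:
            raise ParameterError("gr_cytoplasmic_density must be >= 0")

    @property
    def signal_floor(self) -> float:
        """Binarizing a noise-free, PSF-free channel above this value
        recovers exactly the true signal support."""
        return self.signal_amplitude / 2.0


def _fill_components(value) -> tuple[tuple[float, float, float], ...]:
    """Normalize a GR-fill config entry to mixture components."""
    if (
        isinstance(value, (tuple, list))
        and len(value) == 2
        and np.isscalar(value[0])
    ):
        return ((1.0, float(value[0]), float(value[1])),)
    return tuple(tuple(float(x) for x in comp) for comp in value)


@dataclass
class CellTruth:
    """Ground-truth record of one placed cell (pre-PSF, pre-noise)."""

    cell_id: int
    cell_type: str
    nucleus_label: int
    center: tuple[int, int, int]
    nucleus_voxels: tuple[np.ndarray, ...]  # (z, y, x) index arrays
    nucleus_volume: int
    soma_voxels: tuple[np.ndarray, ...] | None
    soma_volume: int | None
    arbor_volume: int
    nuclear_gr_voxels: int
    nuclear_gr_fraction: float
    cyto_gr_voxels: int
    gfap_covers_nucleus: bool | None = None


@dataclass
class GroundTruth:
    """All placements of one stack, recorded before PSF and noise."""

    cells: list[CellTruth]
    nucleus_labels: np.ndarray  # int32 label volume, 0 = background
    channel_masks: dict[str, np.ndarray]  # true signal support per channel
    channel_true_volume: dict[str, int]

    def cells_of_type(self, ctype: str) -> list[CellTruth]:
        return [c for c in self.cells if c.cell_type == ctype]


def _voxelize_ellipsoid(radii: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoid on a local grid centred at the middle voxel."""
    half = [int(np.ceil(r)) for r in radii]
    zz, yy, xx = np.ogrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    return (
        (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    ) <= 1.0


def _sample_nucleus(
    rng: np.random.Generator,
    volume_range: tuple[int, int],
    max_tries: int = 300,
) -> np.ndarray:
    """Rejection-sample ellipsoid radii until the voxelized volume lands
    in ``volume_range``; returns the local boolean mask."""
    lo, hi = volume_range
    for _ in range(max_tries):
        target = rng.uniform(lo, hi)
        q = rng.uniform(0.55, 0.8)  # z flattening (optical sections)
        e = rng.uniform(0.9, 1.1)  # in-plane eccentricity
        r = (3.0 * target / (4.0 * np.pi * q)) ** (1.0 / 3.0)
        radii = (q * r, e * r, r / e)
        local = _voxelize_ellipsoid(radii)
        if lo <= int(local.sum()) <= hi:
            return local
    raise PlacementError(
        f"could not sample a nucleus with voxel volume in {volume_range}"
    )


def _paint(volume: np.ndarray, center: tuple[int, int, int], local: np.ndarray) -> None:
    """OR a local mask centred at ``center`` into a global volume (clipping)."""
    sl_g, sl_l = _clip_slices(volume.shape, center, local.shape)
    volume[sl_g] |= local[sl_l]


def _clip_slices(shape, center, local_shape):
    sl_g, sl_l = [], []
    for ax in range(3):
        half = local_shape[ax] // 2
        g0, g1 = center[ax] - half, center[ax] + half + 1
        l0 = max(0, -g0)
        l1 = local_shape[ax] - max(0, g1 - shape[ax])
        sl_g.append(slice(max(0, g0), min(shape[ax], g1)))
        sl_l.append(slice(l0, l1))
    return tuple(sl_g), tuple(sl_l)


def _local_shell(local_nucleus: np.ndarray, thickness: float) -> np.ndarray:
    """Soma shell (dilation minus nucleus) on a padded local grid."""
    pad = int(np.ceil(thickness)) + 1
    padded = np.pad(local_nucleus, pad)
    dist = ndi.distance_transform_edt(~padded)
    return (dist <= thickness) & ~padded


def _place_cells(rng, spec: SceneSpec):
    """Place all nuclei without overlap; returns per-cell local masks.

    Separation is enforced by an occupancy volume holding each nucleus
    enlarged by a margin of ``2*soma_thickness + 2`` voxels, so soma
    shells of neighbouring cells can never touch a foreign nucleus.
    """
    shape = spec.stack_shape
    margin = 2.0 * spec.soma_thickness + 2.0
    occupancy = np.zeros(shape, dtype=bool)
    plan = (
        ["microglia"] * spec.n_microglia
        + ["astrocyte"] * spec.n_astrocytes
        + ["other"] * spec.n_other_nuclei
    )
    placed = []
    for ctype in plan:
        vol_range = (
            spec.other_volume_range
            if (ctype == "other" and spec.other_volume_range is not None)
            else spec.nucleus_volume_range
        )
        for attempt in range(300):
            local = _sample_nucleus(rng, vol_range)
            half = [s // 2 for s in local.shape]
            if any(2 * h + 1 > s for h, s in zip(half, shape)):
                continue  # nucleus larger than the stack along an axis
            center = tuple(
                int(rng.integers(h, s - h)) for h, s in zip(half, shape)
            )
            sl_g, sl_l = _clip_slices(shape, center, local.shape)
            if not (occupancy[sl_g] & local[sl_l]).any():
                break
        else:
            raise PlacementError(
                f"scene overcrowded: failed to place a {ctype} nucleus after "
                f"300 attempts ({len(placed)} cells placed)"
            )
        # enlarge by the margin for the occupancy record
        grown = _voxelize_ellipsoid(
            tuple(h + margin for h in ((np.array(local.shape) - 1) / 2.0))
        )
        # conservative: grown axis-aligned ellipsoid contains the true
        # Euclidean dilation of the nucleus by `margin`
        _paint(occupancy, center, grown)
        placed.append((ctype, center, local))
    return placed


def _random_walk_arbor(
    rng,
    painted: np.ndarray,
    start_pool: tuple[np.ndarray, ...],
    center: np.ndarray,
    spec: SceneSpec,
    forbidden: np.ndarray,
    budget: int,
) -> int:
    """Paint up to ``budget`` new process voxels with persistent random
    walks from random soma-surface start points. Each walk is a vectorized
    segment truncated at the first out-of-bounds / forbidden / beyond-reach
    position. Returns the number of voxels painted (== budget unless the
    reachable region saturates)."""
    if budget <= 0 or start_pool[0].size == 0:
        return 0
    shape = np.array(painted.shape)
    vz = np.array(spec.voxel_size)
    flat = painted.ravel()
    forb_flat = forbidden.ravel()
    count = 0
    seg = 200
    max_walks = 80 + budget // 5
    for _ in range(max_walks):
        if count >= budget:
            break
        k = int(rng.integers(start_pool[0].size))
        start = np.array([int(a[k]) for a in start_pool])
        d = rng.normal(size=3)
        d[0] *= 0.4  # processes spread mostly in-plane
        d /= np.linalg.norm(d) + 1e-12
        steps = np.sign(d + rng.normal(scale=0.7, size=(seg, 3))).astype(np.int64)
        pos = start + np.cumsum(steps, axis=0)
        oob = ((pos < 0) | (pos >= shape)).any(axis=1)
        posc = np.clip(pos, 0, shape - 1)
        lin = np.ravel_multi_index(tuple(posc.T), painted.shape)
        bad = (
            oob
            | forb_flat[lin]
            | (np.linalg.norm((posc - center) * vz, axis=1) > spec.arbor_extent)
        )
        n_ok = int(np.argmax(bad)) if bad.any() else seg
        if n_ok == 0:
            continue
        lin = lin[:n_ok]
        uniq, first = np.unique(lin, return_index=True)
        uniq = uniq[np.argsort(first)]  # first-occurrence order
        new = uniq[~flat[uniq]]
        take = new[: budget - count]
        flat[take] = True
        count += take.size
    return count


def _star_filaments(
    rng, painted: np.ndarray, center: np.ndarray, spec: SceneSpec, n_rays: int = 6
) -> None:
    """Astrocyte arbor: straight filaments radiating from the cell centre."""
    shape = np.array(painted.shape)
    vz = np.array(spec.voxel_size)
    reach = spec.arbor_extent
    for _ in range(n_rays):
        d = rng.normal(size=3)
        d[0] *= 0.4
        d /= np.linalg.norm(d) + 1e-12
        n_pts = int(reach / min(vz)) + 1
        for t in np.linspace(0, 1, 2 * n_pts):
            p = center + d * t * reach / vz  # um -> voxel step per axis
            p = np.round(p).astype(int)
            if (p < 0).any() or (p >= shape).any():
                break
            painted[tuple(p)] = True


def generate_stack(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic stack and its exact ground truth.

    Raises
    ------
    PlacementError
        If cells cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.stack_shape
    masks = {name: np.zeros(shape, dtype=bool) for name in CHANNELS}
    labels = np.zeros(shape, dtype=np.int32)

    placed = _place_cells(rng, spec)

    # exclusion zone: every nucleus grown by 1 voxel; arbors and puncta stay out
    nuclei_plus1 = np.zeros(shape, dtype=bool)
    for _, center, local in placed:
        pad = np.pad(local, 1)
        grown = ndi.binary_dilation(pad, structure=np.ones((3, 3, 3), bool))
        _paint(nuclei_plus1, center, grown)

    cells: list[CellTruth] = []
    for idx, (ctype, center, local) in enumerate(placed):
        label = idx + 1
        sl_g, sl_l = _clip_slices(shape, center, local.shape)
        labels[sl_g][local[sl_l]] = label
        masks["DAPI"][sl_g] |= local[sl_l]
        nucleus_voxels = np.nonzero(labels == label)
        nucleus_volume = int(nucleus_voxels[0].size)

        soma_voxels = None
        soma_volume = None
        arbor_volume = 0
        gfap_covers = None
        cyto_region = None

        own = np.zeros(shape, dtype=bool)
        own[sl_g] = local[sl_l]
        own_plus1 = np.zeros(shape, dtype=bool)
        _paint(
            own_plus1,
            center,
            ndi.binary_dilation(np.pad(local, 1), structure=np.ones((3, 3, 3), bool)),
        )
        foreign = nuclei_plus1 & ~own_plus1  # protected zone around other nuclei

        if ctype == "microglia":
            shell = _local_shell(local, spec.soma_thickness)
            soma_mask = np.zeros(shape, dtype=bool)
            _paint(soma_mask, center, shell)
            soma_mask &= ~foreign
            masks["OX-42"] |= own | soma_mask
            # walks may cross the cell's own body (pre-marked, not counted)
            # but never a foreign nucleus zone
            arbor_painted = own | soma_mask
            arbor_volume = _random_walk_arbor(
                rng,
                arbor_painted,
                np.nonzero(soma_mask),
                np.array(center),
                spec,
                foreign,
                spec.arbor_voxel_budget,
            )
            arbor = arbor_painted & ~(own | soma_mask)
            masks["OX-42"] |= arbor
            soma_region = own | soma_mask
            soma_voxels = np.nonzero(soma_region)
            soma_volume = int(soma_voxels[0].size)
            cyto_region = soma_mask | arbor
        elif ctype == "astrocyte":
            gfap_covers = bool(rng.uniform() < spec.gfap_nucleus_coverage)
            shell = _local_shell(local, spec.soma_thickness)
            soma_mask = np.zeros(shape, dtype=bool)
            _paint(soma_mask, center, shell)
            soma_mask &= ~foreign
            if gfap_covers:
                masks["GFAP"] |= own | soma_mask
            else:
                # non-uniform GFAP: the filament hub misses the nucleus body
                masks["GFAP"] |= soma_mask
            arbor = np.zeros(shape, dtype=bool)
            _star_filaments(rng, arbor, np.array(center), spec)
            arbor &= ~nuclei_plus1
            masks["GFAP"] |= arbor
            arbor_volume = int(arbor.sum())
            cyto_region = soma_mask | arbor
        else:
            ring = _local_shell(local, 3.0)
            cyto = np.zeros(shape, dtype=bool)
            _paint(cyto, center, ring)
            cyto_region = cyto & ~nuclei_plus1

        # nuclear GR: fill a drawn fraction of nucleus voxels
        frac = _draw_fill(rng, spec.gr_nuclear_fill.get(ctype, ((1.0, 0.0, 0.0),)))
        k = int(round(frac * nucleus_volume))
        if k > 0:
            pick = rng.choice(nucleus_volume, size=k, replace=False)
            masks["GR"][tuple(a[pick] for a in nucleus_voxels)] = True

        # cytoplasmic GR puncta outside every nucleus
        cyto_count = 0
        if ctype in ("microglia", "astrocyte") and spec.gr_cytoplasmic_density > 0:
            n_puncta = int(rng.poisson(spec.gr_cytoplasmic_density))
            pool = np.nonzero(cyto_region)
            if pool[0].size:
                for _ in range(n_puncta):
                    j = int(rng.integers(pool[0].size))
                    c = np.array([int(a[j]) for a in pool])
                    blob = np.zeros(shape, dtype=bool)
                    _paint(blob, tuple(c), _voxelize_ellipsoid((1.2, 1.2, 1.2)))
                    blob &= ~nuclei_plus1
                    cyto_count += int((blob & ~masks["GR"]).sum())
                    masks["GR"] |= blob

        cells.append(
            CellTruth(
                cell_id=idx,
                cell_type=ctype,
                nucleus_label=label,
                center=tuple(int(c) for c in center),
                nucleus_voxels=nucleus_voxels,
                nucleus_volume=nucleus_volume,
                soma_voxels=soma_voxels,
                soma_volume=soma_volume,
                arbor_volume=arbor_volume,
                nuclear_gr_voxels=k,
                nuclear_gr_fraction=(k / nucleus_volume),
                cyto_gr_voxels=cyto_count,
                gfap_covers_nucleus=gfap_covers,
            )
        )

    truth = GroundTruth(
        cells=cells,
        nucleus_labels=labels,
        channel_masks=masks,
        channel_true_volume={n: int(m.sum()) for n, m in masks.items()},
    )

    img = np.stack(
        [spec.signal_amplitude * masks[name].astype(np.float64) for name in CHANNELS]
    )
    if spec.psf_sigma is not None and any(s > 0 for s in spec.psf_sigma):
        for c in range(img.shape[0]):
            img[c] = ndi.gaussian_filter(img[c], sigma=spec.psf_sigma)
    poisson_scale, gaussian_sd = spec.noise
    if poisson_scale:
        img = rng.poisson(img * poisson_scale).astype(np.float64) / poisson_scale
    if gaussian_sd:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)

    stack = ImageStack(voxels=img, voxel_size=spec.voxel_size)
    return stack, truth


def _draw_fill(rng, components) -> float:
    comps = _fill_components(components)
    weights = np.array([c[0] for c in comps], dtype=float)
    weights = weights / weights.sum()
    i = int(rng.choice(len(comps), p=weights))
    return float(rng.uniform(comps[i][1], comps[i][2]))


# ---------------------------------------------------------------------------
# cohorts

_MEASURES = ("arbor_volume", "soma", "cyto_gr")


@dataclass(frozen=True)
class CohortDesign:
    """A multi-animal factorial cohort with injected group effects.

    ``groups`` lists (age, stress) combinations drawn from the six-group
    young/aged x control/stress/recovery design. ``effect_multipliers``
    maps a group to multiplicative shifts on microglial arbor volume,
    soma thickness and cytoplasmic receptor density; unlisted groups get
    1.0 everywhere.
    """

    groups: tuple[tuple[str, str], ...]
    n_animals_per_group: int
    images_per_animal: int = 1
    effect_multipliers: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    base_spec: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0
    animal_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ParameterError("at least one group required")
        if len(self.groups) > 6 or len(set(self.groups)) != len(self.groups):
            raise ParameterError("at most six distinct (age, stress) groups")
        for age, stress in self.groups:
            if age not in AGE_LEVELS or stress not in STRESS_LEVELS:
                raise ParameterError(f"unknown group ({age}, {stress})")
        if self.n_animals_per_group < 1 or self.images_per_animal < 1:
            raise ParameterError("need >= 1 animal per group and image per animal")
        for group, mults in self.effect_multipliers.items():
            for name, m in mults.items():
                if name not in _MEASURES:
                    raise ParameterError(f"unknown effect measure {name!r}")
                if m <= 0:
                    raise ParameterError(f"multiplier for {name!r} must be > 0")
        if self.animal_ids is not None:
            expected = len(self.groups) * self.n_animals_per_group
            if len(self.animal_ids) != expected:
                raise ManifestError(
                    f"{expected} animal ids required, got {len(self.animal_ids)}"
                )
            if len(set(self.animal_ids)) != len(self.animal_ids):
                raise ManifestError("duplicate animal IDs in cohort design")


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[tuple[ImageStack, GroundTruth]], pd.DataFrame]:
    """Generate every stack of a cohort plus its manifest.

    Per-animal seeds are spawned deterministically from the master seed,
    so animals are independent but the whole cohort is reproducible
    bit-exactly. The manifest records the group, the per-image seed and
    the injected multipliers, plus true per-image volumes for recovery
    tests.
    """
    ss = np.random.SeedSequence(design.seed)
    n_animals = len(design.groups) * design.n_animals_per_group
    animal_seqs = ss.spawn(n_animals)

    results: list[tuple[ImageStack, GroundTruth]] = []
    rows = []
    a = 0
    for age, stress in design.groups:
        mults = {m: 1.0 for m in _MEASURES}
        mults.update(design.effect_multipliers.get((age, stress), {}))
        for i in range(design.n_animals_per_group):
            if design.animal_ids is not None:
                animal_id = design.animal_ids[a]
            else:
                animal_id = f"{age[0].upper()}{stress[0].upper()}{i:02d}"
            image_seqs = animal_seqs[a].spawn(design.images_per_animal)
            a += 1
            for j in range(design.images_per_animal):
                seed = int(image_seqs[j].generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
                spec = replace(
                    design.base_spec,
                    seed=seed,
                    arbor_voxel_budget=int(
                        round(design.base_spec.arbor_voxel_budget * mults["arbor_volume"])
                    ),
                    soma_thickness=design.base_spec.soma_thickness * mults["soma"],
                    gr_cytoplasmic_density=(
                        design.base_spec.gr_cytoplasmic_density * mults["cyto_gr"]
                    ),
                )
                stack, truth = generate_stack(spec)
                image_id = f"{animal_id}_img{j:02d}"
                stack = dataclasses.replace(
                    stack,
                    image_id=image_id,
                    animal_id=animal_id,
                    age=age,
                    stress=stress,
                )
                results.append((stack, truth))
                mg = truth.cells_of_type("microglia")
                rows.append(
                    {
                        "image_id": image_id,
                        "animal_id": animal_id,
                        "age": age,
                        "stress": stress,
                        "image_index": j,
                        "seed": seed,
                        "mult_arbor_volume": mults["arbor_volume"],
                        "mult_soma": mults["soma"],
                        "mult_cyto_gr": mults["cyto_gr"],
                        "true_ox42_volume": truth.channel_true_volume["OX-42"],
                        "true_gfap_volume": truth.channel_true_volume["GFAP"],
                        "true_arbor_volume": sum(c.arbor_volume for c in mg),
                        "true_n_microglia": len(mg),
                    }
                )
    manifest = pd.DataFrame(rows)
    return results, manifest
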