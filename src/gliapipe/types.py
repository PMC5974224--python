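"""Core in-memory containers shared by all pipeline stages.

Array axis convention: volumes are ``(z, y, x)``; multi-channel stacks are
``(c, z, y, x)``. Voxel sizes are micrometres per axis in ``(z, y, x)``
order. The default geometry mirrors a confocal acquisition with a 0.5 um
z-step and a 0.2 um xy pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.ndimage as ndi

#: Fixed channel order (acquisition order): nuclear stain, microglial
#: marker (anti-CD11b/c), glucocorticoid receptor, astrocytic marker.
CHANNELS: tuple[str, ...] = ("DAPI", "OX-42", "GR", "GFAP")

#: Default voxel size in um, (z, y, x).
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.5, 0.2, 0.2)

AGE_LEVELS = ("young", "aged")
STRESS_LEVELS = ("control", "stress", "recovery")


@dataclass
class ImageStack:
    """One 4-channel 3D acquisition with voxel geometry and provenance.

    Parameters
    ----------
    voxels : ndarray, shape (4, z, y, x)
        Nonnegative intensities, one 3D volume per channel.
    voxel_size : tuple of float
        Micrometres per voxel along (z, y, x).
    image_id, animal_id : str
        Provenance identifiers.
    age : {"young", "aged"} or None
    stress : {"control", "stress", "recovery"} or None
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_names: tuple[str, ...] = CHANNELS
    image_id: str = "image"
    animal_id: str = ""
    age: str | None = None
    stress: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != len(CHANNELS):
            raise ValueError(
                f"expected (4, z, y, x) stack, got shape {self.voxels.shape}"
            )
        if tuple(self.channel_names) != CHANNELS:
            raise ValueError(f"channel order must be {CHANNELS}")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be nonnegative")
        if self.age is not None and self.age not in AGE_LEVELS:
            raise ValueError(f"age must be one of {AGE_LEVELS}")
        if self.stress is not None and self.stress not in STRESS_LEVELS:
            raise ValueError(f"stress must be one of {STRESS_LEVELS}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (z, y, x)."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D intensity volume for a named channel."""
        return self.voxels[CHANNELS.index(name)]


@dataclass
class BinaryMask:
    """A thresholded channel: boolean volume plus the rule that produced it."""

    mask: np.ndarray
    source_channel: str = ""
    threshold_used: float = float("nan")
    method: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabeledNuclei:
    """Instance-segmented nuclei: integer label volume (0 = background).

    Labels are contiguous positive integers 1..n. Per-nucleus volumes and
    centroids are computed once from the label volume.
    """

    label_volume: np.ndarray
    volumes: dict[int, int] = field(default_factory=dict)
    centroids: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if not self.volumes:
            self._recompute()
        labels = sorted(self.volumes)
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError("labels must be contiguous positive integers")

    def _recompute(self) -> None:
        counts = np.bincount(self.label_volume.ravel())
        labels = [int(l) for l in np.nonzero(counts)[0] if l > 0]
        self.volumes = {l: int(counts[l]) for l in labels}
        if labels:
            coms = ndi.center_of_mass(
                self.label_volume > 0, self.label_volume, labels
            )
            self.centroids = {
                l: tuple(float(c) for c in com) for l, com in zip(labels, coms)
            }
        else:
            self.centroids = {}

    @property
    def labels(self) -> list[int]:
        return sorted(self.volumes)

    @property
    def n_nuclei(self) -> int:
        return len(self.volumes)

    def mask_for(self, label: int) -> np.ndarray:
        """Boolean voxel set of one nucleus."""
        return self.label_volume == label

    def __iter__(self) -> Iterator[int]:
        return iter(self.labels)


@dataclass
class Focus:
    """One detected receptor punctum."""

    id: int
    volume: int
    centroid: tuple[float, float, float]
    mean_brightness: float
    peak_brightness: float
    voxels: tuple[np.ndarray, ...] | None = None  # (z, y, x) index arrays


@dataclass
class CellRecord:
    """One classified cell and its per-cell receptor measures."""

    nucleus_label: int
    cell_type: str  # "microglia" | "unclassified"
    nucleus_volume: int
    nuclear_gr_fraction: float
    gr_quartile: str  # "Q1".."Q4"
    soma_volume: int | None  # None for unclassified cells
    image_id: str = ""
    animal_id: str = ""


@dataclass
class ImageGRSummary:
    """Image-level totals feeding the per-animal aggregation."""

    image_id: str
    animal_id: str = ""
    microglial_volume: int = 0
    astrocyte_volume: int = 0
    n_nuclei: int = 0
    n_microglia: int = 0
    n_high_gr_nuclei: int = 0
    nonnuclear_gr_microglia: int = 0
    nonnuclear_gr_astrocyte: int = 0
    mean_soma_volume: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_high_gr_nuclei > self.n_microglia:
            raise ValueError("high-GR nucleus count cannot exceed microglia count")
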