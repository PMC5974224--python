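"""Cell-type assignment and compartmental receptor quantification.

A nucleus is classified microglial iff its voxel set is fully covered by
the thresholded microglial-marker (OX-42) mask — a strict 100%-overlap
rule, with an optional relaxation fraction for sensitivity analysis.
Nuclear receptor content is the fraction of nucleus voxels that carry
thresholded GR signal, binned into quartiles; "highly GR dense" means
more than 75% of the nucleus (Q4). Soma volume is marker signal inside a
3-voxel dilation shell around the nucleus. Non-nuclear receptor volume is
the image-level glial GR colocalization minus its nuclear part.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .morphology import dilate_ball
from .types import BinaryMask, CellRecord, ImageGRSummary, LabeledNuclei

__all__ = [
    "classify_microglial_nuclei",
    "nuclear_gr_fraction",
    "quartile_bin",
    "soma_volume",
    "nonnuclear_gr_volume",
    "count_high_gr_nuclei",
    "build_cell_records",
    "summarize_image",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def _as_mask(m: BinaryMask | np.ndarray) -> np.ndarray:
    return m.mask if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool)


def classify_microglial_nuclei(
    nuclei: LabeledNuclei,
    ox42_mask: BinaryMask | np.ndarray,
    min_overlap: float = 1.0,
) -> set[int]:
    """Return labels of nuclei whose marker coverage reaches ``min_overlap``.

    At the default ``min_overlap=1.0`` this is the strict subset test:
    every nucleus voxel must be marker-positive.
    """
    ox42 = _as_mask(ox42_mask)
    if ox42.shape != nuclei.label_volume.shape:
        raise ParameterError("mask and label volume shapes differ")
    if not 0.0 < min_overlap <= 1.0:
        raise ParameterError(f"min_overlap must be in (0, 1], got {min_overlap}")
    labels = nuclei.label_volume
    total = np.bincount(labels.ravel(), minlength=nuclei.n_nuclei + 1)
    covered = np.bincount(labels[ox42].ravel(), minlength=nuclei.n_nuclei + 1)
    out: set[int] = set()
    for label in nuclei.labels:
        if min_overlap >= 1.0:
            if covered[label] == total[label]:
                out.add(label)
        elif covered[label] >= min_overlap * total[label]:
            out.add(label)
    return out


def nuclear_gr_fraction(
    nucleus_mask: np.ndarray, gr_mask: BinaryMask | np.ndarray
) -> float:
    """Fraction of nucleus voxels carrying receptor signal:
    |nucleus ∩ GR| / |nucleus|.
    """
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    n = int(nucleus.sum())
    if n == 0:
        raise ParameterError("nucleus voxel set is empty")
    return float(np.logical_and(nucleus, _as_mask(gr_mask)).sum()) / n


def quartile_bin(fraction: float) -> str:
    """Bin a nuclear receptor fraction into Q1..Q4.

    Bins are right-closed: [0, 0.25], (0.25, 0.5], (0.5, 0.75], (0.75, 1].
    Q4 therefore matches the "more than 75% of the nucleus" rule for
    highly receptor-dense nuclei.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    for i, edge in enumerate((0.25, 0.5, 0.75)):
        if fraction <= edge:
            return QUARTILES[i]
    return "Q4"


def soma_volume(
    nucleus_mask: np.ndarray,
    ox42_mask: BinaryMask | np.ndarray,
    dilation_radius: float = 3.0,
    include_nucleus: bool = True,
) -> int:
    """Marker-positive voxels within the dilation mask around a nucleus.

    The dilation mask is the nucleus grown by a Euclidean ball of
    ``dilation_radius`` voxels on the grid ("three pixels beyond the edge
    of the nucleus"); it contains the nucleus footprint unless
    ``include_nucleus=False``. Non-decreasing in the radius.
    """
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    region = dilate_ball(nucleus, dilation_radius)
    if not include_nucleus:
        region &= ~nucleus
    return int(np.logical_and(region, _as_mask(ox42_mask)).sum())


def nonnuclear_gr_volume(
    gr_mask: BinaryMask | np.ndarray,
    glia_mask: BinaryMask | np.ndarray,
    dapi_mask: BinaryMask | np.ndarray,
) -> int:
    """Image-level non-nuclear glial receptor volume:
    |GR ∩ glia| − |GR ∩ glia ∩ DAPI|.

    The subtraction is restricted to glia-overlapping GR, so the result
    is never negative, and the partition identity
    |GR ∩ glia| = nuclear + non-nuclear holds exactly.
    """
    gr = _as_mask(gr_mask)
    glia = _as_mask(glia_mask)
    dapi = _as_mask(dapi_mask)
    if not gr.shape == glia.shape == dapi.shape:
        raise ParameterError("mask shapes differ")
    gr_glia = np.logical_and(gr, glia)
    return int(gr_glia.sum()) - int(np.logical_and(gr_glia, dapi).sum())


def count_high_gr_nuclei(cells: list[CellRecord]) -> int:
    """Number of microglial cells whose nuclear GR fraction exceeds 75% (Q4)."""
    return sum(
        1 for c in cells if c.cell_type == "microglia" and c.gr_quartile == "Q4"
    )


def build_cell_records(
    nuclei: LabeledNuclei,
    ox42_mask: BinaryMask | np.ndarray,
    gr_mask: BinaryMask | np.ndarray,
    min_overlap: float = 1.0,
    dilation_radius: float = 3.0,
    include_nucleus: bool = True,
    image_id: str = "",
    animal_id: str = "",
) -> list[CellRecord]:
    """Classify every retained nucleus and measure its receptor content.

    Soma volume is measured only for microglia (the classification rule
    guarantees the marker covers the nucleus, so the dilation shell is
    meaningful); unclassified cells carry ``soma_volume=None``.
    """
    microglia = classify_microglial_nuclei(nuclei, ox42_mask, min_overlap)
    records: list[CellRecord] = []
    for label in nuclei.labels:
        nucleus = nuclei.mask_for(label)
        frac = nuclear_gr_fraction(nucleus, gr_mask)
        is_mg = label in microglia
        records.append(
            CellRecord(
                nucleus_label=label,
                cell_type="microglia" if is_mg else "unclassified",
                nucleus_volume=nuclei.volumes[label],
                nuclear_gr_fraction=frac,
                gr_quartile=quartile_bin(frac),
                soma_volume=(
                    soma_volume(nucleus, ox42_mask, dilation_radius, include_nucleus)
                    if is_mg
                    else None
                ),
                image_id=image_id,
                animal_id=animal_id,
            )
        )
    return records


def summarize_image(
    cells: list[CellRecord],
    masks: dict[str, BinaryMask],
    nuclei: LabeledNuclei,
    image_id: str = "",
    animal_id: str = "",
) -> ImageGRSummary:
    """Aggregate one image's cell records and channel masks."""
    somas = [c.soma_volume for c in cells if c.cell_type == "microglia"]
    return ImageGRSummary(
        image_id=image_id,
        animal_id=animal_id,
        microglial_volume=masks["OX-42"].volume_voxels,
        astrocyte_volume=masks["GFAP"].volume_voxels,
        n_nuclei=nuclei.n_nuclei,
        n_microglia=len(somas),
        n_high_gr_nuclei=count_high_gr_nuclei(cells),
        nonnuclear_gr_microglia=nonnuclear_gr_volume(
            masks["GR"], masks["OX-42"], masks["DAPI"]
        ),
        nonnuclear_gr_astrocyte=nonnuclear_gr_volume(
            masks["GR"], masks["GFAP"], masks["DAPI"]
        ),
        mean_soma_volume=float(np.mean(somas)) if somas else float("nan"),
    )
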