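"""Reading and writing the pipeline's on-disk formats.

Stacks are multi-page TIFF files in (c, z, y, x) page order with a JSON
sidecar (``<stem>.json``) carrying voxel geometry, channel order and
provenance. Ground truth is a compressed label TIFF plus a JSON record.
Manifests and result tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ManifestError
from .types import CHANNELS, ImageStack
from .synthetic import GroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth",
    "read_manifest",
    "write_manifest",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), compression="zlib")
    sidecar = {
        "channel_names": list(stack.channel_names),
        "channel_layout": "interleaved",  # all channels in one file, axis 0
        "voxel_size_um_zyx": list(stack.voxel_size),
        "image_id": stack.image_id,
        "animal_id": stack.animal_id,
        "age": stack.age,
        "stress": stack.stress,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    voxels = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ManifestError(f"missing sidecar for {path}")
    meta = json.loads(sidecar_path.read_text())
    if tuple(meta["channel_names"]) != CHANNELS:
        raise ManifestError(f"unexpected channel order in {sidecar_path}")
    return ImageStack(
        voxels=voxels,
        voxel_size=tuple(meta["voxel_size_um_zyx"]),
        image_id=meta.get("image_id", path.stem),
        animal_id=meta.get("animal_id", ""),
        age=meta.get("age"),
        stress=meta.get("stress"),
    )


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write ground truth: label TIFF + per-cell JSON (voxel sets omitted,
    they are reproducible from the labels and the seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, truth.nucleus_labels.astype(np.int32), compression="zlib")
    record = {
        "channel_true_volume": truth.channel_true_volume,
        "cells": [
            {
                "cell_id": c.cell_id,
                "cell_type": c.cell_type,
                "nucleus_label": c.nucleus_label,
                "center_zyx": list(c.center),
                "nucleus_volume": c.nucleus_volume,
                "soma_volume": c.soma_volume,
                "arbor_volume": c.arbor_volume,
                "nuclear_gr_fraction": c.nuclear_gr_fraction,
                "cyto_gr_voxels": c.cyto_gr_voxels,
                "gfap_covers_nucleus": c.gfap_covers_nucleus,
            }
            for c in truth.cells
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(record, indent=1))
    return path


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"image_id", "animal_id", "age", "stress"}
    missing = required - set(manifest.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    return manifest
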