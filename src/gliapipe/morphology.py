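"""Small 3D morphology helpers shared by the segmenter, the classifier
and the scene generator. 26-connectivity is the package-wide convention.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

#: 3x3x3 all-ones structuring element = 26-connectivity.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def dilate_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilate a boolean volume by a Euclidean ball of ``radius`` voxels.

    The ball lives on the voxel grid (anisotropy-naive): a voxel belongs
    to the dilation iff its grid distance to the set is <= radius. The
    result contains the input set. Radius may be fractional.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0 or not mask.any():
        return mask.copy()
    dist = ndi.distance_transform_edt(~mask)
    return dist <= radius
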