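"""Per-channel noise thresholding and binarization.

Each channel's intensity distribution yields a scalar noise threshold;
voxels strictly above it form the channel's binary mask. Thresholds are
computed per image, never pooled across a cohort, and the value used is
carried on the mask for logging.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, ParameterError
from .types import BinaryMask, ImageStack

__all__ = ["compute_threshold", "binarize", "threshold_stack"]


def compute_threshold(
    channel: np.ndarray, method: str = "otsu", **params: float
) -> float:
    """Compute a scalar noise threshold for one channel.

    Parameters
    ----------
    channel : ndarray
        3D intensity volume (any shape works; only the histogram is used).
    method : {"otsu", "percentile", "fixed"}
        ``otsu`` maximizes between-class variance; ``percentile`` takes
        ``p`` (0..100); ``fixed`` returns ``value`` verbatim.

    Returns
    -------
    float
        Deterministic threshold for this channel and method.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ParameterError("cannot threshold an empty array")
    if method == "fixed":
        if "value" not in params:
            raise ParameterError("fixed threshold requires value=")
        return float(params["value"])
    if method == "percentile":
        p = params.get("p", 50.0)
        if not 0.0 <= p <= 100.0:
            raise ParameterError(f"percentile must be in [0, 100], got {p}")
        return float(np.percentile(channel, p))
    if method == "otsu":
        if np.all(channel == channel.flat[0]):
            raise DegenerateHistogramError(
                "Otsu threshold undefined for a constant-valued channel"
            )
        return float(threshold_otsu(channel.ravel()))
    raise ParameterError(f"unknown threshold method {method!r}")


def binarize(
    channel: np.ndarray,
    threshold: float,
    source_channel: str = "",
    method: str = "",
) -> BinaryMask:
    """Binarize a channel with a strict inequality: voxel true iff
    intensity > threshold. Strictness makes fixed-threshold runs bit-exact
    and leaves an all-zero channel empty at threshold 0.
    """
    if not np.isfinite(threshold):
        raise ParameterError(f"threshold must be finite, got {threshold}")
    return BinaryMask(
        mask=np.asarray(channel) > threshold,
        source_channel=source_channel,
        threshold_used=float(threshold),
        method=method,
    )


def threshold_stack(
    stack: ImageStack,
    methods: dict[str, dict] | None = None,
) -> dict[str, BinaryMask]:
    """Threshold and binarize every channel of a stack.

    ``methods`` maps channel name to ``{"method": ..., **params}``;
    unlisted channels default to Otsu.
    """
    methods = methods or {}
    out: dict[str, BinaryMask] = {}
    for name in stack.channel_names:
        cfg = dict(methods.get(name, {"method": "otsu"}))
        method = cfg.pop("method", "otsu")
        t = compute_threshold(stack.channel(name), method, **cfg)
        out[name] = binarize(stack.channel(name), t, source_channel=name, method=method)
    return out
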