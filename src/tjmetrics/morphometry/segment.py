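"""Segmentation of junction ridges from a fluorescence channel."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = ["segment_junctions"]


def segment_junctions(
    image: np.ndarray,
    pixel_size_um: float,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    background: str = "rolling_mean",
    background_radius_um: float = 5.0,
    min_object_px: int = 20,
) -> np.ndarray:
    """Binary foreground mask of junction ridges.

    Pipeline: background subtraction (rolling mean over a square window, or
    subtraction of the image minimum for ``background="constant"``), global
    threshold (Otsu or a fixed value), then removal of connected components
    smaller than ``min_object_px``.

    Raises ``ValueError`` naming the threshold if the foreground is empty.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    if background == "rolling_mean":
        size = max(3, int(round(2 * background_radius_um / pixel_size_um)) | 1)
        sub = img - uniform_filter(img, size=size)
    elif background == "constant":
        sub = img - img.min()
    elif background == "none":
        sub = img
    else:
        raise ValueError(f"unknown background mode {background!r}")
    sub = np.clip(sub, 0.0, None)

    if threshold_method == "otsu":
        if np.ptp(sub) == 0:
            raise ValueError(
                "empty foreground: image is constant after background "
                "subtraction; Otsu threshold undefined"
            )
        thr = float(threshold_otsu(sub))
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    mask = sub > thr
    if min_object_px > 0:
        # drop connected components with fewer than min_object_px pixels
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    if not mask.any():
        raise ValueError(f"empty foreground at threshold {thr:.6g} ({threshold_method})")
    return mask
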