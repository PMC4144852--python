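"""Line-scan intensity profiling and transverse-profile classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

__all__ = ["LineScanProfile", "line_scan", "classify_transverse_profile"]

ProfileClass = Literal["none", "single_peak", "double_peak"]


@dataclass(frozen=True)
class LineScanProfile:
    """Intensity sampled along a scan segment.

    ``positions_um`` runs from 0 at the start point; ``width_um`` is the
    breadth over which intensity was averaged perpendicular to the line.
    """

    positions_um: np.ndarray
    intensity: np.ndarray
    width_um: float

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_um, dtype=float)
        v = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "positions_um", p)
        object.__setattr__(self, "intensity", v)
        if p.ndim != 1 or v.shape != p.shape:
            raise ValueError("positions and intensity must be 1-D and equal length")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("positions must be strictly increasing")


def line_scan(
    image: np.ndarray,
    pixel_size_um: float,
    p_start_um: tuple[float, float],
    p_end_um: tuple[float, float],
    width_um: float = 0.0,
    step_um: float | None = None,
) -> LineScanProfile:
    """Sample intensity along a segment with bilinear interpolation.

    Intensity at each position is averaged over ``width_um`` perpendicular
    to the scan direction. Endpoints are (x, y) in µm and must lie inside
    the image. The sampling step defaults to half a pixel.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    p0 = np.asarray(p_start_um, dtype=float)
    p1 = np.asarray(p_end_um, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= w * pixel_size_um and 0 <= p[1] <= h * pixel_size_um):
            raise ValueError(f"scan endpoint {tuple(p)} µm outside the image")
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValueError("zero-length scan line")
    step = step_um if step_um is not None else pixel_size_um / 2.0
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]

    tangent = (p1 - p0) / length
    normal = np.array([-tangent[1], tangent[0]])
    if width_um > 0:
        n_off = max(2, int(np.ceil(width_um / (pixel_size_um / 2.0))) + 1)
        offsets = np.linspace(-width_um / 2.0, width_um / 2.0, n_off)
    else:
        offsets = np.array([0.0])

    samples = np.empty((offsets.size, n))
    for i, off in enumerate(offsets):
        q = pts + off * normal[None, :]
        rows = q[:, 1] / pixel_size_um - 0.5
        cols = q[:, 0] / pixel_size_um - 0.5
        samples[i] = map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return LineScanProfile(
        positions_um=t * length, intensity=samples.mean(axis=0), width_um=width_um
    )


def classify_transverse_profile(
    profile: LineScanProfile, min_prominence: float = 0.2
) -> ProfileClass:
    """Classify a transverse profile by its count of prominent local maxima.

    ``min_prominence`` is relative to the profile's intensity range:
    0 peaks -> "none", 1 -> "single_peak", >= 2 -> "double_peak".
    """
    y = profile.intensity
    rng = float(np.ptp(y))
    if rng == 0:
        return "none"
    peaks, _ = find_peaks(y, prominence=min_prominence * rng)
    if peaks.size == 0:
        return "none"
    if peaks.size == 1:
        return "single_peak"
    return "double_peak"
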