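"""Synthetic epithelial-monolayer images with exact junction ground truth.

Forward model: seed cell centres in a rectangular field, tessellate with a
Voronoi diagram clipped to the field (by mirroring the seeds across each
edge), replace every cell-cell edge by a sinusoidal zigzag polyline with
controllable amplitude and wavelength, rasterize the polylines into a
fluorescence-like junction channel (line width, Gaussian PSF, background,
additive noise), and optionally render a myosin channel that is either
continuous along the junctions or decorated as two rows of puncta offset to
either side of the junction line.

The generator's polyline network *is* the ground truth: per-side path and
chord lengths, and the pooled zigzag index, are computed exactly from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from skimage.morphology import dilation, disk

from ..network import JunctionNetwork, Side, polyline_length

__all__ = ["MonolayerSpec", "SyntheticImage", "generate_monolayer"]

_TRUTH_SAMPLING_UM = 0.02  # polyline sampling step for zigzag sides

MyosinMode = Literal["none", "continuous", "two_row"]


@dataclass(frozen=True)
class MonolayerSpec:
    """Parameters of one synthetic monolayer render.

    All lengths are in µm; intensities are arbitrary units.
    """

    field_width_um: float = 80.0
    field_height_um: float = 80.0
    n_cells: int = 100
    pixel_size_um: float = 0.1
    tortuosity_amplitude_um: float = 0.5
    tortuosity_wavelength_um: float = 4.0
    junction_width_um: float = 0.3
    psf_sigma_um: float = 0.15
    background_level: float = 20.0
    junction_level: float = 200.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    max_amplitude_chord_fraction: float = 0.35
    myosin_mode: MyosinMode = "none"
    two_row_offset_um: float = 0.5
    puncta_spacing_um: float = 0.8
    puncta_sigma_um: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "field_width_um",
            "field_height_um",
            "pixel_size_um",
            "tortuosity_wavelength_um",
            "junction_width_um",
            "two_row_offset_um",
            "puncta_spacing_um",
            "puncta_sigma_um",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tortuosity_amplitude_um < 0:
            raise ValueError("tortuosity_amplitude_um must be >= 0")
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.pixel_size_um > self.junction_width_um:
            raise ValueError("pixel_size_um must not exceed junction_width_um")
        if self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise_sd and psf_sigma_um must be >= 0")
        if self.myosin_mode not in ("none", "continuous", "two_row"):
            raise ValueError(f"unknown myosin_mode {self.myosin_mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered raster."""
        return (
            int(round(self.field_height_um / self.pixel_size_um)),
            int(round(self.field_width_um / self.pixel_size_um)),
        )


@dataclass
class SyntheticImage:
    """Rendered channels plus the ground-truth network that produced them."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    spec: MonolayerSpec
    truth: JunctionNetwork

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")


# --------------------------------------------------------------------- seeds


def _sample_cell_centres(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Best-candidate (approximate Poisson-disc) sampling of cell centres."""
    w, h = spec.field_width_um, spec.field_height_um
    pts = [rng.uniform((0, 0), (w, h))]
    k = 8  # candidates per accepted point
    for _ in range(spec.n_cells - 1):
        cands = rng.uniform((0, 0), (w, h), size=(k, 2))
        existing = np.asarray(pts)
        d = np.min(
            np.linalg.norm(cands[:, None, :] - existing[None, :, :], axis=2), axis=1
        )
        pts.append(cands[int(np.argmax(d))])
    return np.asarray(pts)


def _mirrored_voronoi(points: np.ndarray, w: float, h: float) -> Voronoi:
    """Voronoi diagram of the points plus their reflections across each field
    edge, which clips every original cell exactly to the field rectangle."""
    reflections = [
        points * [-1, 1],  # across x = 0
        points * [1, -1],  # across y = 0
        np.column_stack([2 * w - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * h - points[:, 1]]),
    ]
    return Voronoi(np.vstack([points] + reflections))


def _on_border(p: np.ndarray, w: float, h: float, tol: float = 1e-9) -> bool:
    return bool(
        p[0] <= tol or p[1] <= tol or p[0] >= w - tol or p[1] >= h - tol
    )


def _build_truth_network(spec: MonolayerSpec, rng: np.random.Generator) -> JunctionNetwork:
    w, h = spec.field_width_um, spec.field_height_um
    centres = _sample_cell_centres(spec, rng)
    vor = _mirrored_voronoi(centres, w, h)
    n = len(centres)

    # collect ridges between two original cells; ridges against mirrored
    # cells lie exactly on the field border and are dropped
    vertex_ids: dict[int, int] = {}
    vertices: dict[int, tuple[float, float]] = {}
    sides: dict[int, Side] = {}
    region_border: dict[int, bool] = {}

    def vid_for(vor_idx: int) -> int:
        if vor_idx not in vertex_ids:
            new = len(vertex_ids)
            vertex_ids[vor_idx] = new
            p = vor.vertices[vor_idx]
            vertices[new] = (float(p[0]), float(p[1]))
        return vertex_ids[vor_idx]

    side_id = 0
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p1 >= n or p2 >= n:
            if min(p1, p2) < n:  # original cell facing a mirrored cell
                region_border[min(p1, p2)] = True
            continue
        if -1 in verts or len(verts) != 2:
            continue  # cannot occur with mirrored seeds, defensive
        a, b = vor.vertices[verts[0]], vor.vertices[verts[1]]
        if np.linalg.norm(a - b) < 1e-9:
            continue
        border = _on_border(a, w, h, tol=1e-6) or _on_border(b, w, h, tol=1e-6)
        v1, v2 = vid_for(verts[0]), vid_for(verts[1])
        sides[side_id] = Side(
            id=side_id,
            v1=v1,
            v2=v2,
            polyline=np.array([vertices[v1], vertices[v2]]),
            border=border,
        )
        side_id += 1

    interior_cells = n - sum(1 for c in region_border.values() if c)
    if interior_cells < 4:
        raise ValueError(
            f"degenerate tessellation: only {interior_cells} interior cells "
            f"(need >= 4); increase n_cells or the field size"
        )

    network = JunctionNetwork(
        vertices=vertices, sides=sides, pixel_size_um=spec.pixel_size_um
    )
    _apply_zigzag(network, spec)
    return network


def _apply_zigzag(network: JunctionNetwork, spec: MonolayerSpec) -> None:
    """Replace each straight side by a sinusoidal perpendicular displacement.

    The displacement uses an integer number of half-waves, m = round(2L/λ)
    clamped to >= 1, so both endpoints stay pinned at the vertices.  To keep
    neighbouring junction bulges from fusing in the render, the amplitude on
    each edge is clamped to ``max_amplitude_chord_fraction`` of its chord;
    the ground-truth polylines always reflect the clamped geometry.
    """
    amp = spec.tortuosity_amplitude_um
    if amp == 0:
        return
    wavelength = spec.tortuosity_wavelength_um
    min_chord = min(
        (float(np.linalg.norm(s.polyline[-1] - s.polyline[0])) for s in network.sides.values()),
        default=np.inf,
    )
    if amp >= min_chord / 2:
        network.warnings.append(
            f"tortuosity amplitude {amp} µm >= half the shortest edge chord "
            f"({min_chord:.3g} µm); short edges are amplitude-clamped"
        )
    for s in network.sides.values():
        p0, p1 = s.polyline[0], s.polyline[-1]
        chord = p1 - p0
        length = float(np.linalg.norm(chord))
        if length < 1e-9:
            continue
        a = min(amp, spec.max_amplitude_chord_fraction * length)
        tangent = chord / length
        normal = np.array([-tangent[1], tangent[0]])
        m = max(1, int(round(2.0 * length / wavelength)))
        n_pts = max(2, int(np.ceil(length / _TRUTH_SAMPLING_UM)) + 1)
        t = np.linspace(0.0, 1.0, n_pts)
        disp = a * np.sin(m * np.pi * t)
        s.polyline = p0[None, :] + t[:, None] * chord[None, :] + disp[:, None] * normal[None, :]


# ----------------------------------------------------------------- rendering


def _um_to_px(points_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Map µm coordinates to fractional (row, col) pixel coordinates.

    Pixel centres sit at (i + 0.5) * pixel_size, so x_um -> col = x/ps - 0.5.
    """
    cols = points_um[:, 0] / pixel_size_um - 0.5
    rows = points_um[:, 1] / pixel_size_um - 0.5
    return np.column_stack([rows, cols])


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at ~`step` spacing along its arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        return points[:1]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(total / step)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.column_stack([x, y])


def _rasterize_centrelines(network: JunctionNetwork, spec: MonolayerSpec) -> np.ndarray:
    """Boolean raster of the (width-dilated) junction centrelines."""
    shape = spec.shape
    ps = spec.pixel_size_um
    mask = np.zeros(shape, dtype=bool)
    for s in network.sides.values():
        dense = _resample_polyline(s.polyline, step=ps / 2.0)
        rc = np.rint(_um_to_px(dense, ps)).astype(int)
        rc[:, 0] = np.clip(rc[:, 0], 0, shape[0] - 1)
        rc[:, 1] = np.clip(rc[:, 1], 0, shape[1] - 1)
        mask[rc[:, 0], rc[:, 1]] = True
    radius_px = int(round(spec.junction_width_um / 2.0 / ps))
    if radius_px >= 1:
        mask = dilation(mask, disk(radius_px))
    return mask


def _finish_channel(
    structure: np.ndarray, spec: MonolayerSpec, rng: np.random.Generator
) -> np.ndarray:
    """PSF blur + background + noise, clipped at zero."""
    img = structure.astype(float)
    if spec.psf_sigma_um > 0:
        img = gaussian_filter(img, sigma=spec.psf_sigma_um / spec.pixel_size_um)
    img = img + spec.background_level
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, None)


def _render_junction_channel(
    network: JunctionNetwork, spec: MonolayerSpec, rng: np.random.Generator
) -> np.ndarray:
    mask = _rasterize_centrelines(network, spec)
    return _finish_channel(mask * spec.junction_level, spec, rng)


def _puncta_positions(network: JunctionNetwork, spec: MonolayerSpec) -> np.ndarray:
    """Centres (µm) of the two punctum rows flanking every junction side."""
    out = []
    for s in network.sides.values():
        dense = _resample_polyline(s.polyline, step=spec.puncta_spacing_um)
        if dense.shape[0] < 2:
            continue
        tangents = np.gradient(dense, axis=0)
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        tangents = tangents / norms
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        out.append(dense + spec.two_row_offset_um * normals)
        out.append(dense - spec.two_row_offset_um * normals)
    if not out:
        return np.empty((0, 2))
    return np.vstack(out)


def _render_myosin_channel(
    network: JunctionNetwork, spec: MonolayerSpec, rng: np.random.Generator
) -> np.ndarray:
    shape = spec.shape
    ps = spec.pixel_size_um
    if spec.myosin_mode == "continuous":
        mask = _rasterize_centrelines(network, spec)
        return _finish_channel(mask * spec.junction_level, spec, rng)
    # two_row: Gaussian puncta at +/- offset perpendicular to the polylines
    impulses = np.zeros(shape, dtype=float)
    pos = _puncta_positions(network, spec)
    if pos.size:
        rc = np.rint(_um_to_px(pos, ps)).astype(int)
        keep = (
            (rc[:, 0] >= 0)
            & (rc[:, 0] < shape[0])
            & (rc[:, 1] >= 0)
            & (rc[:, 1] < shape[1])
        )
        rc = rc[keep]
        np.add.at(impulses, (rc[:, 0], rc[:, 1]), 1.0)
    blobs = gaussian_filter(impulses, sigma=spec.puncta_sigma_um / ps)
    peak = blobs.max()
    if peak > 0:
        blobs = blobs * (spec.junction_level / peak)
    return _finish_channel(blobs, spec, rng)


# ---------------------------------------------------------------- public API


def generate_truth_network(spec: MonolayerSpec) -> JunctionNetwork:
    """Build only the ground-truth network (no rasterization).

    Uses the same RNG stream prefix as :func:`generate_monolayer`, so the
    returned network is identical to the one attached to the full render.
    """
    rng = np.random.default_rng(spec.seed)
    return _build_truth_network(spec, rng)


def amplitude_for_truth_index(
    spec: MonolayerSpec,
    target_index: float,
    max_amplitude_um: float = 6.0,
    tol: float = 1e-3,
) -> float:
    """Solve for the tortuosity amplitude whose pooled ground-truth zigzag
    index (over non-border sides) equals ``target_index``, by bisection.

    The pooled truth index is non-decreasing in amplitude at fixed seed and
    wavelength, which makes bisection valid.
    """
    from ..network import truth_zigzag_index

    if target_index < 1.0:
        raise ValueError("target_index must be >= 1")
    if target_index == 1.0:
        return 0.0

    def truth_at(amp: float) -> float:
        net = generate_truth_network(replace(spec, tortuosity_amplitude_um=amp))
        return truth_zigzag_index(net)

    lo, hi = 0.0, max_amplitude_um
    if truth_at(hi) < target_index:
        raise ValueError(
            f"target index {target_index} unreachable below amplitude {max_amplitude_um} µm "
            f"(chord-fraction clamp limits attainable tortuosity)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if truth_at(mid) < target_index:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_monolayer(spec: MonolayerSpec) -> SyntheticImage:
    """Render a synthetic monolayer and return it with its truth network.

    Deterministic: the same spec (including seed) yields bit-identical
    channels and an identical truth network.
    """
    rng = np.random.default_rng(spec.seed)
    network = _build_truth_network(spec, rng)
    channels = {"junction": _render_junction_channel(network, spec, rng)}
    if spec.myosin_mode != "none":
        channels["myosin"] = _render_myosin_channel(network, spec, rng)
    return SyntheticImage(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        spec=spec,
        truth=network,
    )
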