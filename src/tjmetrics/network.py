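"""Planar junction networks: tricellular vertices joined by polyline sides.

Coordinates are in micrometres with the image convention: origin at the
top-left corner, x increasing rightward, y increasing downward.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Side",
    "JunctionNetwork",
    "EdgeMorphometry",
    "measure_edge",
    "polyline_length",
]


def _segment_lengths(pts: np.ndarray) -> np.ndarray:
    d = np.diff(pts, axis=0)
    return np.sqrt((d * d).sum(axis=1))


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an ordered polyline, summing consecutive distances."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (n >= 2, 2) array")
    return float(_segment_lengths(pts).sum())


@dataclass
class Side:
    """One junctional segment between two vertices.

    ``polyline`` is an ordered (n, 2) array of (x, y) points in µm whose
    first/last points coincide with the coordinates of vertices ``v1``/``v2``.
    ``border`` flags sides clipped by or touching the field border.
    """

    id: int
    v1: int
    v2: int
    polyline: np.ndarray
    border: bool = False

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise ValueError(f"side {self.id}: polyline needs >= 2 points")


@dataclass
class JunctionNetwork:
    """Graph of junction vertices and polyline sides, all in µm.

    ``pixel_size_um`` records the provenance raster resolution (may be None
    for purely geometric networks).
    """

    vertices: dict[int, tuple[float, float]]
    sides: dict[int, Side]
    pixel_size_um: float | None = None
    warnings: list[str] = field(default_factory=list)

    def validate(self, atol_um: float = 1e-6) -> None:
        """Check endpoint consistency between polylines and vertices."""
        for side in self.sides.values():
            for vid, pt in ((side.v1, side.polyline[0]), (side.v2, side.polyline[-1])):
                vx, vy = self.vertices[vid]
                if abs(pt[0] - vx) > atol_um or abs(pt[1] - vy) > atol_um:
                    raise ValueError(
                        f"side {side.id}: polyline endpoint {tuple(pt)} does not "
                        f"match vertex {vid} at {(vx, vy)}"
                    )

    def degree(self) -> dict[int, int]:
        deg: dict[int, int] = {vid: 0 for vid in self.vertices}
        for side in self.sides.values():
            deg[side.v1] += 1
            deg[side.v2] += 1
        return deg

    def interior_sides(self) -> list[Side]:
        """Sides not flagged as border sides."""
        return [s for s in self.sides.values() if not s.border]

    # ------------------------------------------------------------------ io

    def to_json(self) -> str:
        doc = {
            "pixel_size_um": self.pixel_size_um,
            "vertices": [
                {"id": vid, "x_um": x, "y_um": y}
                for vid, (x, y) in sorted(self.vertices.items())
            ],
            "sides": [
                {
                    "id": s.id,
                    "v1": s.v1,
                    "v2": s.v2,
                    "polyline": [[float(x), float(y)] for x, y in s.polyline],
                    "border": bool(s.border),
                }
                for s in sorted(self.sides.values(), key=lambda s: s.id)
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "JunctionNetwork":
        doc = json.loads(text)
        vertices = {v["id"]: (float(v["x_um"]), float(v["y_um"])) for v in doc["vertices"]}
        sides = {
            s["id"]: Side(
                id=s["id"],
                v1=s["v1"],
                v2=s["v2"],
                polyline=np.asarray(s["polyline"], dtype=float),
                border=bool(s["border"]),
            )
            for s in doc["sides"]
        }
        return cls(vertices=vertices, sides=sides, pixel_size_um=doc.get("pixel_size_um"))


@dataclass(frozen=True)
class EdgeMorphometry:
    """Per-side path length (L_TJ) and straight chord length (L_St), in µm."""

    side_id: int
    L_TJ_um: float
    L_St_um: float

    @property
    def ratio(self) -> float:
        return self.L_TJ_um / self.L_St_um


def measure_edge(side: Side, min_chord_um: float = 1e-9) -> EdgeMorphometry | None:
    """Measure one side: path length along the polyline and vertex-to-vertex chord.

    Returns None (and logs the reason) for degenerate sides whose two
    vertices coincide, which have no defined chord.
    """
    l_tj = polyline_length(side.polyline)
    # same arithmetic path as the arc length so straight sides give an
    # exactly-1 ratio
    l_st = float(_segment_lengths(side.polyline[[0, -1]])[0])
    if l_st <= min_chord_um:
        logger.info("side %d excluded: coincident vertices (L_St=%.3g)", side.id, l_st)
        return None
    return EdgeMorphometry(side_id=side.id, L_TJ_um=l_tj, L_St_um=l_st)


def measure_sides(sides: Iterable[Side]) -> dict[int, EdgeMorphometry]:
    """Measure every non-degenerate side, keyed by side id."""
    out: dict[int, EdgeMorphometry] = {}
    for side in sides:
        m = measure_edge(side)
        if m is not None:
            out[side.id] = m
    return out


def truth_zigzag_index(network: JunctionNetwork, include_border: bool = False) -> float:
    """Exact pooled zigzag index of a network: sum(L_TJ) / sum(L_St)."""
    sides = network.sides.values() if include_border else network.interior_sides()
    measured = measure_sides(sides)
    if not measured:
        raise ValueError("network has no measurable sides")
    num = sum(m.L_TJ_um for m in measured.values())
    den = sum(m.L_St_um for m in measured.values())
    return num / den
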