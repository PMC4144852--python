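"""Windowed zigzag-index morphometry.

The zigzag index of a set of junction sides is the ratio of sums
sum(L_TJ) / sum(L_St) — traced path length over vertex-to-vertex chord
length — computed over all sides whose two vertices fall inside a sampling
window. Windows are axis-aligned squares of fixed area placed uniformly at
random inside the field; border-flagged sides are never eligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..network import EdgeMorphometry, JunctionNetwork, measure_sides

__all__ = [
    "Window",
    "ZigzagIndex",
    "CloneSummary",
    "sample_windows",
    "compute_zigzag_index",
    "clone_zigzag_summary",
]

DEFAULT_WINDOW_AREA_UM2 = 840.0
DEFAULT_N_WINDOWS = 5


@dataclass(frozen=True)
class Window:
    """Axis-aligned square sampling window, in µm."""

    x_um: float
    y_um: float
    side_um: float

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_um <= x <= self.x_um + self.side_um
            and self.y_um <= y <= self.y_um + self.side_um
        )


@dataclass(frozen=True)
class ZigzagIndex:
    """Pooled ratio-of-sums statistic for one window's side set."""

    value: float
    n_sides: int
    window: Window | None = None

    def __post_init__(self) -> None:
        if self.n_sides < 1:
            raise ValueError("n_sides must be >= 1")


@dataclass(frozen=True)
class CloneSummary:
    """Mean +/- standard error of per-sample zigzag values across samples."""

    sample_values: tuple[float, ...]
    mean: float
    se: float | None  # None when n == 1
    n: int


def _eligible_sides(network: JunctionNetwork) -> list[int]:
    return [s.id for s in network.sides.values() if not s.border]


def sample_windows(
    network: JunctionNetwork,
    field_size_um: tuple[float, float],
    window_area_um2: float = DEFAULT_WINDOW_AREA_UM2,
    n_windows: int = DEFAULT_N_WINDOWS,
    seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> tuple[list[set[int]], list[Window]]:
    """Place square windows uniformly at random; return side-ID sets.

    A side belongs to a window iff both of its vertices lie inside the
    window. Windows containing zero eligible sides are re-drawn, up to
    ``max_retries`` attempts each. Windows may overlap each other.
    """
    if not _eligible_sides(network):
        raise ValueError("network has no eligible (non-border) sides")
    w_field, h_field = field_size_um
    side_len = float(np.sqrt(window_area_um2))
    if side_len > w_field or side_len > h_field:
        raise ValueError(
            f"window side {side_len:.1f} µm exceeds the field {w_field}x{h_field} µm"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    side_sets: list[set[int]] = []
    windows: list[Window] = []
    for _ in range(n_windows):
        for _attempt in range(max_retries):
            x0 = rng.uniform(0.0, w_field - side_len)
            y0 = rng.uniform(0.0, h_field - side_len)
            win = Window(x_um=x0, y_um=y0, side_um=side_len)
            ids = {
                s.id
                for s in network.sides.values()
                if not s.border
                and win.contains(*network.vertices[s.v1])
                and win.contains(*network.vertices[s.v2])
            }
            if ids:
                side_sets.append(ids)
                windows.append(win)
                break
        else:
            raise ValueError(
                f"could not place a non-empty {side_len:.1f} µm window "
                f"after {max_retries} attempts"
            )
    return side_sets, windows


def compute_zigzag_index(
    side_ids: set[int] | list[int],
    morphometry: dict[int, EdgeMorphometry],
    window: Window | None = None,
) -> ZigzagIndex:
    """Ratio of sums over a side set: sum(L_TJ) / sum(L_St).

    Note this is deliberately *not* the mean of per-side ratios.
    """
    # summation in sorted-id order so the result is bit-identical under
    # any permutation of the input side set
    ids = sorted(i for i in side_ids if i in morphometry)
    if not ids:
        raise ValueError("empty side set (or no side has morphometry)")
    num = sum(morphometry[i].L_TJ_um for i in ids)
    den = sum(morphometry[i].L_St_um for i in ids)
    return ZigzagIndex(value=num / den, n_sides=len(ids), window=window)


def network_zigzag_index(network: JunctionNetwork) -> ZigzagIndex:
    """Pooled index over all eligible (non-border) sides of a network."""
    morph = measure_sides(network.interior_sides())
    return compute_zigzag_index(set(morph), morph)


def clone_zigzag_summary(per_sample_window_indices: list[list[float]]) -> CloneSummary:
    """Aggregate window indices -> per-sample means -> clone mean +/- SE.

    Each inner list holds the window index values of one sample; the clone
    statistic is the mean across sample means, with the standard error over
    samples (undefined for a single sample).
    """
    if not per_sample_window_indices:
        raise ValueError("need at least one sample")
    sample_values = []
    for i, windows in enumerate(per_sample_window_indices):
        if not windows:
            raise ValueError(f"sample {i} has no window indices")
        sample_values.append(float(np.mean(windows)))
    n = len(sample_values)
    mean = float(np.mean(sample_values))
    se = float(np.std(sample_values, ddof=1) / np.sqrt(n)) if n > 1 else None
    return CloneSummary(sample_values=tuple(sample_values), mean=mean, se=se, n=n)
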