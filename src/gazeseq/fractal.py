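"""Box-counting fractal dimension of gaze scanpaths.

The trajectory (raw gaze samples connected in time order) is rasterized
onto a square power-of-two occupancy grid, aspect ratio preserved; box
counts N(eps) are taken over aligned, non-overlapping dyadic blocks, and
the dimension is the OLS slope of log N(eps) versus log(1/eps) over the
non-saturated scale range.

Rasterization rule: a cell is occupied when it contains a sample point
or when its center lies within half a cell side of any segment between
consecutive samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyScanpathError, InsufficientScalesError

DEFAULT_GRID_SIZE = 512


@dataclass
class OccupancyGrid:
    size: int
    cells: np.ndarray  # (size, size) bool, [row, col]

    def __post_init__(self) -> None:
        if self.size < 4 or (self.size & (self.size - 1)) != 0:
            raise ValueError("grid size must be a power of two >= 4")
        if self.cells.shape != (self.size, self.size):
            raise ValueError("cell array shape must match grid size")

    @property
    def n_occupied(self) -> int:
        return int(self.cells.sum())


@dataclass
class BoxCountCurve:
    scales: np.ndarray
    counts: np.ndarray
    n_occupied: int | None = None


@dataclass
class FDResult:
    fd: float
    r2: float
    scales_used: tuple[int, ...]


def default_scales(grid_size: int) -> list[int]:
    """Dyadic scales 2, 4, ..., G/4 (largest scales excluded)."""
    scales = []
    eps = 2
    while eps <= grid_size // 4:
        scales.append(eps)
        eps *= 2
    return scales


def _segment_distance(cx, cy, x0, y0, x1, y1):
    dx, dy = x1 - x0, y1 - y0
    length2 = dx * dx + dy * dy
    if length2 == 0.0:
        return np.hypot(cx - x0, cy - y0)
    tproj = np.clip(((cx - x0) * dx + (cy - y0) * dy) / length2, 0.0, 1.0)
    return np.hypot(cx - (x0 + tproj * dx), cy - (y0 + tproj * dy))


_NEIGHBOR_OFFSETS = np.array(
    [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)], dtype=int
)


def _mark_polyline(cells: np.ndarray, u: np.ndarray, v: np.ndarray) -> None:
    """Occupy every cell whose center lies within 0.5 of any segment.

    Candidate cells are gathered from 3x3 neighborhoods of points sampled
    along each segment at <= 0.5-cell spacing, which provably covers the
    target set; the exact point-to-segment distance predicate then
    filters them.  Fully vectorized across all segments.
    """
    size = cells.shape[0]
    x0, y0 = u[:-1], v[:-1]
    dx, dy = np.diff(u), np.diff(v)
    length = np.hypot(dx, dy)
    n_steps = np.maximum(1, np.ceil(length / 0.5).astype(int))
    n_pts = n_steps + 1

    seg_id = np.repeat(np.arange(len(dx)), n_pts)
    offsets = np.concatenate([[0], np.cumsum(n_pts)[:-1]])
    within = np.arange(n_pts.sum()) - offsets[seg_id]
    frac = within / n_steps[seg_id]
    px = x0[seg_id] + frac * dx[seg_id]
    py = y0[seg_id] + frac * dy[seg_id]
    base_c = np.floor(px).astype(int)
    base_r = np.floor(py).astype(int)

    sx0, sy0 = x0[seg_id], y0[seg_id]
    sdx, sdy = dx[seg_id], dy[seg_id]
    slen2 = np.maximum(sdx * sdx + sdy * sdy, 1e-300)
    for di, dj in _NEIGHBOR_OFFSETS:
        r = base_r + di
        c = base_c + dj
        cx, cy = c + 0.5, r + 0.5
        tproj = np.clip(((cx - sx0) * sdx + (cy - sy0) * sdy) / slen2, 0.0, 1.0)
        dist = np.hypot(cx - (sx0 + tproj * sdx), cy - (sy0 + tproj * sdy))
        hit = (dist <= 0.5 + 1e-9) & (r >= 0) & (r < size) & (c >= 0) & (c < size)
        cells[r[hit], c[hit]] = True


def rasterize_scanpath(stream, grid_size: int = DEFAULT_GRID_SIZE, frame=None) -> OccupancyGrid:
    """Rasterize a scanpath onto an occupancy grid.

    ``stream`` is a GazeStream (global coordinates) or an ``(x, y)``
    pair of arrays.  ``frame`` gives the ``(width, height)`` of the
    coordinate frame; when omitted the data bounding box is used.  One
    isotropic scale factor maps the frame into the grid (letterboxing),
    so aspect ratio is preserved.
    """
    if hasattr(stream, "x"):
        x = np.asarray(stream.x, dtype=float)
        y = np.asarray(stream.y, dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in stream)
    if len(x) == 0:
        raise EmptyScanpathError("cannot rasterize an empty scanpath")
    if grid_size < 4 or (grid_size & (grid_size - 1)) != 0:
        raise ValueError("grid_size must be a power of two >= 4")

    if frame is not None:
        width, height = float(frame[0]), float(frame[1])
        x0 = y0 = 0.0
    else:
        x0, y0 = float(x.min()), float(y.min())
        width = max(float(x.max()) - x0, 1e-9)
        height = max(float(y.max()) - y0, 1e-9)
    scale = grid_size / max(width, height)
    u = (x - x0) * scale
    v = (y - y0) * scale

    cells = np.zeros((grid_size, grid_size), dtype=bool)
    rows = np.clip(np.floor(v).astype(int), 0, grid_size - 1)
    cols = np.clip(np.floor(u).astype(int), 0, grid_size - 1)
    cells[rows, cols] = True
    if len(u) > 1:
        _mark_polyline(cells, u, v)
    return OccupancyGrid(size=grid_size, cells=cells)


def box_count(grid: OccupancyGrid, scales=None) -> BoxCountCurve:
    """Count occupied eps x eps aligned blocks for each scale."""
    if grid.n_occupied < 1:
        raise ValueError("grid has no occupied cells")
    if scales is None:
        scales = default_scales(grid.size)
    scales = [int(s) for s in scales]
    if sorted(set(scales)) != scales:
        raise ValueError("scales must be strictly increasing")
    for eps in scales:
        if eps < 1 or grid.size % eps != 0:
            raise ValueError(f"scale {eps} does not divide grid size {grid.size}")
    counts = []
    for eps in scales:
        blocks = grid.cells.reshape(grid.size // eps, eps, grid.size // eps, eps)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return BoxCountCurve(
        scales=np.array(scales), counts=np.array(counts), n_occupied=grid.n_occupied
    )


def _usable_mask(counts: np.ndarray, n_occupied: int | None) -> np.ndarray:
    usable = np.ones(len(counts), dtype=bool)
    ones = np.flatnonzero(counts == 1)
    if len(ones) > 1:
        usable[ones[1:]] = False  # bottom saturation: keep first N == 1 only
    if n_occupied is not None:
        usable &= counts != n_occupied  # top saturation: no refinement left
    return usable


def fractal_dimension(curve: BoxCountCurve) -> FDResult:
    """OLS slope of log N(eps) vs log(1/eps) over usable scales."""
    scales = np.asarray(curve.scales, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if np.all(counts == 1):
        # degenerate point-like set: zero-dimensional by definition
        return FDResult(fd=0.0, r2=1.0, scales_used=tuple(int(s) for s in curve.scales))
    usable = _usable_mask(counts.astype(int), curve.n_occupied)
    if usable.sum() < 3:
        raise InsufficientScalesError(
            f"only {int(usable.sum())} usable scales after saturation filtering; need >= 3"
        )
    xs = np.log(1.0 / scales[usable])
    ys = np.log(counts[usable])
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    ss_res = float(((ys - fitted) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FDResult(
        fd=float(slope),
        r2=float(r2),
        scales_used=tuple(int(s) for s in scales[usable]),
    )


def fd_of_stream(stream, grid_size: int = DEFAULT_GRID_SIZE, frame=None, scales=None) -> FDResult:
    """Convenience: rasterize, box-count and fit in one call."""
    grid = rasterize_scanpath(stream, grid_size=grid_size, frame=frame)
    return fractal_dimension(box_count(grid, scales=scales))


def fd_table(entries, grid_size: int = DEFAULT_GRID_SIZE, frame=None) -> pd.DataFrame:
    """FD per reading for ``(reader_id, case_id, stream)`` entries."""
    rows = []
    for reader_id, case_id, stream in entries:
        result = fd_of_stream(stream, grid_size=grid_size, frame=frame)
        rows.append(
            {
                "reader_id": reader_id,
                "case_id": case_id,
                "fd": result.fd,
                "r2": result.r2,
                "n_scales": len(result.scales_used),
            }
        )
    return pd.DataFrame(rows, columns=["reader_id", "case_id", "fd", "r2", "n_scales"])
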