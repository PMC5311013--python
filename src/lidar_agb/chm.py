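"""Canopy height model: per-cell maximum rasterization and gap interpolation.

The CHM is a 1 m grid holding, in each cell, the height of the highest
return that fell inside it.  Sparse clouds leave many cells empty; empty
cells inside the convex hull of the retained per-cell maxima are filled by
interpolating over the Delaunay triangulation of those maxima (at their
true return positions, not cell centres).  The interpolation contract is
that constant fields are reproduced exactly and planar fields to 1e-6
inside the hull; cells outside the hull stay nodata and are excluded from
metrics rather than extrapolated.

The same 10 structure metrics are then derived from the pixel heights.
Unlike the echo model, the CHM height statistics use *all* valid pixels
(no 2 m canopy cut): each pixel already represents the top surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .metrics import (DEFAULT_CANOPY_THRESHOLD, MetricVector, Waveform,
                      area_under_canopy_waveform, height_statistics)
from .pointcloud import NormalizedPointCloud, PlotGeometry

__all__ = [
    "CELL_DIRECT", "CELL_INTERPOLATED", "CELL_NODATA",
    "ChmRaster", "rasterize_max_height", "interpolate_empty_cells",
    "compute_chm_metrics", "write_chm_asc", "read_chm_asc",
]

CELL_NODATA = 0
CELL_DIRECT = 1
CELL_INTERPOLATED = 2


@dataclass
class ChmRaster:
    """1 m (by default) grid of maximum return heights.

    ``status`` distinguishes cells observed directly, cells filled by
    interpolation, and nodata cells (empty outside the hull, or outside the
    plot footprint).  ``source_x/y/h`` register the per-cell argmax returns
    used to build the grid — they are the generators for gap interpolation.
    """

    origin_x: float
    origin_y: float
    resolution: float
    heights: np.ndarray          # (ny, nx), NaN where nodata
    status: np.ndarray           # (ny, nx) of CELL_* codes
    source_x: np.ndarray
    source_y: np.ndarray
    source_h: np.ndarray
    in_plot: np.ndarray | None = None  # cells whose centre lies in the plot

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("CHM resolution must be positive")
        if self.in_plot is None:
            self.in_plot = np.ones_like(self.status, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def valid_heights(self) -> np.ndarray:
        """Heights of all non-nodata in-plot pixels (direct + interpolated)."""
        mask = (self.status != CELL_NODATA) & self.in_plot
        return self.heights[mask]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        xs = self.origin_x + (np.arange(nx) + 0.5) * self.resolution
        ys = self.origin_y + (np.arange(ny) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)


def rasterize_max_height(cloud: NormalizedPointCloud, plot: PlotGeometry,
                         resolution: float = 1.0) -> ChmRaster:
    """Grid the plot bounding box and keep the highest return per cell.

    The grid origin snaps to the bounding-box lower-left corner.  Cells
    whose centre lies outside the plot footprint (edge cells of circular
    plots) are marked nodata and never filled.
    """
    if resolution <= 0:
        raise ValueError("CHM resolution must be positive")
    xmin, ymin, xmax, ymax = plot.bounding_box()
    nx = max(1, int(np.ceil((xmax - xmin) / resolution - 1e-9)))
    ny = max(1, int(np.ceil((ymax - ymin) / resolution - 1e-9)))
    heights = np.full((ny, nx), np.nan)
    status = np.full((ny, nx), CELL_NODATA, dtype=np.int8)
    cx, cy = np.meshgrid(xmin + (np.arange(nx) + 0.5) * resolution,
                         ymin + (np.arange(ny) + 0.5) * resolution)
    in_plot = plot.contains(cx.ravel(), cy.ravel()).reshape(ny, nx)

    if len(cloud):
        j = np.floor((cloud.x - xmin) / resolution).astype(int)
        i = np.floor((cloud.y - ymin) / resolution).astype(int)
        # boundary returns at the top/right edge belong to the last cell
        j = np.clip(j, 0, nx - 1)
        i = np.clip(i, 0, ny - 1)
        flat = i * nx + j
        # ascending height sort: the last write per cell is the maximum
        order = np.argsort(cloud.h, kind="stable")
        hf = heights.ravel()
        hf[flat[order]] = cloud.h[order]
        argmax = np.full(ny * nx, -1, dtype=np.int64)
        argmax[flat[order]] = order
        filled = argmax >= 0
        status.ravel()[filled] = CELL_DIRECT
        src = argmax[filled]
        source_x, source_y, source_h = cloud.x[src], cloud.y[src], cloud.h[src]
    else:
        source_x = source_y = source_h = np.empty(0)

    return ChmRaster(xmin, ymin, resolution, heights, status,
                     source_x, source_y, source_h, in_plot)


def interpolate_empty_cells(chm: ChmRaster) -> ChmRaster:
    """Fill empty in-plot cells from the Delaunay triangulation of the
    registered maxima; cells outside the convex hull stay nodata.

    With fewer than 3 non-collinear generators the raster is returned
    unchanged with a warning.  Interpolating an already-complete raster is a
    no-op (idempotence).
    """
    empty = (chm.status == CELL_NODATA) & chm.in_plot
    if not empty.any():
        return chm
    if chm.source_h.size < 3:
        warnings.warn("fewer than 3 direct cells; CHM gaps left unfilled",
                      stacklevel=2)
        return chm
    try:
        interp = LinearNDInterpolator(
            np.column_stack([chm.source_x, chm.source_y]), chm.source_h)
    except QhullError:
        warnings.warn("degenerate (collinear) direct cells; CHM gaps left "
                      "unfilled", stacklevel=2)
        return chm
    cx, cy = chm.cell_centers()
    est = interp(cx[empty], cy[empty])
    heights = chm.heights.copy()
    status = chm.status.copy()
    inside = np.isfinite(est)
    rows, cols = np.nonzero(empty)
    heights[rows[inside], cols[inside]] = est[inside]
    status[rows[inside], cols[inside]] = CELL_INTERPOLATED
    return ChmRaster(chm.origin_x, chm.origin_y, chm.resolution, heights,
                     status, chm.source_x, chm.source_y, chm.source_h,
                     chm.in_plot)


def compute_chm_metrics(chm: ChmRaster,
                        fc_threshold: float = DEFAULT_CANOPY_THRESHOLD,
                        bin_width: float = 0.5, **tags) -> MetricVector:
    """The 10 metrics from CHM pixel heights (all valid pixels, no canopy cut).

    FC is the fraction of valid pixels at or above ``fc_threshold``; the
    pseudo-waveform for AUCW is built over all valid pixel heights with the
    same binning as the echo model, starting at the lowest pixel.
    """
    h = chm.valid_heights()
    stats = height_statistics(h)
    tags.setdefault("data_model", "chm")
    if h.size == 0:
        return MetricVector(AUCW=0.0, FC=0.0, **stats, **tags)
    fc = float(np.count_nonzero(h >= fc_threshold)) / h.size
    lo = float(h.min())
    n_bins = max(1, int(np.ceil((h.max() - lo) / bin_width)))
    if lo + n_bins * bin_width <= h.max():
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(h, bins=edges)
    wf = Waveform(edges, counts / counts.sum(), bin_width)
    return MetricVector(AUCW=area_under_canopy_waveform(wf), FC=fc,
                        **stats, **tags)


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid)


def write_chm_asc(chm: ChmRaster, path: str | Path,
                  nodata: float = -9999.0) -> None:
    """Write the height grid as an ESRI ASCII raster (row 1 = northernmost)."""
    ny, nx = chm.shape
    grid = np.where(np.isfinite(chm.heights), chm.heights, nodata)
    with open(path, "w") as f:
        f.write(f"ncols {nx}\nnrows {ny}\n"
                f"xllcorner {chm.origin_x}\nyllcorner {chm.origin_y}\n"
                f"cellsize {chm.resolution}\nNODATA_value {nodata}\n")
        np.savetxt(f, grid[::-1], fmt="%.4f")


def read_chm_asc(path: str | Path) -> ChmRaster:
    """Read an ESRI ASCII raster back into a (sourceless) ChmRaster."""
    header: dict[str, float] = {}
    with open(path) as f:
        for _ in range(6):
            key, value = f.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(f, ndmin=2)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    heights = np.where(grid == nodata, np.nan, grid)
    status = np.where(np.isfinite(heights), CELL_DIRECT, CELL_NODATA)
    e = np.empty(0)
    return ChmRaster(header["xllcorner"], header["yllcorner"],
                     header["cellsize"], heights, status.astype(np.int8),
                     e, e, e)
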