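"""Point-cloud containers, height normalization, plot clipping and thinning.

The central object is :class:`NormalizedPointCloud`: discrete LiDAR returns
carrying heights above ground.  Everything downstream (echo metrics, CHM
construction, the density experiment) consumes clouds that have been
normalized against a DEM and clipped to a field-plot footprint.

Coordinates are assumed to live in a single planar metric CRS; no
reprojection is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUND_CLASS",
    "VEGETATION_CLASS",
    "RawPointCloud",
    "NormalizedPointCloud",
    "PlotGeometry",
    "DemRaster",
    "read_point_cloud",
    "write_point_cloud_csv",
    "normalize_heights",
    "clip_to_plot",
    "thin_to_density",
    "point_density",
]

#: ASPRS-style classification codes used throughout.
GROUND_CLASS = 2
VEGETATION_CLASS = 5

M2_PER_HA = 10_000.0


@dataclass
class RawPointCloud:
    """Un-normalized returns: planimetric position and raw elevation."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray
    return_number: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.classification = np.asarray(self.classification, dtype=int)
        if self.return_number is None:
            self.return_number = np.ones(self.x.size, dtype=int)
        n = self.x.size
        if not (self.y.size == self.z.size == self.classification.size == n):
            raise ValueError("coordinate/attribute arrays must share one length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                      and np.isfinite(self.z).all()):
            raise ValueError("non-finite coordinates in point cloud")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class NormalizedPointCloud:
    """Returns with heights above ground, plus processing lineage.

    ``provenance`` records where the cloud came from and any thinning applied
    (seed and target density), so every experiment condition is re-runnable.
    """

    x: np.ndarray
    y: np.ndarray
    h: np.ndarray
    classification: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.classification = np.asarray(self.classification, dtype=int)
        if not (self.x.size == self.y.size == self.h.size == self.classification.size):
            raise ValueError("coordinate/attribute arrays must share one length")
        if self.h.size and not np.isfinite(self.h).all():
            raise ValueError("non-finite heights in normalized cloud")

    def __len__(self) -> int:
        return self.x.size

    def subset(self, index: np.ndarray, **extra_provenance) -> "NormalizedPointCloud":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return NormalizedPointCloud(
            self.x[index], self.y[index], self.h[index],
            self.classification[index], prov,
        )


@dataclass(frozen=True)
class PlotGeometry:
    """Circular or square field-plot footprint.

    ``dimension`` is the radius (circle) or side length (square) in metres;
    ``area_ha`` is derived and kept consistent with the shape.
    """

    center_x: float
    center_y: float
    shape: str  # "circle" | "square"
    dimension: float

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown plot shape {self.shape!r}")
        if self.dimension <= 0:
            raise ValueError("plot dimension must be positive")

    @property
    def area_m2(self) -> float:
        if self.shape == "circle":
            return math.pi * self.dimension**2
        return self.dimension**2

    @property
    def area_ha(self) -> float:
        return self.area_m2 / M2_PER_HA

    @classmethod
    def from_area(cls, center_x: float, center_y: float, shape: str,
                  area_ha: float) -> "PlotGeometry":
        """Back-compute the radius/side from a target area.

        A 0.09 ha circle gets radius sqrt(900/pi) = 16.93 m, the usual field
        convention for "0.09 ha (radius = 16.9 m)" plots.
        """
        area_m2 = area_ha * M2_PER_HA
        if shape == "circle":
            dim = math.sqrt(area_m2 / math.pi)
        elif shape == "square":
            dim = math.sqrt(area_m2)
        else:
            raise ValueError(f"unknown plot shape {shape!r}")
        return cls(center_x, center_y, shape, dim)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean membership; the boundary (equality) is inside (closed region)."""
        dx = np.asarray(x, dtype=float) - self.center_x
        dy = np.asarray(y, dtype=float) - self.center_y
        if self.shape == "circle":
            return dx * dx + dy * dy <= self.dimension**2
        half = self.dimension / 2.0
        return (np.abs(dx) <= half) & (np.abs(dy) <= half)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the footprint."""
        half = self.dimension if self.shape == "circle" else self.dimension / 2.0
        return (self.center_x - half, self.center_y - half,
                self.center_x + half, self.center_y + half)


@dataclass
class DemRaster:
    """Regular ground-elevation grid. ``grid[i, j]`` is the cell at
    ``x = origin_x + (j + 0.5) * resolution``, ``y = origin_y + (i + 0.5) * resolution``
    (row index increases with y)."""

    origin_x: float
    origin_y: float
    resolution: float
    grid: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("DEM resolution must be positive")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("DEM grid must be 2-D")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.grid.shape
        return (self.origin_x, self.origin_y,
                self.origin_x + nx * self.resolution,
                self.origin_y + ny * self.resolution)

    @classmethod
    def flat(cls, origin_x: float, origin_y: float, size_x: float, size_y: float,
             resolution: float = 1.0, elevation: float = 0.0) -> "DemRaster":
        nx = max(1, int(math.ceil(size_x / resolution)))
        ny = max(1, int(math.ceil(size_y / resolution)))
        return cls(origin_x, origin_y, resolution,
                   np.full((ny, nx), elevation, dtype=float))

    def sample(self, x: np.ndarray, y: np.ndarray,
               method: str = "bilinear") -> np.ndarray:
        """Ground elevation under (x, y) by bilinear (default) or nearest
        interpolation between cell centres; nodata cells propagate NaN.
        Coordinates beyond the outermost cell centres (but inside the grid
        extent) use nearest-edge extension."""
        from scipy.interpolate import RegularGridInterpolator

        ny, nx = self.grid.shape
        xc = self.origin_x + (np.arange(nx) + 0.5) * self.resolution
        yc = self.origin_y + (np.arange(ny) + 0.5) * self.resolution
        grid = np.where(self.grid == self.nodata, np.nan, self.grid)
        if nx == 1 and ny == 1:
            return np.full(np.asarray(x).shape, grid[0, 0])
        # clamp to the cell-centre hull: half-cell edge margin extends flat
        xq = np.clip(np.asarray(x, dtype=float), xc[0], xc[-1])
        yq = np.clip(np.asarray(y, dtype=float), yc[0], yc[-1])
        if ny == 1:
            interp = RegularGridInterpolator(
                (xc,), grid[0, :],
                method="linear" if method == "bilinear" else "nearest")
            return interp(xq[..., None] if xq.ndim == 0 else xq)
        if nx == 1:
            interp = RegularGridInterpolator(
                (yc,), grid[:, 0],
                method="linear" if method == "bilinear" else "nearest")
            return interp(yq)
        interp = RegularGridInterpolator(
            (yc, xc), grid,
            method="linear" if method == "bilinear" else "nearest")
        return interp(np.column_stack([np.atleast_1d(yq), np.atleast_1d(xq)]))


# ---------------------------------------------------------------------------
# I/O


def read_point_cloud(path: str | Path, format: str = "xyz-csv") -> RawPointCloud:
    """Read a point cloud from disk.

    ``xyz-csv`` is a header-required CSV dialect ``x,y,z,class`` (UTF-8,
    '.' decimal). ``las`` requires the optional ``laspy`` dependency.
    An empty file yields an empty cloud with a warning, not an exception.
    """
    path = Path(path)
    if format == "las":
        try:
            import laspy  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "LAS input requires the optional 'laspy' dependency "
                "(pip install lidar-agb[las]); alternatively convert to the "
                "x,y,z,class CSV dialect") from exc
        las = laspy.read(path)  # pragma: no cover
        return RawPointCloud(np.asarray(las.x), np.asarray(las.y),
                             np.asarray(las.z),
                             np.asarray(las.classification, dtype=int))
    if format != "xyz-csv":
        raise ValueError(f"unknown point-cloud format {format!r} "
                         "(expected 'las' or 'xyz-csv')")
    if path.stat().st_size == 0:
        warnings.warn(f"empty point-cloud file {path}", stacklevel=2)
        e = np.empty(0)
        return RawPointCloud(e, e, e, np.empty(0, dtype=int))
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty point-cloud file {path}", stacklevel=2)
        e = np.empty(0)
        return RawPointCloud(e, e, e, np.empty(0, dtype=int))
    required = {"x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: CSV point cloud must have header columns x,y,z[,class]; "
            f"got {list(df.columns)}")
    bad = df[["x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        first = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: malformed record at data row {first + 1}")
    cls = (df["class"].to_numpy(dtype=int) if "class" in df.columns
           else np.full(len(df), VEGETATION_CLASS))
    return RawPointCloud(df["x"].to_numpy(float), df["y"].to_numpy(float),
                         df["z"].to_numpy(float), cls)


def write_point_cloud_csv(cloud: RawPointCloud | NormalizedPointCloud,
                          path: str | Path) -> None:
    """Write the x,y,z,class CSV dialect (``z`` holds ``h`` for normalized clouds)."""
    z = cloud.z if isinstance(cloud, RawPointCloud) else cloud.h
    pd.DataFrame({"x": cloud.x, "y": cloud.y, "z": z,
                  "class": cloud.classification}).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Processing


def normalize_heights(cloud: RawPointCloud, dem: DemRaster,
                      method: str = "bilinear",
                      low_clamp: float = 0.5) -> NormalizedPointCloud:
    """Subtract DEM ground elevation: ``h = z - dem(x, y)``.

    Returns outside the DEM extent raise; returns over DEM nodata are dropped
    with a warning.  Slightly sub-ground heights in ``(-low_clamp, 0)`` are
    clamped to 0; anything below ``-low_clamp`` is dropped with a warning
    (sensor noise vs genuinely bad normalization).
    """
    if len(cloud) == 0:
        e = np.empty(0)
        return NormalizedPointCloud(e, e, e, np.empty(0, dtype=int),
                                    {"normalized": True})
    xmin, ymin, xmax, ymax = dem.extent
    outside = ((cloud.x < xmin) | (cloud.x > xmax)
               | (cloud.y < ymin) | (cloud.y > ymax))
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} returns fall outside the DEM extent "
            f"({xmin}, {ymin})-({xmax}, {ymax})")
    ground = dem.sample(cloud.x, cloud.y, method=method)
    keep = np.isfinite(ground)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} returns over DEM nodata",
                      stacklevel=2)
    h = cloud.z[keep] - ground[keep]
    x, y, cls = cloud.x[keep], cloud.y[keep], cloud.classification[keep]
    below = h < -low_clamp
    if below.any():
        warnings.warn(
            f"dropped {int(below.sum())} returns more than {low_clamp} m "
            "below ground", stacklevel=2)
        x, y, h, cls = x[~below], y[~below], h[~below], cls[~below]
    h = np.maximum(h, 0.0)  # clamp (-low_clamp, 0) to ground
    return NormalizedPointCloud(x, y, h, cls, {"normalized": True})


def clip_to_plot(cloud: NormalizedPointCloud,
                 plot: PlotGeometry) -> NormalizedPointCloud:
    """Retain returns inside the plot footprint (boundary inclusive)."""
    return cloud.subset(plot.contains(cloud.x, cloud.y),
                        plot=(plot.shape, plot.dimension,
                              plot.center_x, plot.center_y))


def thin_to_density(cloud: NormalizedPointCloud, plot: PlotGeometry,
                    target_density: float,
                    seed: int | np.random.SeedSequence) -> NormalizedPointCloud:
    """Randomly remove returns until the target density is reached.

    Keeps a uniform random subset (without replacement) of size
    ``round(target_density * area_m2)``.  If the cloud is already at or below
    the target the original is returned unchanged with a warning (thinning
    cannot up-sample).  Deterministic given the seed; lineage is recorded in
    the provenance.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    n_keep = int(np.round(target_density * plot.area_m2))
    if n_keep >= len(cloud):
        if n_keep > len(cloud):
            warnings.warn(
                f"target density {target_density} points/m2 needs {n_keep} "
                f"returns but only {len(cloud)} available; returning cloud "
                "unchanged", stacklevel=2)
        return replace(cloud)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(cloud), size=n_keep, replace=False)
    keep.sort()
    seed_repr = seed if isinstance(seed, int) else "seedsequence"
    return cloud.subset(keep, thinned_to=target_density, thin_seed=seed_repr)


def point_density(cloud: NormalizedPointCloud, plot: PlotGeometry) -> float:
    """Returns per square metre over the plot area (all classes counted)."""
    area = plot.area_m2
    if area <= 0:
        raise ValueError("plot area must be positive")
    return len(cloud) / area
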