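"""Synthetic forest stands, discrete-return point clouds and field AGB.

The generator exists so the whole pipeline — normalization, clipping,
thinning, echo and CHM metrics, the density/plot-size experiment and the
power-law AGB models — can be exercised end-to-end with known ground truth.
It emulates the statistical structure the analysis assumes rather than the
physics of a laser scanner:

* tree stems are a homogeneous Poisson process over a rectangular stand;
* each tree carries a paraboloid-of-revolution crown envelope between its
  crown base and its top;
* one return per simulated pulse, at a uniformly random planimetric
  position: a position under one or more crowns yields a canopy return at
  the local envelope height minus an exponential penetration offset (mean
  10% of crown depth, truncated at the crown base), so denser sampling
  raises the observed maximum — the mechanism behind the density effect;
  positions in gaps, or a ``ground_fraction`` share of pulses anywhere,
  yield ground returns at h = 0;
* per-tree "field" AGB follows a power law in a synthetic stem diameter
  with multiplicative lognormal noise, summed per plot and scaled to
  Mg/ha — the stand-in for field allometries.

The ground is flat at elevation 0 and a DEM of zeros is emitted alongside,
so height normalization is exercised but trivially invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import (GROUND_CLASS, VEGETATION_CLASS, DemRaster,
                         NormalizedPointCloud, PlotGeometry, RawPointCloud,
                         write_point_cloud_csv)

__all__ = ["StandConfig", "Tree", "StudyDataset", "simulate_stand",
           "sample_returns", "assign_field_agb", "generate_study",
           "write_study", "load_study"]


@dataclass
class StandConfig:
    """Parameters of one simulated stand and its LiDAR acquisition.

    Defaults describe a closed-canopy moist forest surveyed at high density:
    500 stems/ha above the census threshold, Weibull-distributed heights,
    crowns occupying the upper 60% of each tree, ~0.9 projected canopy
    cover, and 20 returns per m^2.
    """

    extent_x: float = 100.0           # m
    extent_y: float = 100.0           # m
    stem_density: float = 500.0       # trees per ha
    height_distribution: tuple = ("weibull", 2.2, 16.0)  # family, shape, scale (m)
    height_min: float = 3.0           # m, added to the Weibull draw
    crown_ratio: float = 0.6          # fraction of height occupied by crown
    crown_radius_intercept: float = 1.2  # m
    crown_radius_slope: float = 0.18     # m per m of height
    target_point_density: float = 20.0   # returns per m^2
    ground_fraction: float = 0.15     # pulses reaching ground anywhere
    penetration_fraction: float = 0.10  # mean offset as fraction of crown depth
    noise_sd_xy: float = 0.0          # m
    noise_sd_z: float = 0.05          # m
    edge_buffer: float = 10.0         # m of tree placement beyond the extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ValueError("stand extent must be positive")
        if self.stem_density <= 0:
            raise ValueError("stem density must be positive")
        if self.target_point_density <= 0:
            raise ValueError("point density must be positive")
        if not 0.0 <= self.ground_fraction <= 1.0:
            raise ValueError("ground_fraction must be in [0, 1]")
        if not 0.0 < self.crown_ratio <= 1.0:
            raise ValueError("crown_ratio must be in (0, 1]")

    @property
    def area_m2(self) -> float:
        return self.extent_x * self.extent_y

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0


@dataclass
class Tree:
    x: float
    y: float
    height: float
    crown_base: float
    crown_radius: float
    dbh_proxy: float  # cm, synthetic stem size driving the field allometry

    def __post_init__(self) -> None:
        if not 0.0 <= self.crown_base < self.height:
            raise ValueError("crown base must lie in [0, height)")
        if self.crown_radius <= 0:
            raise ValueError("crown radius must be positive")


@dataclass
class StudyDataset:
    """One synthetic study: plots, their clouds, field AGB and the truth block."""

    plots: list            # PlotGeometry per plot (the field geometry)
    plot_ids: list
    clouds: list           # NormalizedPointCloud per plot, original density
    field_agb: np.ndarray  # Mg/ha per plot
    truth: dict = field(default_factory=dict)
    configs: list = field(default_factory=list)
    dem: DemRaster | None = None

    def __post_init__(self) -> None:
        n = len(self.plots)
        if not (len(self.clouds) == n == len(self.plot_ids)
                == len(self.field_agb)):
            raise ValueError("one cloud, id and AGB value per plot required")
        self.field_agb = np.asarray(self.field_agb, dtype=float)
        if (self.field_agb <= 0).any():
            raise ValueError("field AGB must be positive")


def _draw_heights(rng: np.random.Generator, n: int, config: StandConfig) -> np.ndarray:
    family, *params = config.height_distribution
    if family == "weibull":
        shape, scale = params
        return config.height_min + scale * rng.weibull(shape, n)
    if family == "lognormal":
        mu, sigma = params
        return config.height_min + rng.lognormal(mu, sigma, n)
    raise ValueError(f"unknown height distribution family {family!r}")


def simulate_stand(config: StandConfig,
                   rng: np.random.Generator | None = None) -> list[Tree]:
    """Draw a stand: Poisson number of trees placed uniformly over the extent.

    The synthetic stem diameter follows a standard height-diameter shape
    (dbh ~ h^1.4) with lognormal scatter, so taller stands carry more AGB.

    Trees are placed over the extent expanded by ``edge_buffer`` on every
    side (the forest continues beyond the surveyed block), so crowns
    overhang the extent edges and returns near the boundary are not
    systematically sparser; the Poisson mean is density times the
    *buffered* area.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b = config.edge_buffer
    buffered_ha = ((config.extent_x + 2 * b) * (config.extent_y + 2 * b)
                   / 10_000.0)
    mean_count = config.stem_density * buffered_ha
    n = rng.poisson(mean_count)
    xs = rng.uniform(-b, config.extent_x + b, n)
    ys = rng.uniform(-b, config.extent_y + b, n)
    heights = _draw_heights(rng, n, config)
    dbh = 0.8 * heights**1.4 * np.exp(rng.normal(0.0, 0.15, n))
    trees = []
    for i in range(n):
        h = float(heights[i])
        trees.append(Tree(
            x=float(xs[i]), y=float(ys[i]), height=h,
            crown_base=h * (1.0 - config.crown_ratio),
            crown_radius=config.crown_radius_intercept
            + config.crown_radius_slope * h,
            dbh_proxy=float(dbh[i]),
        ))
    return trees


def _crown_envelope_heights(
        trees: list[Tree], px: np.ndarray, py: np.ndarray,
        k_neighbors: int = 16) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tallest crown envelope over each position, plus the crown depth and
    crown base of the tree providing it.  Positions under no crown get
    envelope 0, depth 0, base 0.

    The envelope of one tree is a paraboloid of revolution: apex at the tree
    top, descending to the crown base at the crown edge.
    """
    n_pos = px.size
    env = np.zeros(n_pos)
    depth = np.zeros(n_pos)
    base = np.zeros(n_pos)
    if not trees:
        return env, depth, base
    tx = np.array([t.x for t in trees])
    ty = np.array([t.y for t in trees])
    th = np.array([t.height for t in trees])
    tb = np.array([t.crown_base for t in trees])
    tr = np.array([t.crown_radius for t in trees])
    rmax = tr.max()
    tree_index = cKDTree(np.column_stack([tx, ty]))
    k = min(k_neighbors, len(trees))
    dist, idx = tree_index.query(np.column_stack([px, py]), k=k,
                                 distance_upper_bound=rmax)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    hit = dist < np.inf
    idx_safe = np.where(hit, idx, 0)
    r = np.where(hit, dist, np.inf)
    inside = r <= tr[idx_safe]
    frac = np.where(inside, r / tr[idx_safe], 1.0)
    cand = np.where(inside, tb[idx_safe]
                    + (th[idx_safe] - tb[idx_safe]) * (1.0 - frac**2), 0.0)
    best = cand.argmax(axis=1)
    rows = np.arange(n_pos)
    env = cand[rows, best]
    chosen = idx_safe[rows, best]
    covered = env > 0
    depth[covered] = (th[chosen] - tb[chosen])[covered]
    base[covered] = tb[chosen][covered]
    return env, depth, base


def sample_returns(trees: list[Tree], config: StandConfig,
                   rng: np.random.Generator | None = None) -> NormalizedPointCloud:
    """Simulate one acquisition: exactly round(density * area) returns.

    Positional jitter is added before the crown lookup; z-noise is a
    truncated normal (clipped at +-3 sd) so no return can sit more than
    3 * noise_sd_z below ground or above the tallest envelope by more than
    the same margin.  Canopy returns are classified 5, ground returns 2.
    An empty tree list yields an all-ground cloud.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = int(round(config.target_point_density * config.area_m2))
    px = rng.uniform(0.0, config.extent_x, n)
    py = rng.uniform(0.0, config.extent_y, n)
    if config.noise_sd_xy > 0:
        px = np.clip(px + rng.normal(0, config.noise_sd_xy, n), 0, config.extent_x)
        py = np.clip(py + rng.normal(0, config.noise_sd_xy, n), 0, config.extent_y)
    env, depth, base = _crown_envelope_heights(trees, px, py)
    to_ground = rng.random(n) < config.ground_fraction
    canopy = (env > 0) & ~to_ground
    h = np.zeros(n)
    if canopy.any():
        pen = rng.exponential(config.penetration_fraction * depth[canopy])
        h[canopy] = np.maximum(env[canopy] - pen, base[canopy])
    if config.noise_sd_z > 0:
        zn = np.clip(rng.normal(0.0, config.noise_sd_z, n),
                     -3 * config.noise_sd_z, 3 * config.noise_sd_z)
        h = h + zn
    h[~canopy] = np.maximum(h[~canopy], 0.0)  # ground returns stay at/above 0
    h = np.maximum(h, 0.0)
    cls = np.where(canopy, VEGETATION_CLASS, GROUND_CLASS)
    return NormalizedPointCloud(px, py, h, cls,
                                {"source": "synthetic",
                                 "target_density": config.target_point_density})


def assign_field_agb(trees_per_plot: list[list[Tree]],
                     plot_areas_ha: np.ndarray | list[float],
                     allometry: tuple[float, float] = (0.06, 2.4),
                     noise_sd: float = 0.3,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Plot AGB (Mg/ha) from the per-tree power-law allometry.

    tree_agb_kg = a * dbh^b * exp(eps), eps ~ N(0, noise_sd^2); plot AGB is
    the tree sum converted to Mg and divided by the plot area in ha.
    """
    a, b = allometry
    if a <= 0 or b <= 0:
        raise ValueError("allometry coefficients must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = np.empty(len(trees_per_plot))
    for i, (trees, area) in enumerate(zip(trees_per_plot, plot_areas_ha)):
        dbh = np.array([t.dbh_proxy for t in trees])
        eps = rng.normal(0.0, noise_sd, dbh.size) if noise_sd > 0 else 0.0
        agb_kg = a * dbh**b * np.exp(eps)
        out[i] = agb_kg.sum() / 1000.0 / area
    return out


def generate_study(n_plots: int = 100, seed: int = 0,
                   base_config: StandConfig | None = None,
                   field_plot_area_ha: float = 1.0,
                   field_plot_shape: str = "square",
                   height_scale_range: tuple[float, float] = (8.0, 25.0),
                   allometry: tuple[float, float] = (0.06, 2.4),
                   agb_noise_sd: float = 0.3) -> StudyDataset:
    """Simulate a whole study: independent 1 ha stands, one field plot each.

    Between-plot structure comes from varying the Weibull height scale per
    stand over ``height_scale_range``, giving the broad AGB–mean-height
    gradient the power-law models are fitted to.  Each plot's field geometry
    is centred on its stand.  All randomness derives from ``seed``; plot i
    uses the sub-stream (seed, i), so any single plot is re-runnable in
    isolation.
    """
    if base_config is None:
        base_config = StandConfig()
    rng_scales = np.random.default_rng(np.random.SeedSequence((seed, 982451653)))
    scales = rng_scales.uniform(*height_scale_range, n_plots)
    plots, ids, clouds, trees_per_plot, configs = [], [], [], [], []
    family, shape, _ = base_config.height_distribution
    for i in range(n_plots):
        cfg = StandConfig(
            **{**asdict(base_config),
               "height_distribution": (family, shape, float(scales[i])),
               "seed": seed})
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        trees = simulate_stand(cfg, rng)
        cloud = sample_returns(trees, cfg, rng)
        center = (cfg.extent_x / 2.0, cfg.extent_y / 2.0)
        geom = PlotGeometry.from_area(*center, field_plot_shape,
                                      field_plot_area_ha)
        in_plot = [t for t in trees if geom.contains(
            np.array([t.x]), np.array([t.y]))[0]]
        plots.append(geom)
        ids.append(i)
        clouds.append(cloud)
        trees_per_plot.append(in_plot)
        configs.append(cfg)
    agb_rng = np.random.default_rng(np.random.SeedSequence((seed, 15485863)))
    field_agb = assign_field_agb(
        trees_per_plot, [p.area_ha for p in plots], allometry,
        agb_noise_sd, agb_rng)
    # degenerate empty plots would carry zero biomass; regenerate is the
    # caller's job — here we floor at a trace value to keep logs defined
    field_agb = np.maximum(field_agb, 1e-6)
    dem = DemRaster.flat(0.0, 0.0, base_config.extent_x, base_config.extent_y)
    truth = {"allometry_a": allometry[0], "allometry_b": allometry[1],
             "agb_noise_sd": agb_noise_sd, "seed": seed,
             "height_scale_range": list(height_scale_range)}
    return StudyDataset(plots, ids, clouds, field_agb, truth, configs, dem)


# ---------------------------------------------------------------------------
# Study persistence: per-plot CSV clouds + a JSON manifest


def write_study(study: StudyDataset, out_dir: str | Path) -> Path:
    """Write clouds as x,y,z,class CSVs, the zero DEM as ESRI ASCII, and a
    manifest JSON (plot table + field AGB + truth block)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_rows = []
    for pid, geom, cloud in zip(study.plot_ids, study.plots, study.clouds):
        fname = f"plot_{pid}.csv"
        raw = RawPointCloud(cloud.x, cloud.y, cloud.h, cloud.classification)
        write_point_cloud_csv(raw, out / fname)
        plot_rows.append({"id": pid, "center_x": geom.center_x,
                          "center_y": geom.center_y, "shape": geom.shape,
                          "dimension": geom.dimension,
                          "area_ha": geom.area_ha, "cloud": fname})
    if study.dem is not None:
        from .chm import ChmRaster, write_chm_asc
        grid = study.dem.grid
        write_chm_asc(ChmRaster(study.dem.origin_x, study.dem.origin_y,
                                study.dem.resolution, grid,
                                np.ones_like(grid, dtype=np.int8),
                                np.empty(0), np.empty(0), np.empty(0)),
                      out / "dem.asc")
    manifest = {"plots": plot_rows,
                "field_agb": study.field_agb.tolist(),
                "truth": study.truth}
    (out / "study.json").write_text(json.dumps(manifest, indent=1))
    return out / "study.json"


def load_study(manifest_path: str | Path) -> StudyDataset:
    """Load a study written by :func:`write_study` (clouds are re-read as
    already-normalized heights; trees are not persisted)."""
    from .pointcloud import read_point_cloud

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    plots, ids, clouds = [], [], []
    for row in manifest["plots"]:
        plots.append(PlotGeometry(row["center_x"], row["center_y"],
                                  row["shape"], row["dimension"]))
        ids.append(row["id"])
        raw = read_point_cloud(base / row["cloud"], "xyz-csv")
        clouds.append(NormalizedPointCloud(raw.x, raw.y, raw.z,
                                           raw.classification,
                                           {"source": str(base / row["cloud"])}))
    return StudyDataset(plots, ids, clouds,
                        np.asarray(manifest["field_agb"]),
                        manifest.get("truth", {}))
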