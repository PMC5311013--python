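"""The factorial density x plot-size experiment and its paired statistics.

For every plot the pipeline computes both data models' metric vectors at
the original point density and at each thinned density, and at every plot
size, then compares conditions pairwise per metric: a two-sided Wilcoxon
signed-rank test on the per-plot differences (the primary test, since
LiDAR metrics are generally non-normal), a two-sided one-sample t-test for
reference, and a Lilliefors-style Kolmogorov-Smirnov normality screen used
only for reporting.

No multiple-testing correction is applied across the metric x condition
grid by default (a Holm option exists); alpha defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chm import compute_chm_metrics, interpolate_empty_cells, rasterize_max_height
from .metrics import METRIC_NAMES, compute_echo_metrics
from .pointcloud import PlotGeometry, clip_to_plot, thin_to_density
from .synthetic import StudyDataset

__all__ = [
    "WilcoxonResult", "ComparisonResult", "ExperimentGrid", "GridResult",
    "paired_differences", "wilcoxon_signed_rank", "one_sample_t",
    "ks_normality_screen", "condition_metrics", "run_grid",
]


# ---------------------------------------------------------------------------
# Paired tests


@dataclass
class WilcoxonResult:
    statistic: float       # W+ (sum of positive ranks after zero removal)
    p_value: float
    n: int                 # pairs used after zero removal
    method: str            # "exact" | "normal-approx" | "degenerate"
    degenerate: bool = False


def wilcoxon_signed_rank(d: np.ndarray, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of zero median difference.

    Classical procedure: zero differences are dropped, tied absolute values
    get mid-ranks.  For n <= ``exact_max_n`` (after zero removal) the exact
    null distribution of W+ is computed by convolution over the 2^n sign
    assignments (mid-ranks make W+ a half-integer lattice, handled by
    doubling the ranks); beyond that a normal approximation with tie and
    continuity corrections is used.  All differences zero gives p = 1,
    flagged degenerate.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty differences vector")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        total = int(r2.sum())
        # counts[s] = number of sign assignments with doubled-W+ == s
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r].copy()
        counts /= 2.0**n
        w2 = int(np.rint(2.0 * w_plus))
        cdf = counts[:w2 + 1].sum()
        sf = counts[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(w_plus, float(p), n, "exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - (tie_counts**3 - tie_counts).sum() / 48.0)
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", True)
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(min(1.0, p)), n, "normal-approx")


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def one_sample_t(d: np.ndarray) -> TTestResult:
    """Two-sided one-sample t-test of zero mean difference (n-1 df)."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if np.std(d, ddof=1) == 0.0:
        return TTestResult(np.nan, 1.0 if d.mean() == 0 else 0.0,
                           d.size, True)
    res = sps.ttest_1samp(d, 0.0)
    return TTestResult(float(res.statistic), float(res.pvalue), d.size)


def ks_normality_screen(values: np.ndarray) -> tuple[float, float]:
    """Lilliefors KS statistic and p-value against a Normal with
    sample-estimated mean and sd.  Reporting-only: it never gates which
    paired test is run.  A constant sample returns p = 0."""
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("normality screen needs n >= 5")
    if np.ptp(values) == 0.0:
        return np.inf, 0.0
    stat, p = lilliefors(values, dist="norm")
    return float(stat), float(p)


def paired_differences(a: pd.DataFrame, b: pd.DataFrame,
                       metric: str) -> tuple[np.ndarray, int]:
    """Per-plot ``a - b`` for one metric, paired by plot_id.

    Both tables need ``plot_id`` and the metric column and identical id
    sets (an id mismatch is an error naming the offenders).  Rows where
    either side is NaN (undefined metric) are dropped pairwise; the count
    of dropped pairs is returned alongside the differences.
    """
    ids_a, ids_b = set(a["plot_id"]), set(b["plot_id"])
    if ids_a != ids_b:
        raise ValueError("plot id mismatch between tables: "
                         f"{sorted(ids_a ^ ids_b)[:10]}")
    if a["plot_id"].duplicated().any() or b["plot_id"].duplicated().any():
        raise ValueError("duplicate plot ids in a metric table")
    sa = a.set_index("plot_id")[metric].sort_index()
    sb = b.set_index("plot_id")[metric].sort_index()
    diff = (sa - sb).to_numpy(dtype=float)
    ok = np.isfinite(diff)
    return diff[ok], int((~ok).sum())


# ---------------------------------------------------------------------------
# Grid driver


@dataclass
class ComparisonResult:
    """One paired condition comparison for one metric and data model."""

    comparison: str        # "density" | "plot_size"
    metric: str
    data_model: str
    plot_size: float       # ha (the size at which the comparison is made)
    density: float | str   # the non-reference condition
    reference: float | str
    n_pairs: int
    n_dropped: int
    mean_diff: float
    sd_diff: float
    wilcoxon_stat: float
    wilcoxon_p: float
    ttest_p: float
    significant: bool


@dataclass
class ExperimentGrid:
    """Factorial design: which densities and plot sizes to run.

    ``densities`` are the thinning targets (points/m^2); the reference is
    the original (unthinned) cloud, labelled "orig".  ``reference_plot_size``
    defaults to the largest size in the grid (the field-plot convention of
    1 ha sites); plot shapes follow the field convention of circles for
    0.09 ha plots and squares for the larger nested sizes, overridable via
    ``shape_rule``.
    """

    densities: tuple = (10.0, 5.0, 1.0)
    plot_sizes: tuple = (0.09, 0.25, 0.5, 1.0)
    reference_plot_size: float | None = None
    alpha: float = 0.05
    seed: int = 0
    canopy_threshold: float = 2.0
    fc_threshold: float | None = None
    chm_resolution: float = 1.0
    holm_correction: bool = False
    shape_rule: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.reference_plot_size is None:
            self.reference_plot_size = max(self.plot_sizes)
        if self.reference_plot_size not in self.plot_sizes:
            raise ValueError("reference plot size must be in plot_sizes")
        if self.shape_rule is None:
            self.shape_rule = lambda area_ha: ("circle" if area_ha <= 0.1
                                               else "square")


@dataclass
class GridResult:
    metrics: pd.DataFrame       # tidy: one row per (plot, model, density, size)
    comparisons: pd.DataFrame   # one row per ComparisonResult
    alpha: float

    def significance_matrix(self) -> pd.DataFrame:
        """The check-mark table: rows are condition pairs, columns are
        (data model, metric), entries are booleans at alpha."""
        return self.comparisons.pivot_table(
            index=["comparison", "plot_size", "density"],
            columns=["data_model", "metric"], values="significant",
            aggfunc="first").astype(bool)


def condition_metrics(cloud, geom: PlotGeometry, *, density_label,
                      canopy_threshold: float = 2.0,
                      fc_threshold: float | None = None,
                      chm_resolution: float = 1.0, plot_id="") -> list[dict]:
    """Echo and CHM metric rows for one (cloud, geometry) condition."""
    echo = compute_echo_metrics(cloud, canopy_threshold, fc_threshold,
                                plot_id=plot_id, point_density=density_label,
                                plot_size=geom.area_ha)
    chm = interpolate_empty_cells(
        rasterize_max_height(cloud, geom, chm_resolution))
    chm_fc = fc_threshold if fc_threshold is not None else canopy_threshold
    chm_row = compute_chm_metrics(chm, chm_fc, plot_id=plot_id,
                                  point_density=density_label,
                                  plot_size=geom.area_ha)
    return [echo.as_dict(), chm_row.as_dict()]


def _compare(metrics: pd.DataFrame, comparison: str, sel_a: dict, sel_b: dict,
             plot_size: float, density, reference, alpha: float) -> list[ComparisonResult]:
    out = []
    for model in ("echo", "chm"):
        a = metrics[(metrics["data_model"] == model)
                    & np.logical_and.reduce(
                        [metrics[k] == v for k, v in sel_a.items()])]
        b = metrics[(metrics["data_model"] == model)
                    & np.logical_and.reduce(
                        [metrics[k] == v for k, v in sel_b.items()])]
        for metric in METRIC_NAMES:
            diff, dropped = paired_differences(a, b, metric)
            if diff.size == 0:
                out.append(ComparisonResult(
                    comparison, metric, model, plot_size, density, reference,
                    0, dropped, np.nan, np.nan, np.nan, np.nan, np.nan, False))
                continue
            w = wilcoxon_signed_rank(diff)
            t = one_sample_t(diff) if diff.size >= 2 else TTestResult(
                np.nan, np.nan, diff.size, True)
            out.append(ComparisonResult(
                comparison, metric, model, plot_size, density, reference,
                w.n, dropped, float(diff.mean()),
                float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
                w.statistic, w.p_value, t.p_value, w.p_value < alpha))
    return out


def run_grid(study: StudyDataset, grid: ExperimentGrid) -> GridResult:
    """Run the full factorial experiment on a study.

    For every plot and plot size the original cloud is clipped, both data
    models' metrics computed, then the clipped cloud is thinned to each
    target density (fresh sub-seed per condition derived from the grid seed
    by the counter scheme (seed, plot index, size index, density index))
    and metrics recomputed.  Density comparisons pair thinned vs original at
    fixed size; plot-size comparisons pair each size against the reference
    size at fixed density.  Significance is the Wilcoxon decision at alpha
    (optionally Holm-corrected across metrics within a condition).
    """
    rows: list[dict] = []
    for ip, (pid, geom0, cloud) in enumerate(
            zip(study.plot_ids, study.plots, study.clouds)):
        for isz, size in enumerate(grid.plot_sizes):
            geom = PlotGeometry.from_area(geom0.center_x, geom0.center_y,
                                          grid.shape_rule(size), size)
            clipped = clip_to_plot(cloud, geom)
            rows.extend(condition_metrics(
                clipped, geom, density_label="orig", plot_id=pid,
                canopy_threshold=grid.canopy_threshold,
                fc_threshold=grid.fc_threshold,
                chm_resolution=grid.chm_resolution))
            for idn, dens in enumerate(grid.densities):
                seed = np.random.SeedSequence((grid.seed, ip, isz, idn))
                thinned = thin_to_density(clipped, geom, dens, seed)
                rows.extend(condition_metrics(
                    thinned, geom, density_label=dens, plot_id=pid,
                    canopy_threshold=grid.canopy_threshold,
                    fc_threshold=grid.fc_threshold,
                    chm_resolution=grid.chm_resolution))
    metrics = pd.DataFrame(rows)

    comparisons: list[ComparisonResult] = []
    for size in grid.plot_sizes:
        for dens in grid.densities:
            comparisons.extend(_compare(
                metrics, "density",
                {"plot_size": PlotGeometry.from_area(0, 0, grid.shape_rule(size), size).area_ha,
                 "point_density": dens},
                {"plot_size": PlotGeometry.from_area(0, 0, grid.shape_rule(size), size).area_ha,
                 "point_density": "orig"},
                size, dens, "orig", grid.alpha))
    ref_size = grid.reference_plot_size
    for size in grid.plot_sizes:
        if size == ref_size:
            continue
        for dens in ["orig", *grid.densities]:
            comparisons.extend(_compare(
                metrics, "plot_size",
                {"plot_size": PlotGeometry.from_area(0, 0, grid.shape_rule(size), size).area_ha,
                 "point_density": dens},
                {"plot_size": PlotGeometry.from_area(0, 0, grid.shape_rule(ref_size), ref_size).area_ha,
                 "point_density": dens},
                size, dens, f"size {ref_size} ha", grid.alpha))
    comp = pd.DataFrame([vars(c) for c in comparisons])
    if grid.holm_correction and len(comp):
        from statsmodels.stats.multitest import multipletests
        groups = comp.groupby(["comparison", "plot_size", "density",
                               "data_model"], sort=False)
        adjusted = np.full(len(comp), np.nan)
        for _, idx in groups.groups.items():
            p = comp.loc[idx, "wilcoxon_p"].to_numpy()
            ok = np.isfinite(p)
            if ok.any():
                adj = multipletests(p[ok], alpha=grid.alpha,
                                    method="holm")[1]
                adjusted[np.asarray(idx)[ok]] = adj
        comp["wilcoxon_p_holm"] = adjusted
        comp["significant"] = adjusted < grid.alpha
    return GridResult(metrics, comp, grid.alpha)
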