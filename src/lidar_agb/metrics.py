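"""The ten echo-based canopy structure metrics.

Height statistics (MaxH, MeanH, P25H, P50H, P75H, P90H, StdH, CV) are
computed over *canopy* returns, i.e. returns with height at or above the
canopy threshold (default 2 m).  Fractional cover (FC) is the fraction of
all returns at or above a cover threshold, which defaults to the canopy
threshold but is site-configurable (e.g. 27 m for tall tropical canopies
where only emergent crowns track biomass).  AUCW is the area under the
canopy pseudo-waveform: the normalized vertical histogram of canopy-return
heights integrated by trapezoid and divided by the height range, a scalar
summary of how canopy material is distributed vertically.

Plots without any canopy return report NaN for the height statistics (so
regressions can exclude rather than absorb them), FC = 0 and AUCW = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud import NormalizedPointCloud

__all__ = [
    "METRIC_NAMES",
    "MetricVector",
    "Waveform",
    "compute_echo_metrics",
    "fractional_cover",
    "canopy_pseudo_waveform",
    "area_under_canopy_waveform",
    "height_statistics",
]

#: Canonical metric column order for tidy output tables.
METRIC_NAMES = ("AUCW", "CV", "FC", "MaxH", "MeanH",
                "P25H", "P50H", "P75H", "P90H", "StdH")

DEFAULT_CANOPY_THRESHOLD = 2.0


@dataclass
class MetricVector:
    """The 10 structure metrics for one plot under one experiment condition."""

    AUCW: float
    CV: float
    FC: float
    MaxH: float
    MeanH: float
    P25H: float
    P50H: float
    P75H: float
    P90H: float
    StdH: float
    data_model: str = "echo"  # "echo" | "chm"
    point_density: float | str = "orig"
    plot_size: float = np.nan  # ha
    plot_id: str | int = ""

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d.update(data_model=self.data_model, point_density=self.point_density,
                 plot_size=self.plot_size, plot_id=self.plot_id)
        return d


@dataclass
class Waveform:
    """Normalized vertical histogram of canopy heights (a pseudo-waveform)."""

    bin_edges: np.ndarray
    bin_values: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if (self.bin_values < 0).any():
            raise ValueError("negative waveform bin")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def height_range(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])


def height_statistics(h: np.ndarray) -> dict:
    """MaxH, MeanH, quartile/90th percentiles, StdH and CV of a height sample.

    Percentiles use linear interpolation between order statistics (the
    common 'type 7' convention, numpy's default).  StdH is the sample
    standard deviation (ddof=1); a single observation gives StdH = 0 so the
    CV identity stays defined.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        return {k: np.nan for k in ("MaxH", "MeanH", "P25H", "P50H", "P75H",
                                    "P90H", "StdH", "CV")}
    p25, p50, p75, p90 = np.percentile(h, [25, 50, 75, 90])
    mean = float(h.mean())
    std = float(h.std(ddof=1)) if h.size > 1 else 0.0
    cv = std / mean if mean > 0 else np.nan
    return {"MaxH": float(h.max()), "MeanH": mean, "P25H": float(p25),
            "P50H": float(p50), "P75H": float(p75), "P90H": float(p90),
            "StdH": std, "CV": cv}


def fractional_cover(cloud: NormalizedPointCloud, threshold: float) -> float:
    """count(h >= threshold) / count(all returns); NaN on an empty cloud."""
    n = len(cloud)
    if n == 0:
        return np.nan
    return float(np.count_nonzero(cloud.h >= threshold)) / n


def canopy_pseudo_waveform(cloud: NormalizedPointCloud,
                           canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD,
                           bin_width: float = 0.5,
                           hmax: float | None = None) -> Waveform:
    """Histogram canopy-return heights over [threshold, hmax], normalized to sum 1.

    ``hmax`` defaults to the tallest canopy return rounded up to the next bin
    edge above the threshold (at least one bin).  Heights from a pixel grid
    can be passed through the same machinery by wrapping them in a cloud.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    canopy = cloud.h[cloud.h >= canopy_threshold]
    if hmax is None:
        top = canopy.max() if canopy.size else canopy_threshold
        n_bins = max(1, int(np.ceil((top - canopy_threshold) / bin_width)))
        # a return exactly on the top edge must land in the last bin
        if canopy.size and canopy_threshold + n_bins * bin_width <= top:
            n_bins += 1
        hmax = canopy_threshold + n_bins * bin_width
    else:
        if hmax <= canopy_threshold:
            raise ValueError("hmax must exceed the canopy threshold")
        n_bins = int(np.ceil((hmax - canopy_threshold) / bin_width))
    edges = canopy_threshold + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(canopy, bins=edges)
    total = counts.sum()
    values = counts / total if total else counts.astype(float)
    return Waveform(edges, values, bin_width)


def area_under_canopy_waveform(w: Waveform) -> float:
    """Trapezoidal integral of the waveform over bin centers, range-normalized.

    Dividing by the height range makes the statistic comparable across plots
    with different canopy depths.  0 when there are no canopy returns.
    """
    if w.bin_values.sum() == 0:
        return 0.0
    if w.bin_values.size < 2:
        return 0.0  # a single bin spans no center-to-center distance
    return float(np.trapezoid(w.bin_values, w.bin_centers) / w.height_range)


def compute_echo_metrics(cloud: NormalizedPointCloud,
                         canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD,
                         fc_threshold: float | None = None,
                         bin_width: float = 0.5,
                         **tags) -> MetricVector:
    """All 10 metrics from a plot-clipped normalized cloud (echo data model).

    ``fc_threshold`` defaults to ``canopy_threshold``; pass e.g. 27.0 for
    sites where cover is only meaningful for the emergent canopy.
    """
    canopy = cloud.h[cloud.h >= canopy_threshold]
    stats = height_statistics(canopy)
    if len(cloud) == 0:
        fc = 0.0
    else:
        fc = fractional_cover(cloud, fc_threshold if fc_threshold is not None
                              else canopy_threshold)
    wf = canopy_pseudo_waveform(cloud, canopy_threshold, bin_width)
    aucw = area_under_canopy_waveform(wf)
    tags.setdefault("data_model", "echo")
    return MetricVector(AUCW=aucw, FC=fc, **stats, **tags)
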