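import numpy as np
import pytest

import lidar_agb as la


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_plot():
    """One 40x40 m stand with its 0.09 ha square plot and 20 pts/m2 cloud."""
    cfg = la.StandConfig(extent_x=40.0, extent_y=40.0, seed=42)
    trees = la.simulate_stand(cfg)
    cloud = la.sample_returns(trees, cfg)
    geom = la.PlotGeometry(20.0, 20.0, "square", 30.0)  # 0.09 ha
    return cfg, trees, geom, la.clip_to_plot(cloud, geom)


@pytest.fixture(scope="session")
def plot_ensemble():
    """100 independent small stands for directional/ensemble properties.

    40x40 m stands at 20 returns/m2 with a 0.09 ha square plot each;
    per-stand Weibull height scale varies so the ensemble spans the
    sparse-to-tall structure gradient.
    """
    plots = []
    for i in range(100):
        scale = 8.0 + 17.0 * (i / 99.0)
        cfg = la.StandConfig(extent_x=40.0, extent_y=40.0,
                             height_distribution=("weibull", 2.2, scale),
                             seed=1000 + i)
        trees = la.simulate_stand(cfg)
        cloud = la.sample_returns(trees, cfg)
        geom = la.PlotGeometry(20.0, 20.0, "square", 30.0)
        plots.append((geom, la.clip_to_plot(cloud, geom)))
    return plots
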