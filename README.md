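# lidar-agb

How much LiDAR point density does forest aboveground-biomass (AGB)
estimation actually need — and does the answer depend on whether you work
from the 3D return cloud or from a rasterized canopy height model (CHM)?

`lidar-agb` is a tested, reusable pipeline for that question, aimed at
researchers in forest remote sensing and people planning LiDAR campaigns.
It implements:

* a **point-cloud core**: CSV/LAS-dialect readers, DEM height
  normalization (bilinear), plot clipping (circular and square field
  plots), random return thinning to a target density with exact count and
  subset guarantees, and density accounting;
* the **ten standard canopy structure metrics** from the echo (return)
  cloud — MaxH, MeanH, P25H/P50H/P75H/P90H, StdH, CV, fractional cover
  (FC) and the area under the canopy pseudo-waveform (AUCW) — over canopy
  returns with height ≥ 2 m;
* a **CHM data model**: 1 m per-cell maximum rasterization with argmax
  provenance, Delaunay-based gap interpolation (constants exact, planes to
  1e-6 inside the hull), and the same ten metrics over pixels;
* the **factorial experiment** (data model × point density × plot size)
  with paired two-sided Wilcoxon signed-rank tests (exact null for n ≤ 25,
  ties and zeros handled classically), one-sample t-tests and a Lilliefors
  normality screen, emitting tidy metric/comparison tables and a
  significance matrix;
* **power-law AGB models** ŷ = αXᵝ and ŷ = αx₁ᵝx₂ᵞ (X, x₁ = mean canopy
  height, x₂ = FC), fitted by NLS with log-OLS initialization, evaluated
  by 70/30 holdout or leave-one-out jackknife (R², RMSE, relRMSE), and
  **cross-density transfer**: the AGB error incurred by applying a model
  calibrated at high density to metrics from thinned data;
* a **synthetic forest generator** — Poisson stands, paraboloid crown
  envelopes, exponential within-crown penetration, power-law field AGB
  with lognormal noise — so the entire pipeline runs end-to-end with known
  ground truth and exact seeded reproducibility.

## Worked example

```python
import pandas as pd
import lidar_agb as la
from lidar_agb.regression import transfer_curve

study = la.generate_study(n_plots=40, seed=7)          # 40 one-ha stands
grid = la.ExperimentGrid(densities=(10.0, 5.0, 1.0),
                         plot_sizes=(0.09, 1.0),
                         reference_plot_size=1.0, seed=7)
res = la.run_grid(study, grid)                          # both data models
agb = pd.Series(study.field_agb, index=study.plot_ids)

for model in ("echo", "chm"):
    fit, curve = transfer_curve(res.metrics, agb, model, plot_size=1.0)
    print(f"{model:4s}  AGB = {fit.alpha:.3f} * MeanH^{fit.beta:.3f}   "
          + "  ".join(f"{r.density:g}/m2: {r.error_percent:5.2f}%"
                      for r in curve))

row = res.significance_matrix().loc[("density", 1.0, 1.0)]
print("significant at 1 pt/m2, 1 ha:",
      f"echo {int(row['echo'].sum())}/10, chm {int(row['chm'].sum())}/10")
```

prints

```
echo  AGB = 0.451 * MeanH^2.381   10/m2:  0.19%  5/m2:  0.39%  1/m2:  0.81%
chm   AGB = 0.469 * MeanH^2.308   10/m2:  3.83%  5/m2: 11.49%  1/m2: 43.24%
significant at 1 pt/m2, 1 ha: echo 2/10, chm 10/10
```

Reading: both data models calibrate nearly identical power-law AGB models
at the 20 returns/m² reference density. Transferring the echo-based model
to thinned data costs well under 1% of mean predicted AGB even at
1 return/m², whereas the CHM-based model degrades monotonically and loses
43% at 1 return/m² — at low density most 1 m cells are empty and the
interpolated maxima sit far below the true canopy top. The significance
matrix shows the same story at the metric level: at 1 return/m² every CHM
metric differs significantly from its full-density value, while most echo
metrics do not.

The same stages are scriptable from a shell:

```bash
lidar-agb simulate --n-plots 100 --seed 1 --out study/
lidar-agb grid --study study/study.json --densities 10,5,1 \
          --plot-sizes 0.09,0.25,0.5,1.0 --seed 1 --out grid/
lidar-agb fit --metrics grid/metrics.csv --field agb.csv --out fit.json
lidar-agb transfer --fit fit.json --metrics thin.csv \
          --reference-metrics ref.csv --field agb.csv
```

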