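"""Power-law AGB models: fitting, evaluation and cross-density transfer.

Two model forms are fitted per data model:

    yhat = alpha * X^beta                 (mean canopy height only)
    yhat = alpha * x1^beta * x2^gamma     (mean canopy height and cover)

with X / x1 the mean canopy height (m), x2 the fractional cover and y the
field AGB (Mg/ha).  Fitting is nonlinear least squares on the original
(untransformed) scale, initialized from an ordinary least-squares fit of
log y on log X (and log x2); the log-linear start means the NLS solution
never ends with a larger sum of squares than its initialization.
Evaluation reports R^2, RMSE (Mg/ha) and relRMSE (RMSE as a percent of the
mean observed AGB of the evaluation set), under a 70/30 holdout for
adequately sized studies or leave-one-out jackknife for small ones.

Cross-density transfer applies a model calibrated at the reference density
to metrics derived from thinned clouds; the headline error is the RMS
difference between thinned-input and reference-input predictions expressed
as a percent of the mean reference prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PowerModelFit", "ModelEvaluation", "CrossDensityResult",
    "fit_power_model", "evaluate", "holdout_split", "jackknife_evaluate",
    "cross_density_apply", "transfer_curve",
]


@dataclass
class PowerModelFit:
    """alpha, beta (and gamma) plus asymptotic parameter SDs."""

    form: str                   # "one-variable" | "two-variable"
    alpha: float
    beta: float
    gamma: float | None = None
    alpha_sd: float = np.nan
    beta_sd: float = np.nan
    gamma_sd: float = np.nan
    data_model: str = ""
    calibration_density: float | str = ""
    converged: bool = True
    n: int = 0

    def predict(self, X: np.ndarray, x2: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.form == "two-variable":
            if x2 is None:
                raise ValueError("two-variable model needs x2")
            return self.alpha * X**self.beta * np.asarray(x2, float)**self.gamma
        return self.alpha * X**self.beta

    def to_json(self, path: str | Path) -> None:
        d = {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                 else v) for k, v in vars(self).items()}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerModelFit":
        d = json.loads(Path(path).read_text())
        for k in ("alpha_sd", "beta_sd", "gamma_sd"):
            if d.get(k) is None:
                d[k] = np.nan
        return cls(**d)


@dataclass
class ModelEvaluation:
    r2: float
    rmse: float          # Mg/ha
    rel_rmse: float      # percent of mean observed AGB
    n: int
    protocol: str        # "in-sample" | "holdout" | "jackknife" | "cross-density"
    extra: dict = field(default_factory=dict)


def _validate_positive(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    bad = ~(np.isfinite(values) & (values > 0))
    if bad.any():
        raise ValueError(f"{name} must be positive and finite; offending "
                         f"indices {np.flatnonzero(bad)[:10].tolist()}")
    return values


def _sse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(((y - yhat) ** 2).sum())


def fit_power_model(X: np.ndarray, y: np.ndarray,
                    form: str = "one-variable",
                    x2: np.ndarray | None = None,
                    scale: str = "original", **tags) -> PowerModelFit:
    """Fit yhat = alpha X^beta (or alpha x1^beta x2^gamma) by NLS.

    ``scale='log'`` returns the log-OLS fit directly (sensitivity mode);
    the default minimizes squared error on the original scale.  At least 3
    (one-variable) or 4 (two-variable) plots are required, all inputs
    positive.  If the optimizer fails to improve on the log-linear start,
    the start is returned with ``converged=False``.
    """
    X = _validate_positive("X", X)
    y = _validate_positive("y", y)
    two = form == "two-variable"
    if form not in ("one-variable", "two-variable"):
        raise ValueError(f"unknown model form {form!r}")
    if two:
        if x2 is None:
            raise ValueError("two-variable form requires x2")
        x2 = _validate_positive("x2", x2)
    min_n = 4 if two else 3
    if X.size < min_n:
        raise ValueError(f"{form} fit needs at least {min_n} plots")

    # log-OLS initialization
    design = [np.ones_like(X), np.log(X)] + ([np.log(x2)] if two else [])
    coef, *_ = np.linalg.lstsq(np.column_stack(design), np.log(y), rcond=None)
    p0 = [float(np.exp(coef[0])), float(coef[1])] + ([float(coef[2])] if two else [])

    if scale == "log":
        fit = PowerModelFit(form, p0[0], p0[1], p0[2] if two else None,
                            n=X.size, **tags)
        return fit

    if two:
        def model(xdata, a, b, g):
            return a * xdata[0]**b * xdata[1]**g
        xdata = np.vstack([X, x2])
    else:
        def model(xdata, a, b):
            return a * xdata**b
        xdata = X
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, xdata, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
    # the log-linear start is the floor: never return a worse SSE
    if _sse(y, model(xdata, *popt)) > _sse(y, model(xdata, *p0)):
        popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
    sds = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else \
        np.full(len(popt), np.nan)
    return PowerModelFit(
        form, float(popt[0]), float(popt[1]),
        float(popt[2]) if two else None,
        alpha_sd=float(sds[0]), beta_sd=float(sds[1]),
        gamma_sd=float(sds[2]) if two else np.nan,
        converged=converged, n=X.size, **tags)


def evaluate(fit: PowerModelFit, X: np.ndarray, y: np.ndarray,
             x2: np.ndarray | None = None,
             protocol: str = "in-sample") -> ModelEvaluation:
    """R^2 (about mean y), RMSE and relRMSE of the fit on an evaluation set."""
    X = _validate_positive("X", X)
    y = _validate_positive("y", y)
    if X.size == 0:
        raise ValueError("empty evaluation set")
    yhat = fit.predict(X, x2)
    sse = _sse(y, yhat)
    sst = _sse(y, np.full_like(y, y.mean()))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(sse / y.size))
    return ModelEvaluation(r2, rmse, 100.0 * rmse / float(y.mean()),
                           int(y.size), protocol)


def holdout_split(plot_ids, calibration_fraction: float = 0.7,
                  seed: int | np.random.SeedSequence = 0):
    """Seeded disjoint-exhaustive random split; calibration size =
    round(fraction * n).  Requires n >= 5 (use the jackknife below that)."""
    plot_ids = np.asarray(plot_ids)
    n = plot_ids.size
    if n < 5:
        raise ValueError("holdout split needs n >= 5; use jackknife_evaluate")
    n_cal = int(np.round(calibration_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return plot_ids[np.sort(perm[:n_cal])], plot_ids[np.sort(perm[n_cal:])]


def jackknife_evaluate(X: np.ndarray, y: np.ndarray,
                       x2: np.ndarray | None = None,
                       form: str = "one-variable",
                       **tags) -> tuple[ModelEvaluation, "np.ndarray"]:
    """Leave-one-out evaluation for small samples.

    Each plot is predicted by the model fitted on the other n-1; R^2/RMSE/
    relRMSE are computed over the n out-of-fit predictions.  Also returns
    the (n, k) array of per-fold parameters, whose column means/SDs are the
    usual jackknife parameter summary.  A fold whose fit fails is flagged
    and excluded with a warning.
    """
    X = _validate_positive("X", X)
    y = _validate_positive("y", y)
    n = X.size
    if n < 4:
        raise ValueError("jackknife needs n >= 4")
    preds = np.full(n, np.nan)
    params = []
    for i in range(n):
        mask = np.arange(n) != i
        try:
            fit = fit_power_model(X[mask], y[mask], form,
                                  x2[mask] if x2 is not None else None)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"jackknife fold {i} failed: {exc}", stacklevel=2)
            params.append([np.nan] * (3 if form == "two-variable" else 2))
            continue
        preds[i] = fit.predict(X[i:i + 1],
                               x2[i:i + 1] if x2 is not None else None)[0]
        params.append([fit.alpha, fit.beta]
                      + ([fit.gamma] if form == "two-variable" else []))
    ok = np.isfinite(preds)
    sse = _sse(y[ok], preds[ok])
    sst = _sse(y[ok], np.full(ok.sum(), y[ok].mean()))
    rmse = float(np.sqrt(sse / ok.sum()))
    ev = ModelEvaluation(1.0 - sse / sst if sst > 0 else np.nan, rmse,
                         100.0 * rmse / float(y[ok].mean()), int(ok.sum()),
                         "jackknife")
    params = np.asarray(params, dtype=float)
    ev.extra = {"param_mean": np.nanmean(params, axis=0).tolist(),
                "param_sd": np.nanstd(params, axis=0, ddof=1).tolist()}
    return ev, params


@dataclass
class CrossDensityResult:
    """Transfer of a reference-density model to thinned-density metrics."""

    error_percent: float          # RMS(pred_thin - pred_ref) / mean(pred_ref) * 100
    evaluation: ModelEvaluation   # thinned-input predictions vs field AGB
    density: float | str = ""


def cross_density_apply(fit: PowerModelFit,
                        X_ref: np.ndarray, X_thin: np.ndarray,
                        y: np.ndarray,
                        x2_ref: np.ndarray | None = None,
                        x2_thin: np.ndarray | None = None,
                        density: float | str = "") -> CrossDensityResult:
    """Apply a reference-density fit to thinned metrics of the same plots.

    Arrays must be aligned plot-wise (same order, same plots).  The error
    percent compares thinned-input predictions with reference-input
    predictions, normalized by the mean reference prediction — the loss
    attributable to the density change alone, independent of model error.
    """
    X_ref = _validate_positive("X_ref", X_ref)
    X_thin = _validate_positive("X_thin", X_thin)
    y = _validate_positive("y", y)
    if not (X_ref.size == X_thin.size == y.size):
        raise ValueError("plot mismatch: X_ref, X_thin and y must align")
    pred_ref = fit.predict(X_ref, x2_ref)
    pred_thin = fit.predict(X_thin, x2_thin)
    err = 100.0 * np.sqrt(np.mean((pred_thin - pred_ref) ** 2)) / pred_ref.mean()
    ev = evaluate(fit, X_thin, y, x2_thin, protocol="cross-density")
    return CrossDensityResult(float(err), ev, density)


def transfer_curve(metrics, field_agb, data_model: str = "echo",
                   form: str = "one-variable",
                   plot_size: float | None = None,
                   densities=None, reference="orig"):
    """Fit at the reference density and apply across thinned densities.

    ``metrics`` is the tidy metric table from the experiment driver (one
    row per plot/model/density/size); ``field_agb`` a mapping or pandas
    Series of plot_id -> AGB.  Returns ``(fit, [CrossDensityResult per
    density])`` ordered as given (default: every thinned density present,
    descending).
    """
    import pandas as pd

    agb = pd.Series(field_agb) if not isinstance(field_agb, pd.Series) \
        else field_agb
    sel = metrics[metrics["data_model"] == data_model]
    if plot_size is not None:
        sel = sel[np.isclose(sel["plot_size"].astype(float), plot_size,
                             rtol=1e-6)]
    ref = sel[sel["point_density"] == reference].set_index("plot_id")
    ref = ref.loc[ref.index.intersection(agb.index)].sort_index()
    two = form == "two-variable"
    X_ref = ref["MeanH"].to_numpy()
    x2_ref = ref["FC"].to_numpy() if two else None
    y = agb.loc[ref.index].to_numpy(dtype=float)
    fit = fit_power_model(X_ref, y, form, x2_ref, data_model=data_model,
                          calibration_density=str(reference))
    if densities is None:
        densities = sorted(
            {d for d in sel["point_density"] if d != reference}, reverse=True)
    results = []
    for dens in densities:
        thin = sel[sel["point_density"] == dens].set_index("plot_id")
        thin = thin.loc[ref.index]
        results.append(cross_density_apply(
            fit, X_ref, thin["MeanH"].to_numpy(), y,
            x2_ref, thin["FC"].to_numpy() if two else None, dens))
    return fit, results
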