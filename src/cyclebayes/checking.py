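"""Posterior-predictive checks, R-squared assessment and CI-width accounting.

Goodness of fit for the time-course channel is assessed three ways:

* graphical: pointwise 5/50/95% bands of the posterior predictive of the
  *mean* of the data (modeled log-ratios, no observation noise re-added);
* R-squared of the modeled log-ratios against a null model with a separate
  mean for each experiment, summarized over posterior draws;
* a reference R-squared from a cross-validated cubic smoothing spline,
  approximating the best fit any smooth curve could achieve.

Parameter determination is summarized by the width of each parameter's 90%
credible interval relative to its prior range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .model import ModelSpec, ParameterVector, PriorSpec
from .simulate import integrate, time_average

__all__ = [
    "CheckReport",
    "posterior_predictive",
    "predict_log_ratios",
    "r_squared",
    "r2_distribution",
    "spline_reference_r2",
    "ci_width_summary",
    "plot_bands",
]

logger = logging.getLogger(__name__)

#: Fixed grid of smoothing parameters searched by leave-one-out CV.
SPLINE_LAM_GRID = np.logspace(-2.0, 6.0, 25)


@dataclass
class CheckReport:
    """Model-checking summary for one posterior sample set."""

    bands: pd.DataFrame          # experiment, gene, time_min, q05, q50, q95
    r2: pd.DataFrame             # gene, r2_median, r2_q05, r2_q95
    spline_r2: pd.DataFrame      # gene, r2_spline
    ci_widths: pd.DataFrame      # parameter, width, prior_width, ratio
    n_constrained: int           # parameters with ratio < 0.5
    n_failed_draws: int


def predict_log_ratios(
    model: ModelSpec,
    pv: ParameterVector,
    design: pd.DataFrame,
    log_base: str = "e",
) -> np.ndarray | None:
    """Modeled log-ratios at design points for one parameter vector.

    ``design`` needs columns gene and time_min.  Returns ``None`` when the
    simulation fails or a time average is non-positive.
    """
    times_s = design["time_min"].to_numpy(dtype=float) * 60.0
    traj = integrate(model, pv, eval_times=times_s)
    if not traj.success:
        return None
    denom = 1.0 if log_base == "e" else np.log(2.0)
    out = np.empty(len(design))
    for gene, sub in design.groupby("gene", sort=False):
        species = f"mRNA_{gene}"
        mbar = time_average(traj, species)
        m = traj.at_times(species, sub["time_min"].to_numpy(dtype=float) * 60.0)
        if mbar <= 0 or np.any(m <= 0):
            return None
        out[sub.index.to_numpy()] = np.log(m / mbar) / denom
    return out


def _draw_predictions(
    draws: np.ndarray,
    make_pv,
    model: ModelSpec,
    design: pd.DataFrame,
    log_base: str = "e",
) -> tuple[np.ndarray, int]:
    """Stack predicted log-ratios over draws; count dropped failures."""
    design = design.reset_index(drop=True)
    preds = []
    failed = 0
    for row in draws:
        p = predict_log_ratios(model, make_pv(row), design, log_base=log_base)
        if p is None:
            failed += 1
        else:
            preds.append(p)
    if failed:
        logger.warning("dropped %d failed simulations in posterior predictive", failed)
    if not preds:
        raise ValueError("all posterior draws failed to simulate")
    return np.asarray(preds), failed


def posterior_predictive(
    draws: np.ndarray,
    make_pv,
    model: ModelSpec,
    design: pd.DataFrame,
    log_base: str = "e",
    quantiles: tuple[float, float, float] = (0.05, 0.5, 0.95),
    observation_noise: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, int]:
    """Pointwise predictive quantile bands of the modeled mean log-ratios.

    ``draws`` is an (n_draws, dim) array of free coordinates; ``make_pv``
    maps one row to a full :class:`ParameterVector` (for sampler output,
    ``posterior.full_vector``).  By default the band describes the
    predictive of the *mean* (no re-noising); passing an
    ``observation_noise`` scale adds t(3) measurement noise per draw for a
    full posterior-predictive check.  Returns the band table and the
    number of dropped failed simulations.
    """
    design = design.reset_index(drop=True)
    preds, failed = _draw_predictions(draws, make_pv, model, design, log_base)
    if observation_noise is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        preds = preds + observation_noise * rng.standard_t(3, size=preds.shape)
    q05, q50, q95 = np.quantile(preds, quantiles, axis=0)
    bands = design[["experiment", "gene", "time_min"]].copy() if "experiment" in design else design[["gene", "time_min"]].copy()
    bands["q05"], bands["q50"], bands["q95"] = q05, q50, q95
    return bands, failed


def r_squared(observed, predicted, experiment_ids) -> float:
    """Coefficient of determination against a per-experiment-mean null.

    ``R^2 = 1 - SS_res / SS_null`` where the null predicts each
    experiment's own mean.  Returns NaN when the null sum of squares is
    zero (undefined).
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    ids = np.asarray(experiment_ids)
    if y.shape != f.shape or y.shape != ids.shape:
        raise ValueError("observed, predicted and experiment_ids must align")
    null = np.empty_like(y)
    for e in pd.unique(ids):
        mask = ids == e
        if mask.sum() < 2:
            raise ValueError(f"experiment {e!r} has fewer than 2 records")
        null[mask] = y[mask].mean()
    ss_null = float(np.sum((y - null) ** 2))
    if ss_null == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_null


def r2_distribution(
    draws: np.ndarray,
    make_pv,
    model: ModelSpec,
    data: pd.DataFrame,
    log_base: str = "e",
) -> pd.DataFrame:
    """Posterior distribution of per-gene R-squared values.

    For each draw the modeled log-ratios are scored with :func:`r_squared`
    per gene; the table reports the median and central 90% interval.
    """
    data = data.reset_index(drop=True)
    preds, _ = _draw_predictions(draws, make_pv, model, data, log_base)
    rows = []
    for gene, sub in data.groupby("gene", sort=False):
        idx = sub.index.to_numpy()
        vals = np.array([
            r_squared(sub["log_ratio"].to_numpy(), p[idx], sub["experiment"].to_numpy())
            for p in preds
        ])
        rows.append({
            "gene": gene,
            "r2_median": float(np.median(vals)),
            "r2_q05": float(np.quantile(vals, 0.05)),
            "r2_q95": float(np.quantile(vals, 0.95)),
        })
    return pd.DataFrame(rows)


def _loo_spline_predictions(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    pred = np.empty_like(y)
    n = x.size
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        spl = make_smoothing_spline(x[mask], y[mask], lam=lam)
        pred[i] = spl(x[i])
    return pred


def spline_reference_r2(data: pd.DataFrame, min_points: int = 8) -> float:
    """Reference R-squared from a cross-validated cubic smoothing spline.

    For each experiment a natural cubic smoothing spline is fitted to the
    (time, log-ratio) records of one gene, with the smoothing parameter
    selected by leave-one-out CV over the fixed grid
    :data:`SPLINE_LAM_GRID` (deterministic: identical input gives
    identical output).  The fitted values are scored with
    :func:`r_squared` against the per-experiment-mean null.  Experiments
    with fewer than ``min_points`` time points return NaN.
    """
    data = data.reset_index(drop=True)
    fitted = np.empty(len(data))
    for exp, sub in data.groupby("experiment", sort=False):
        x = sub["time_min"].to_numpy(dtype=float)
        y = sub["log_ratio"].to_numpy(dtype=float)
        if x.size < min_points or np.unique(x).size < x.size:
            return float("nan")
        order = np.argsort(x)
        xo, yo = x[order], y[order]
        sq_err = np.array([
            (yo - _loo_spline_predictions(xo, yo, lam)) ** 2
            for lam in SPLINE_LAM_GRID
        ])
        means = sq_err.mean(axis=1)
        i_min = int(np.argmin(means))
        # one-standard-error rule: the smoothest lambda whose CV score is
        # within one standard error of the minimum (guards against
        # near-interpolating fits picked by noisy leave-one-out scores)
        se = sq_err[i_min].std(ddof=1) / np.sqrt(x.size)
        best = SPLINE_LAM_GRID[np.flatnonzero(means <= means[i_min] + se)[-1]]
        spl = make_smoothing_spline(xo, yo, lam=best)
        fitted[sub.index.to_numpy()] = spl(x)
    return r_squared(
        data["log_ratio"].to_numpy(), fitted, data["experiment"].to_numpy()
    )


def ci_width_summary(
    draws: np.ndarray,
    names,
    prior: PriorSpec,
    level: float = 0.9,
    min_draws: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Per-parameter credible-interval widths relative to the prior range.

    Width is ``q95 - q5`` on sampling scale (log10 for rates and
    concentrations); the summary additionally counts how many parameters
    have a width below half of their prior range.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} draws")
    names = tuple(names)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    sub = prior.subset(names)
    q_lo = np.quantile(draws, lo_q, axis=0)
    q_hi = np.quantile(draws, hi_q, axis=0)
    width = q_hi - q_lo
    table = pd.DataFrame({
        "parameter": names,
        "ci_low": q_lo,
        "ci_high": q_hi,
        "width": width,
        "prior_width": sub.width,
        "ratio": width / sub.width,
    })
    return table, int((table["ratio"] < 0.5).sum())


def plot_bands(bands: pd.DataFrame, data: pd.DataFrame | None, path: str) -> None:
    """Write a figure of predictive bands overlaid on the observations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(pd.unique(bands["gene"]))
    fig, axes = plt.subplots(len(genes), 1, figsize=(7, 2.2 * len(genes)),
                             squeeze=False, sharex=True)
    for ax, gene in zip(axes[:, 0], genes):
        sub = bands[bands["gene"] == gene].sort_values("time_min")
        ax.fill_between(sub["time_min"], sub["q05"], sub["q95"], alpha=0.3,
                        color="crimson", label="90% band")
        ax.plot(sub["time_min"], sub["q50"], color="crimson", label="median")
        if data is not None:
            d = data[data["gene"] == gene]
            for exp, de in d.groupby("experiment"):
                de = de.sort_values("time_min")
                ax.plot(de["time_min"], de["log_ratio"], "o-", ms=3, lw=0.7,
                        alpha=0.7, label=str(exp))
        ax.set_ylabel(f"{gene}\nlog ratio")
    axes[-1, 0].set_xlabel("time (min, 80-min cycle)")
    axes[0, 0].legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
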