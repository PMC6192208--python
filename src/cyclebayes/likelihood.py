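"""Priors, robust Student-t likelihoods and the tempered log-posterior.

Two data channels enter the likelihood:

* relative time-course data — log-ratios of synchronized to unsynchronized
  expression; the modeled value is ``log(m_g(t) / mbar_g)`` where ``mbar_g``
  is the transcript's time average over two cell cycles;
* absolute steady-state data — ``log10`` concentrations; the modeled value
  is ``log10`` of the trajectory time average.

Both channels use a location-scale Student-t error model with 3 degrees of
freedom for robustness to outlying measurements, with one inferred scale
per channel (``sigma_tc``, ``sigma_ss``).  Priors are independent uniform
boxes on log10 scale (Hill exponents linear).  The tempered posterior is
``log prior + beta * log likelihood`` so that the beta = 0 chain samples
the prior exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import ModelSpec, ParameterVector, PriorSpec, compile_rates, param_names
from .simulate import (
    DEFAULT_GRID_POINTS,
    TrajectorySet,
    decoupled_solution,
    integrate,
    time_average,
)

__all__ = [
    "TimeCourseDataset",
    "SteadyStateDataset",
    "log_t_density",
    "relative_loglik",
    "absolute_loglik",
    "log_prior",
    "log_posterior_tempered",
    "Posterior",
]

_LN2 = math.log(2.0)


class DataError(ValueError):
    """Raised when a dataset is inconsistent with the model or schema."""


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

TC_COLUMNS = ("experiment", "gene", "time_min", "log_ratio")
SS_COLUMNS = ("kind", "gene", "log10_conc_uM", "source")


@dataclass
class TimeCourseDataset:
    """Relative time-course records on the common 80-min cell-cycle frame.

    ``records`` columns: experiment, gene, time_min (0..160 on the rescaled
    frame), log_ratio.  ``native_periods`` maps experiment id to the native
    doubling time in minutes (before rescaling).
    """

    records: pd.DataFrame
    native_periods: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TC_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"time-course table missing columns {missing}")
        t = self.records["time_min"].to_numpy(dtype=float)
        if t.size and (t.min() < -1e-9 or t.max() > 160.0 + 1e-9):
            raise DataError("time-course times must lie within [0, 160] min")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["gene"]))

    def validate_against(self, model: ModelSpec) -> None:
        unknown = set(self.genes()) - set(model.gene_names)
        if unknown:
            raise DataError(f"time-course data references genes not in model: {sorted(unknown)}")


@dataclass
class SteadyStateDataset:
    """Absolute steady-state records: log10 concentrations in micromolar.

    ``kind`` is ``"mRNA"`` or ``"protein"``; multiple sources per species
    enter as independent records.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SS_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"steady-state table missing columns {missing}")
        kinds = set(self.records["kind"].unique())
        if not kinds <= {"mRNA", "protein"}:
            raise DataError(f"unknown species kinds {sorted(kinds - {'mRNA', 'protein'})}")
        vals = self.records["log10_conc_uM"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DataError("non-finite steady-state values")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def validate_against(self, model: ModelSpec) -> None:
        unknown = set(self.records["gene"].unique()) - set(model.gene_names)
        if unknown:
            raise DataError(f"steady-state data references genes not in model: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _log_t_norm(df: float) -> float:
    """Log normalizing constant of the standard Student-t density."""
    return float(
        gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0) - 0.5 * math.log(df * math.pi)
    )


def log_t_density(x, center, scale, df: float = 3.0):
    """Log density of the location-scale Student-t distribution.

    At the mode with unit scale and ``df=3`` this equals
    ``log(2 / (pi * sqrt(3)))``.
    """
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    z = (np.asarray(x, dtype=float) - center) / scale
    out = _log_t_norm(df) - np.log(scale) - ((df + 1.0) / 2.0) * np.log1p(z * z / df)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Channel log-likelihoods (reference implementations on a TrajectorySet)
# ---------------------------------------------------------------------------

def relative_loglik(
    traj: TrajectorySet,
    data: TimeCourseDataset,
    sigma_tc: float,
    log_base: str = "e",
) -> float:
    """Student-t log-likelihood of relative time-course data.

    Each record is centered on the log ratio of the modeled transcript
    concentration to its own time average over two cycles.  ``log_base``
    is ``"e"`` (natural log, default) or ``"2"`` for log2-ratio input.
    A failed simulation yields ``-inf``.
    """
    if not traj.success:
        return -math.inf
    denom = 1.0 if log_base == "e" else _LN2
    total = 0.0
    for gene, sub in data.records.groupby("gene", sort=False):
        species = f"mRNA_{gene}"
        try:
            mbar = time_average(traj, species)
        except KeyError:
            raise DataError(f"time-course data references gene {gene!r} not in model")
        times_s = sub["time_min"].to_numpy(dtype=float) * 60.0
        m = traj.at_times(species, times_s)
        if mbar <= 0 or np.any(m <= 0):
            return -math.inf
        centers = np.log(m / mbar) / denom
        y = sub["log_ratio"].to_numpy(dtype=float)
        total += float(np.sum(log_t_density(y, centers, sigma_tc)))
    return total


def absolute_loglik(traj: TrajectorySet, data: SteadyStateDataset, sigma_ss: float) -> float:
    """Student-t log-likelihood of absolute steady-state data.

    Each record is centered on ``log10`` of the modeled time average of the
    corresponding species; a non-positive time average yields ``-inf``.
    """
    if not traj.success:
        return -math.inf
    total = 0.0
    for (kind, gene), sub in data.records.groupby(["kind", "gene"], sort=False):
        species = f"{kind}_{gene}"
        try:
            avg = time_average(traj, species)
        except KeyError:
            raise DataError(f"steady-state data references species {species!r} not in model")
        if avg <= 0:
            return -math.inf
        center = math.log10(avg)
        y = sub["log10_conc_uM"].to_numpy(dtype=float)
        total += float(np.sum(log_t_density(y, center, sigma_ss)))
    return total


def log_prior(params: ParameterVector, prior: PriorSpec) -> float:
    """Uniform box prior on sampling scale: constant inside, -inf outside."""
    if tuple(prior.names) != tuple(params.names):
        raise ValueError("prior and parameter vector name mismatch")
    if not prior.contains(params.values):
        return -math.inf
    return -prior.log_volume()


def log_posterior_tempered(
    params: ParameterVector,
    model: ModelSpec,
    prior: PriorSpec,
    tc_data: TimeCourseDataset | None = None,
    ss_data: SteadyStateDataset | None = None,
    beta: float = 1.0,
    log_base: str = "e",
) -> float:
    """Reference tempered log-posterior: ``log_prior + beta * loglik``.

    ``beta=0`` is the prior, ``beta=1`` the full posterior.  This is the
    straightforward composition of the channel likelihoods; the sampler
    uses the equivalent but vectorized :class:`Posterior`.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("inverse temperature beta must lie in [0, 1]")
    lp = log_prior(params, prior)
    if lp == -math.inf:
        return -math.inf
    if beta == 0.0 or (tc_data is None and ss_data is None):
        return lp
    lin = params.to_linear()
    eval_times = None
    if tc_data is not None:
        eval_times = tc_data.records["time_min"].to_numpy(dtype=float) * 60.0
    traj = integrate(model, params, eval_times=eval_times)
    ll = 0.0
    if tc_data is not None:
        ll += relative_loglik(traj, tc_data, lin["sigma_tc"], log_base=log_base)
    if ss_data is not None:
        ll += absolute_loglik(traj, ss_data, lin["sigma_ss"])
    return lp + beta * ll


# ---------------------------------------------------------------------------
# Fast posterior used by the sampler
# ---------------------------------------------------------------------------

class Posterior:
    """Vectorized joint posterior over the free parameters of a model.

    Precomputes the evaluation grid (dense grid merged with data times),
    trapezoid weights and record index arrays at construction so that
    repeated evaluations during MCMC are cheap.  Decoupled (linear,
    basal-only) models take a closed-form batched path; regulated models
    fall back to per-evaluation LSODA integration.

    Parameters listed in ``fixed`` (sampling-scale values) are excluded
    from the sampled vector; ``logp`` operates on the remaining free
    parameters in :func:`cyclebayes.model.param_names` order.
    """

    def __init__(
        self,
        model: ModelSpec,
        prior: PriorSpec,
        tc_data: TimeCourseDataset | None = None,
        ss_data: SteadyStateDataset | None = None,
        fixed: Mapping[str, float] | None = None,
        log_base: str = "e",
        n_dense: int = DEFAULT_GRID_POINTS,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> None:
        self.model = model
        self.log_base = log_base
        self.n_dense = n_dense
        self.rtol = rtol
        self.atol = atol
        all_names = param_names(model)
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(all_names)
        if unknown:
            raise ValueError(f"fixed parameters not in model: {sorted(unknown)}")
        self.fixed = fixed
        self.free_names = tuple(n for n in all_names if n not in fixed)
        self.all_names = all_names
        self.prior = prior.subset(self.free_names)
        self._template = np.zeros(len(all_names))
        for n, v in fixed.items():
            self._template[all_names.index(n)] = v
        self._free_idx = np.array([all_names.index(n) for n in self.free_names])
        self._lp_inside = -self.prior.log_volume()

        if tc_data is not None:
            tc_data.validate_against(model)
        if ss_data is not None:
            ss_data.validate_against(model)
        self.tc_data = tc_data
        self.ss_data = ss_data

        # Evaluation grid: dense grid over [0, 2T] merged with data times.
        grid = np.linspace(0.0, 2.0 * model.period, n_dense)
        tc_times = np.zeros(0)
        if tc_data is not None and len(tc_data):
            tc_times = tc_data.records["time_min"].to_numpy(dtype=float) * 60.0
        self.grid = np.union1d(grid, tc_times)
        nt = self.grid.size
        # Trapezoid weights normalized so (y * w).sum() is the time average.
        w = np.zeros(nt)
        dt = np.diff(self.grid)
        w[:-1] += dt / 2.0
        w[1:] += dt / 2.0
        self._avg_w = w / (self.grid[-1] - self.grid[0])

        gi = {g: i for i, g in enumerate(model.gene_names)}
        if tc_data is not None and len(tc_data):
            rec = tc_data.records
            self._tc_gene = rec["gene"].map(gi).to_numpy(dtype=int)
            self._tc_pos = np.searchsorted(self.grid, tc_times)
            self._tc_y = rec["log_ratio"].to_numpy(dtype=float)
        else:
            self._tc_gene = np.zeros(0, dtype=int)
            self._tc_pos = np.zeros(0, dtype=int)
            self._tc_y = np.zeros(0)
        if ss_data is not None and len(ss_data):
            rec = ss_data.records
            self._ss_gene = rec["gene"].map(gi).to_numpy(dtype=int)
            self._ss_is_protein = (rec["kind"] == "protein").to_numpy()
            self._ss_y = rec["log10_conc_uM"].to_numpy(dtype=float)
        else:
            self._ss_gene = np.zeros(0, dtype=int)
            self._ss_is_protein = np.zeros(0, dtype=bool)
            self._ss_y = np.zeros(0)

        # Index maps from the full sampling-scale vector into rate arrays.
        def idx(fmt: str) -> np.ndarray:
            return np.array([all_names.index(fmt.format(g)) for g in model.gene_names])

        self._i_beta = idx("beta_{}")
        self._i_deltap = idx("deltap_{}")
        self._i_m0 = idx("m0_{}")
        self._i_p0 = idx("p0_{}")
        self._i_deltam = all_names.index("deltam")
        self._i_kappa = all_names.index("kappa")
        self._i_stc = all_names.index("sigma_tc")
        self._i_sss = all_names.index("sigma_ss")
        self._t_norm = _log_t_norm(3.0)
        self._log_denom = 1.0 if log_base == "e" else _LN2

    # -- basic protocol ----------------------------------------------------
    @property
    def dim(self) -> int:
        return len(self.free_names)

    def sample_prior(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        return self.prior.sample(rng, size)

    def full_vector(self, theta: np.ndarray) -> ParameterVector:
        """Embed free coordinates into a full sampling-scale vector."""
        full = np.array(self._template)
        full[self._free_idx] = theta
        return ParameterVector(self.all_names, full)

    # -- evaluation --------------------------------------------------------
    def logp(self, theta: np.ndarray) -> tuple[float, float]:
        """Return ``(log_prior, log_likelihood)`` at free coordinates."""
        lps, lls = self.logp_batch(np.asarray(theta, dtype=float)[None, :])
        return float(lps[0]), float(lls[0])

    def logp_batch(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        thetas = np.asarray(thetas, dtype=float)
        C = thetas.shape[0]
        inside = self.prior.contains(thetas)
        lps = np.where(inside, self._lp_inside, -np.inf)
        lls = np.full(C, -np.inf)
        if not inside.any():
            return lps, lls
        full = np.tile(self._template, (C, 1))
        full[:, self._free_idx] = thetas
        if self.model.is_decoupled:
            lls_in = self._ll_decoupled(full[inside])
        else:
            lls_in = np.array([self._ll_general(row) for row in full[inside]])
        lls[inside] = lls_in
        return lps, lls

    def _ll_decoupled(self, full: np.ndarray) -> np.ndarray:
        lin = 10.0 ** full
        m, P = decoupled_solution(
            lin[:, self._i_beta],
            lin[:, [self._i_deltam]],
            lin[:, [self._i_kappa]],
            lin[:, self._i_deltap],
            lin[:, self._i_m0],
            lin[:, self._i_p0],
            self.grid,
        )
        return self._ll_from_series(m, P, lin[:, self._i_stc], lin[:, self._i_sss])

    def _ll_general(self, full_row: np.ndarray) -> float:
        pv = ParameterVector(self.all_names, full_row)
        traj = integrate(
            self.model, pv, rtol=self.rtol, atol=self.atol, n_dense=self.n_dense,
            eval_times=self.grid,
        )
        if not traj.success:
            return -math.inf
        # Re-grid onto the precomputed grid (integrate merges, so exact).
        if traj.t.size != self.grid.size:
            idx = np.searchsorted(traj.t, self.grid)
            y = traj.y[:, idx]
        else:
            y = traj.y
        G = self.model.n_genes
        lin = pv.to_linear()
        ll = self._ll_from_series(
            y[None, :G, :], y[None, G:, :],
            np.array([lin["sigma_tc"]]), np.array([lin["sigma_ss"]]),
        )
        return float(ll[0])

    def _ll_from_series(
        self, m: np.ndarray, P: np.ndarray, sigma_tc: np.ndarray, sigma_ss: np.ndarray
    ) -> np.ndarray:
        """Joint channel log-likelihood from species series (C, G, nt)."""
        C = m.shape[0]
        ll = np.zeros(C)
        mbar = (m * self._avg_w).sum(axis=-1)  # (C, G)
        bad = np.zeros(C, dtype=bool)
        if self._tc_y.size:
            mg = m[:, self._tc_gene, self._tc_pos]  # (C, R)
            bad |= np.any(mg <= 0, axis=-1) | np.any(mbar <= 0, axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                centers = (np.log(mg) - np.log(mbar[:, self._tc_gene])) / self._log_denom
                z = (self._tc_y - centers) / sigma_tc[:, None]
                ll += self._tc_y.size * (self._t_norm - np.log(sigma_tc)) - 2.0 * np.nansum(
                    np.log1p(z * z / 3.0), axis=-1
                )
        if self._ss_y.size:
            pbar = (P * self._avg_w).sum(axis=-1)
            avg = np.where(self._ss_is_protein, pbar[:, self._ss_gene], mbar[:, self._ss_gene])
            bad |= np.any(avg <= 0, axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (self._ss_y - np.log10(avg)) / sigma_ss[:, None]
                ll += self._ss_y.size * (self._t_norm - np.log(sigma_ss)) - 2.0 * np.nansum(
                    np.log1p(z * z / 3.0), axis=-1
                )
        ll[bad | ~np.isfinite(ll)] = -np.inf
        return ll

    def tempered(self, theta: np.ndarray, beta: float) -> float:
        """Tempered log-posterior ``log_prior + beta * log_likelihood``."""
        lp, ll = self.logp(theta)
        if lp == -math.inf:
            return -math.inf
        return lp if beta == 0.0 else lp + beta * ll
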