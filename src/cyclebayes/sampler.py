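"""Parallel-tempered MCMC with automated blocking and adaptive scaling.

The sampler runs a ladder of chains at inverse temperatures
``beta_i = (i / (n-1))^2`` tempering the likelihood only, so chain 0
samples the prior and chain n-1 the posterior.  At each iteration a random
choice is made (probability ``swap_prob``, default 0.99) between swapping a
random adjacent pair of chains and updating every chain with
``mh_steps`` (default 5) blocked Metropolis-Hastings steps.  Parameters are
blocked automatically by single-linkage clustering of the empirical
correlation of recent cold-chain draws; each block proposes from a
multivariate normal whose covariance is the empirical covariance of those
draws, with a scalar scale adapted (diminishing adaptation, frozen after
burn-in) toward a per-block acceptance rate of 0.23.

Replica identities travel with states through swaps, giving a ledger from
which prior-to-posterior round trips are counted as a mixing diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "LadderConfig",
    "ChainState",
    "BlockingPlan",
    "SamplerOutput",
    "DensityTarget",
    "make_ladder",
    "auto_block",
    "single_block_plan",
    "mh_block_update",
    "adapt_scale",
    "swap_move",
    "run_blocked_mh",
    "run_pt",
    "count_round_trips",
    "diagnostics",
]

TARGET_ACCEPTANCE = 0.23
SCALE_BOUNDS = (1e-6, 1e3)


@dataclass(frozen=True)
class LadderConfig:
    """Temperature ladder and per-iteration move mix."""

    betas: np.ndarray
    swap_prob: float = 0.99
    mh_steps: int = 5

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.size < 2 or b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ConfigurationError(
                "ladder must be strictly increasing from beta=0 to beta=1"
            )
        if not 0.0 < self.swap_prob < 1.0:
            raise ConfigurationError("swap probability must lie in (0, 1)")
        object.__setattr__(self, "betas", b)

    @property
    def n_chains(self) -> int:
        return self.betas.size


def make_ladder(n: int, swap_prob: float = 0.99, mh_steps: int = 5) -> LadderConfig:
    """Quadratic inverse-temperature ladder ``beta_i = (i/(n-1))^2``."""
    if n < 2:
        raise ConfigurationError("a ladder needs at least 2 chains")
    i = np.arange(n, dtype=float)
    return LadderConfig(betas=(i / (n - 1)) ** 2, swap_prob=swap_prob, mh_steps=mh_steps)


@dataclass
class ChainState:
    """Per-chain state: coordinates, cached densities, replica label."""

    theta: np.ndarray
    log_prior: float
    log_lik: float
    label: int = 0


@dataclass
class BlockingPlan:
    """Disjoint exhaustive parameter blocks with proposal shape per block.

    ``chols[b]`` is the Cholesky factor of the (regularized) empirical
    covariance of block ``b``; ``scales[b]`` the scalar multiplier subject
    to adaptation.
    """

    blocks: list[np.ndarray]
    chols: list[np.ndarray]
    scales: np.ndarray

    def __post_init__(self) -> None:
        idx = np.concatenate(self.blocks) if self.blocks else np.zeros(0, dtype=int)
        if len(np.unique(idx)) != idx.size:
            raise ConfigurationError("blocks must be disjoint")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def dim(self) -> int:
        return sum(len(b) for b in self.blocks)


def _default_scale(block_dim: int) -> float:
    return 2.38 / math.sqrt(block_dim)


def single_block_plan(dim: int, sd: np.ndarray | float = 1.0) -> BlockingPlan:
    """One block over all parameters with a diagonal proposal covariance."""
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (dim,))
    return BlockingPlan(
        blocks=[np.arange(dim)],
        chols=[np.diag(sd)],
        scales=np.array([_default_scale(dim)]),
    )


def auto_block(
    draws: np.ndarray, threshold: float = 0.5, min_samples: int = 100
) -> BlockingPlan:
    """Automatic blocking from recent draws.

    Parameters whose absolute empirical correlation reaches ``threshold``
    are merged by single-linkage clustering; each block's proposal
    covariance is the empirical covariance plus 1e-8 jitter.  With fewer
    than ``min_samples`` draws a single all-parameter block is returned;
    zero-variance parameters get singleton blocks with unit variance.
    """
    draws = np.asarray(draws, dtype=float)
    n, d = draws.shape
    if n < min_samples:
        return single_block_plan(d, sd=np.maximum(draws.std(axis=0), 1.0) if n > 1 else 1.0)
    var = draws.var(axis=0)
    degenerate = var <= 0
    active = np.flatnonzero(~degenerate)
    labels = np.zeros(d, dtype=int)
    if active.size > 1:
        corr = np.corrcoef(draws[:, active], rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = squareform(1.0 - np.abs(corr), checks=False)
        z = linkage(dist, method="single")
        labels[active] = fcluster(z, t=1.0 - threshold, criterion="distance")
    elif active.size == 1:
        labels[active] = 1
    next_label = labels.max() + 1
    for j in np.flatnonzero(degenerate):
        labels[j] = next_label
        next_label += 1

    blocks, chols, scales = [], [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        blocks.append(idx)
        if degenerate[idx].any():
            cov = np.eye(idx.size)
        else:
            cov = np.atleast_2d(np.cov(draws[:, idx], rowvar=False))
            cov = cov + 1e-8 * np.eye(idx.size)
        chols.append(np.linalg.cholesky(cov))
        scales.append(_default_scale(idx.size))
    return BlockingPlan(blocks=blocks, chols=chols, scales=np.array(scales))


def adapt_scale(
    scale: float,
    acc_rate: float,
    t: int,
    target: float = TARGET_ACCEPTANCE,
    exponent: float = 0.6,
) -> float:
    """Diminishing-adaptation update ``log s += t^-exponent * (acc - target)``.

    ``t`` is the adaptation round (1-based); the result is clamped to
    ``[1e-6, 1e3]``.
    """
    if t < 1:
        raise ValueError("adaptation round t must be >= 1")
    new = math.exp(math.log(scale) + t ** (-exponent) * (acc_rate - target))
    return float(min(max(new, SCALE_BOUNDS[0]), SCALE_BOUNDS[1]))


def swap_move(
    state_i: ChainState, state_j: ChainState, beta_i: float, beta_j: float,
    rng: np.random.Generator,
) -> bool:
    """Attempt a replica exchange between two adjacent chains.

    Accepts with probability ``min(1, exp((beta_i - beta_j) * (l_j - l_i)))``
    where ``l`` is the untempered log-likelihood; on acceptance the full
    states (including replica labels) are exchanged in place.
    """
    dll = state_j.log_lik - state_i.log_lik
    if math.isnan(dll):  # both -inf: free exchange
        logr = 0.0
    else:
        logr = (beta_i - beta_j) * dll
    if logr >= 0 or math.log(rng.uniform()) < logr:
        for attr in ("theta", "log_prior", "log_lik", "label"):
            a, b = getattr(state_i, attr), getattr(state_j, attr)
            setattr(state_i, attr, b)
            setattr(state_j, attr, a)
        return True
    return False


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

class DensityTarget:
    """Adapter exposing an arbitrary log-density with the sampler protocol.

    The density is treated as the *likelihood* (the prior term is flat), so
    it can be tempered directly.  ``sample_ref`` provides initial states.
    """

    def __init__(
        self,
        log_density: Callable[[np.ndarray], float],
        dim: int,
        sample_ref: Callable[[np.random.Generator], np.ndarray] | None = None,
        log_density_batch: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> None:
        self._f = log_density
        self._fb = log_density_batch
        self.dim = dim
        self._sample_ref = sample_ref

    def logp(self, theta: np.ndarray) -> tuple[float, float]:
        return 0.0, float(self._f(np.asarray(theta, dtype=float)))

    def logp_batch(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        thetas = np.asarray(thetas, dtype=float)
        if self._fb is not None:
            lls = np.atleast_1d(np.asarray(self._fb(thetas), dtype=float))
        else:
            lls = np.array([self._f(row) for row in thetas], dtype=float)
        return np.zeros(thetas.shape[0]), lls

    def sample_prior(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        if self._sample_ref is None:
            shape = (self.dim,) if size is None else (size, self.dim)
            return rng.standard_normal(shape)
        if size is None:
            return self._sample_ref(rng)
        return np.stack([self._sample_ref(rng) for _ in range(size)])


# ---------------------------------------------------------------------------
# Metropolis-Hastings kernels
# ---------------------------------------------------------------------------

def _tempered(lps: np.ndarray, lls: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """``lp + beta*ll`` with the convention ``0 * (-inf) = 0``."""
    out = np.array(lps, dtype=float)
    pos = betas > 0
    out[pos] += betas[pos] * lls[pos]
    return out


def _sweep(
    target,
    thetas: np.ndarray,
    lps: np.ndarray,
    lls: np.ndarray,
    betas: np.ndarray,
    plan: BlockingPlan,
    scales: np.ndarray,
    rng: np.random.Generator,
    acc_counts: np.ndarray,
    prop_counts: np.ndarray,
    chain_chols: list | None = None,
) -> None:
    """One MH step over all blocks for all chains, in place.

    ``scales`` has shape (n_chains, n_blocks); acceptance bookkeeping is
    accumulated into ``acc_counts``/``prop_counts`` of the same shape.
    ``chain_chols`` optionally supplies per-chain Cholesky factors
    (one (n_chains, d_b, d_b) array per block), overriding the shared
    per-block factor of ``plan``.
    """
    C = thetas.shape[0]
    for b, (idx, L) in enumerate(zip(plan.blocks, plan.chols)):
        z = rng.standard_normal((C, idx.size))
        if chain_chols is not None and chain_chols[b] is not None:
            step = scales[:, b, None] * np.einsum("cij,cj->ci", chain_chols[b], z)
        else:
            step = scales[:, b, None] * (z @ L.T)
        prop = thetas.copy()
        prop[:, idx] += step
        lp2, ll2 = target.logp_batch(prop)
        with np.errstate(invalid="ignore"):
            logr = _tempered(lp2, ll2, betas) - _tempered(lps, lls, betas)
        # Both sides -inf (e.g. invalid current state): move freely.
        logr = np.where(np.isnan(logr), 0.0, logr)
        accept = np.log(rng.uniform(size=C)) < logr
        if accept.any():
            thetas[accept] = prop[accept]
            lps[accept] = lp2[accept]
            lls[accept] = ll2[accept]
        acc_counts[:, b] += accept
        prop_counts[:, b] += 1


def mh_block_update(
    state: ChainState,
    plan: BlockingPlan,
    beta: float,
    rng: np.random.Generator,
    target=None,
) -> tuple[ChainState, np.ndarray]:
    """One blocked MH step on a single chain; returns per-block accept flags.

    The proposal is multivariate normal per block (symmetric, so plain
    Metropolis acceptance with the tempered posterior ratio).
    """
    if target is None:
        raise ValueError("mh_block_update requires the target posterior")
    thetas = state.theta[None, :].copy()
    lps = np.array([state.log_prior])
    lls = np.array([state.log_lik])
    acc = np.zeros((1, plan.n_blocks), dtype=int)
    props = np.zeros((1, plan.n_blocks), dtype=int)
    _sweep(target, thetas, lps, lls, np.array([beta]), plan,
           np.tile(plan.scales, (1, 1)), rng, acc, props)
    state.theta = thetas[0]
    state.log_prior = float(lps[0])
    state.log_lik = float(lls[0])
    return state, acc[0].astype(bool)


@dataclass
class MHResult:
    """Output of a single-chain adaptive blocked MH run."""

    draws: np.ndarray
    plan: BlockingPlan
    post_acceptance: np.ndarray  # per-block acceptance after freezing
    acc_history: list[np.ndarray] = field(default_factory=list)


def run_blocked_mh(
    target,
    n_adapt: int,
    n_post: int,
    seed: int,
    init: np.ndarray | None = None,
    adapt_every: int = 50,
    reblock_every: int = 2000,
    target_acc: float = TARGET_ACCEPTANCE,
) -> MHResult:
    """Adaptive blocked Metropolis-Hastings on a single (untempered) chain.

    Runs ``n_adapt`` adaptation steps (diminishing scale adaptation every
    ``adapt_every`` steps, re-blocking every ``reblock_every``), freezes the
    plan, then runs ``n_post`` further steps whose per-block acceptance is
    reported.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(init, dtype=float) if init is not None else target.sample_prior(rng)
    lp, ll = target.logp(theta)
    thetas = theta[None, :].copy()
    lps, lls = np.array([lp]), np.array([ll])
    betas = np.ones(1)
    plan = single_block_plan(target.dim)
    scales = plan.scales[None, :].copy()
    draws = np.empty((n_adapt + n_post, target.dim))
    acc = np.zeros((1, plan.n_blocks), dtype=int)
    props = np.zeros((1, plan.n_blocks), dtype=int)
    acc_history: list[np.ndarray] = []
    round_no = 0
    for t in range(n_adapt):
        _sweep(target, thetas, lps, lls, betas, plan, scales, rng, acc, props)
        draws[t] = thetas[0]
        if (t + 1) % adapt_every == 0:
            round_no += 1
            rates = acc[0] / np.maximum(props[0], 1)
            acc_history.append(rates.copy())
            for b in range(plan.n_blocks):
                scales[0, b] = adapt_scale(scales[0, b], rates[b], round_no, target_acc)
            acc[:] = 0
            props[:] = 0
        if (t + 1) % reblock_every == 0 and t + 1 < n_adapt:
            recent = draws[max(0, t + 1 - reblock_every): t + 1]
            plan = auto_block(recent)
            scales = plan.scales[None, :].copy()
            acc = np.zeros((1, plan.n_blocks), dtype=int)
            props = np.zeros((1, plan.n_blocks), dtype=int)
            round_no = 0
    # frozen phase
    acc = np.zeros((1, plan.n_blocks), dtype=int)
    props = np.zeros((1, plan.n_blocks), dtype=int)
    for t in range(n_post):
        _sweep(target, thetas, lps, lls, betas, plan, scales, rng, acc, props)
        draws[n_adapt + t] = thetas[0]
    plan.scales = scales[0].copy()
    post_acceptance = acc[0] / np.maximum(props[0], 1)
    return MHResult(draws=draws, plan=plan, post_acceptance=post_acceptance,
                    acc_history=acc_history)


# ---------------------------------------------------------------------------
# Parallel tempering driver
# ---------------------------------------------------------------------------

@dataclass
class SamplerOutput:
    """Posterior draws plus sampler bookkeeping for one PT run."""

    draws: np.ndarray            # (n_draws, dim) cold-chain subsampled draws
    log_prior: np.ndarray        # per draw
    log_lik: np.ndarray          # per draw
    names: tuple[str, ...]
    ledger: np.ndarray           # (n_iterations, n_chains) replica labels
    betas: np.ndarray
    acceptance: np.ndarray       # (n_chains, n_blocks) final MH acceptance
    swap_attempts: int
    swap_accepts: int
    acc_history: list[np.ndarray]
    scale_history: list[np.ndarray]
    plan: BlockingPlan | None
    seed: int
    settings: dict

    @property
    def swap_rate(self) -> float:
        return self.swap_accepts / max(self.swap_attempts, 1)


def run_pt(
    target,
    ladder: LadderConfig,
    burn_in: int,
    n_samples: int,
    subsample: int,
    seed: int,
    adapt_every: int = 50,
    reblock_every: int = 10_000,
    names: Sequence[str] | None = None,
    checkpoint_every: int | None = None,
) -> SamplerOutput:
    """Parallel-tempered MCMC with the choose-swap-or-update iteration loop.

    Each of the ``burn_in + n_samples`` iterations either swaps a random
    adjacent chain pair (probability ``ladder.swap_prob``) or applies
    ``ladder.mh_steps`` blocked MH steps to every chain.  Scale adaptation
    and re-blocking happen only during burn-in; afterwards the proposal is
    frozen.  Cold-chain (beta=1) states are recorded every ``subsample``
    post-burn-in iterations.  Fully reproducible given ``seed``.
    """
    if burn_in < 0 or n_samples <= 0 or subsample <= 0:
        raise ConfigurationError("burn_in, n_samples and subsample must be positive")
    rng = np.random.default_rng(seed)
    C = ladder.n_chains
    betas = ladder.betas
    dim = target.dim

    thetas = target.sample_prior(rng, C)
    lps, lls = target.logp_batch(thetas)
    if np.any(np.isnan(lls)) or np.any(np.isnan(lps)):
        raise ValueError("posterior returned NaN; -inf is the only legal failure value")
    labels = np.arange(C)

    plan = single_block_plan(
        dim, sd=getattr(target, "prior", None).width / 10.0
        if getattr(target, "prior", None) is not None else 1.0,
    )
    scales = np.tile(plan.scales, (C, 1))
    acc = np.zeros((C, plan.n_blocks), dtype=int)
    props = np.zeros((C, plan.n_blocks), dtype=int)
    acc_history: list[np.ndarray] = []
    scale_history: list[np.ndarray] = []
    round_no = 0

    total = burn_in + n_samples
    ledger = np.empty((total, C), dtype=np.int16)
    n_keep = n_samples // subsample
    draws = np.empty((n_keep, dim))
    draw_lp = np.empty(n_keep)
    draw_ll = np.empty(n_keep)
    kept = 0
    swap_attempts = 0
    swap_accepts = 0
    update_iters = 0
    recent: list[np.ndarray] = []  # per-update-iteration (C, dim) snapshots
    chain_chols: list | None = None

    for t in range(total):
        if rng.uniform() < ladder.swap_prob:
            i = int(rng.integers(0, C - 1))
            swap_attempts += 1
            dll = lls[i + 1] - lls[i]
            if math.isnan(dll):
                logr = 0.0
            else:
                logr = (betas[i] - betas[i + 1]) * dll
            if logr >= 0 or math.log(rng.uniform()) < logr:
                swap_accepts += 1
                thetas[[i, i + 1]] = thetas[[i + 1, i]]
                lps[[i, i + 1]] = lps[[i + 1, i]]
                lls[[i, i + 1]] = lls[[i + 1, i]]
                labels[[i, i + 1]] = labels[[i + 1, i]]
        else:
            for _ in range(ladder.mh_steps):
                _sweep(target, thetas, lps, lls, betas, plan, scales, rng, acc,
                       props, chain_chols)
            update_iters += 1
            in_burn = t < burn_in
            if in_burn:
                recent.append(thetas.copy())
                if len(recent) > 4000:
                    del recent[:2000]
                if update_iters % adapt_every == 0:
                    round_no += 1
                    rates = acc / np.maximum(props, 1)
                    acc_history.append(rates.copy())
                    scale_history.append(scales.copy())
                    for c in range(C):
                        for b in range(plan.n_blocks):
                            scales[c, b] = adapt_scale(scales[c, b], rates[c, b], round_no)
                    acc[:] = 0
                    props[:] = 0
        if t + 1 < burn_in and (t + 1) % reblock_every == 0:
            window = np.asarray(recent[-2000:])  # (n, C, dim)
            if window.shape[0] >= 100:
                # Block structure from the cold chain; proposal covariance
                # per chain from that chain's own preceding samples.
                # Preserve each chain's learned scale multiplier (relative
                # to the default) so adaptation resumes near its fixed point.
                old_default = np.array([_default_scale(len(b)) for b in plan.blocks])
                mult = np.exp(np.median(np.log(scales / old_default), axis=1))
                plan = auto_block(window[:, -1, :])
                chain_chols = []
                for idx in plan.blocks:
                    mats = np.empty((C, idx.size, idx.size))
                    for c in range(C):
                        cov = np.atleast_2d(np.cov(window[:, c, idx], rowvar=False))
                        cov = cov + 1e-8 * np.eye(idx.size)
                        try:
                            mats[c] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            mats[c] = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-8)))
                    chain_chols.append(mats)
                scales = np.outer(mult, plan.scales)
                acc = np.zeros((C, plan.n_blocks), dtype=int)
                props = np.zeros((C, plan.n_blocks), dtype=int)
                round_no = 0
        ledger[t] = labels
        if checkpoint_every and (t + 1) % checkpoint_every == 0:
            _, rt = count_round_trips(ledger[: t + 1])
            rates = acc / np.maximum(props, 1)
            logger.info(
                "checkpoint iter=%d mh_acceptance=%.3f swap_rate=%.3f round_trips=%d",
                t + 1, float(rates.mean()),
                swap_accepts / max(swap_attempts, 1), rt,
            )
        if t >= burn_in and (t - burn_in + 1) % subsample == 0 and kept < n_keep:
            draws[kept] = thetas[-1]
            draw_lp[kept] = lps[-1]
            draw_ll[kept] = lls[-1]
            kept += 1

    acceptance = acc / np.maximum(props, 1)
    return SamplerOutput(
        draws=draws[:kept],
        log_prior=draw_lp[:kept],
        log_lik=draw_ll[:kept],
        names=tuple(names) if names is not None
        else tuple(getattr(target, "free_names", tuple(f"p{i}" for i in range(dim)))),
        ledger=ledger,
        betas=betas.copy(),
        acceptance=acceptance,
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        acc_history=acc_history,
        scale_history=scale_history,
        plan=plan,
        seed=seed,
        settings={
            "n_chains": C,
            "swap_prob": ladder.swap_prob,
            "mh_steps": ladder.mh_steps,
            "burn_in": burn_in,
            "n_samples": n_samples,
            "subsample": subsample,
            "adapt_every": adapt_every,
            "reblock_every": reblock_every,
        },
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def count_round_trips(ledger: np.ndarray) -> tuple[np.ndarray, int]:
    """Count completed prior-to-posterior-and-back round trips per replica.

    ``ledger[t, c]`` holds the replica label at chain ``c`` during iteration
    ``t``.  A round trip is one full cycle chain 0 -> chain n-1 -> chain 0
    of a replica's position.  Returns (per-replica counts, total).
    """
    ledger = np.asarray(ledger)
    T, C = ledger.shape
    # positions[t, r] = chain index occupied by replica r at iteration t
    positions = np.empty_like(ledger, dtype=np.int64)
    rows = np.arange(T)[:, None]
    positions[rows, ledger.astype(np.int64)] = np.arange(C)[None, :]
    counts = np.zeros(C, dtype=int)
    for r in range(C):
        pos = positions[:, r]
        # event sequence: 0 at prior chain, 1 at posterior chain
        ev = np.where(pos == 0, 0, np.where(pos == C - 1, 1, -1))
        ev = ev[ev >= 0]
        if ev.size == 0:
            continue
        changes = np.flatnonzero(np.diff(ev) != 0)
        compressed = np.concatenate([[ev[0]], ev[changes + 1]])
        first_bottom = np.flatnonzero(compressed == 0)
        if first_bottom.size == 0:
            continue
        # after the first prior-chain touch the sequence alternates 0,1,0,1...
        counts[r] = (compressed.size - 1 - first_bottom[0]) // 2
    return counts, int(counts.sum())


def diagnostics(output: SamplerOutput, min_draws: int = 10) -> dict:
    """Per-parameter trace diagnostics: ESS, lag-1 autocorrelation, flags."""
    import arviz as az

    draws = output.draws
    if draws.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} draws for diagnostics")
    result = {}
    for j, name in enumerate(output.names):
        x = draws[:, j]
        degenerate = bool(np.var(x) == 0)
        if degenerate:
            result[name] = {"ess": 0.0, "lag1_acf": np.nan, "degenerate": True}
            continue
        ess = float(az.ess(x[None, :]))
        acf = az.autocorr(x)
        result[name] = {
            "ess": ess,
            "lag1_acf": float(acf[1]) if acf.size > 1 else np.nan,
            "degenerate": False,
        }
    return result
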