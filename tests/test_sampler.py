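"""Ladder, blocking, adaptive MH kernel, swaps, PT driver and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from cyclebayes.model import ConfigurationError
from cyclebayes.sampler import (
    ChainState,
    DensityTarget,
    SamplerOutput,
    adapt_scale,
    auto_block,
    count_round_trips,
    diagnostics,
    make_ladder,
    mh_block_update,
    run_blocked_mh,
    run_pt,
    single_block_plan,
    swap_move,
)


class TestLadder:
    def test_quadratic_formula(self):
        lad = make_ladder(32)
        assert lad.betas[0] == 0.0 and lad.betas[-1] == 1.0
        assert lad.betas[16] == pytest.approx((16 / 31) ** 2)

    def test_two_chains(self):
        assert make_ladder(2).betas.tolist() == [0.0, 1.0]

    def test_too_few_chains(self):
        with pytest.raises(ConfigurationError):
            make_ladder(1)


class TestAutoBlock:
    def test_independent_variables_mostly_singletons(self):
        """Independent coordinates should rarely be merged."""
        frac = []
        for seed in range(5):
            draws = np.random.default_rng(seed).standard_normal((1000, 8))
            plan = auto_block(draws)
            frac.append(sum(len(b) == 1 for b in plan.blocks) / 8)
        assert np.mean(frac) >= 0.9

    def test_duplicated_variable_merged(self, rng):
        x = rng.standard_normal(1000)
        draws = np.column_stack([x, x + 1e-6 * rng.standard_normal(1000),
                                 rng.standard_normal(1000)])
        plan = auto_block(draws)
        joint = [set(b.tolist()) for b in plan.blocks]
        assert {0, 1} in joint

    def test_small_sample_fallback_single_block(self, rng):
        plan = auto_block(rng.standard_normal((50, 6)))
        assert plan.n_blocks == 1 and len(plan.blocks[0]) == 6

    def test_degenerate_parameter_gets_singleton_unit_block(self, rng):
        draws = np.column_stack([rng.standard_normal(500), np.full(500, 2.0)])
        plan = auto_block(draws)
        block_of_1 = [b for b in plan.blocks if 1 in b.tolist()][0]
        assert len(block_of_1) == 1
        i = plan.blocks.index(block_of_1)
        assert plan.chols[i][0, 0] == pytest.approx(1.0)

    def test_blocks_disjoint_exhaustive(self, rng):
        draws = rng.standard_normal((300, 7))
        plan = auto_block(draws)
        idx = np.sort(np.concatenate(plan.blocks))
        assert idx.tolist() == list(range(7))


class TestAdaptScale:
    def test_fixed_point(self):
        assert adapt_scale(1.3, 0.23, t=5) == pytest.approx(1.3)

    def test_monotone(self):
        assert adapt_scale(1.0, 1.0, t=1) > 1.0
        assert adapt_scale(1.0, 0.0, t=1) < 1.0

    def test_clamped(self):
        assert adapt_scale(1e-6, 0.0, t=1) == 1e-6
        assert adapt_scale(1e3, 1.0, t=1) == 1e3

    def test_long_run_acceptance_converges_on_gaussian(self):
        """Adaptation drives acceptance to 0.23 +/- 0.05 on a 3-d Gaussian."""
        cov = np.diag([1.0, 4.0, 0.25])
        mvn = stats.multivariate_normal(mean=np.zeros(3), cov=cov)
        target = DensityTarget(mvn.logpdf, 3, log_density_batch=mvn.logpdf)
        res = run_blocked_mh(target, n_adapt=8000, n_post=6000, seed=3)
        assert abs(res.post_acceptance.mean() - 0.23) < 0.05


class TestMHKernel:
    def test_two_d_gaussian_moments(self):
        cov = np.array([[1.0, 0.8], [0.8, 2.0]])
        mvn = stats.multivariate_normal(mean=[1.0, -2.0], cov=cov)
        target = DensityTarget(mvn.logpdf, 2, log_density_batch=mvn.logpdf)
        res = run_blocked_mh(target, n_adapt=6000, n_post=14000, seed=9)
        draws = res.draws[6000:]
        ess = 14000 / 40  # conservative autocorrelation allowance
        for j, (mu, var) in enumerate(zip([1.0, -2.0], np.diag(cov))):
            se = math.sqrt(var / ess)
            assert abs(draws[:, j].mean() - mu) < 3 * se

    def test_flat_target_accepts_in_box(self):
        """On a flat density every proposal is accepted."""
        target = DensityTarget(lambda x: 0.0, 3,
                               log_density_batch=lambda X: np.zeros(X.shape[0]))
        state = ChainState(theta=np.zeros(3), log_prior=0.0, log_lik=0.0)
        plan = single_block_plan(3, sd=0.1)
        rng = np.random.default_rng(0)
        n_acc = 0
        for _ in range(200):
            _, flags = mh_block_update(state, plan, 1.0, rng, target=target)
            n_acc += int(flags[0])
        assert n_acc == 200

    def test_small_scale_limit_accepts(self):
        mvn = stats.multivariate_normal(mean=np.zeros(2))
        target = DensityTarget(mvn.logpdf, 2, log_density_batch=mvn.logpdf)
        state = ChainState(theta=np.zeros(2), log_prior=0.0,
                           log_lik=float(mvn.logpdf(np.zeros(2))))
        plan = single_block_plan(2, sd=1e-9)
        rng = np.random.default_rng(1)
        accepted = sum(
            int(mh_block_update(state, plan, 1.0, rng, target=target)[1][0])
            for _ in range(200)
        )
        assert accepted >= 198


class TestDetailedBalance:
    def test_three_state_reversibility(self):
        """Reversibility of the block-update kernel: on a 1-d Gaussian
        chain coarse-grained to 3 states, forward and backward transition
        counts between any pair of states agree within MC error."""
        mvn = stats.norm()

        def batch(X):
            return mvn.logpdf(X[:, 0])

        target = DensityTarget(lambda x: float(mvn.logpdf(x[0])), 1,
                               sample_ref=lambda r: r.standard_normal(1),
                               log_density_batch=batch)
        res = run_blocked_mh(target, n_adapt=4000, n_post=40_000, seed=17)
        x = res.draws[4000:, 0]
        states = np.digitize(x, [-0.5, 0.5])
        counts = np.zeros((3, 3))
        for a, b in zip(states[:-1], states[1:]):
            counts[a, b] += 1
        for i in range(3):
            for j in range(i + 1, 3):
                n = counts[i, j] + counts[j, i]
                assert abs(counts[i, j] - counts[j, i]) < 4 * math.sqrt(n)


class TestSwapMove:
    def test_equal_likelihoods_always_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = ChainState(np.array([0.0]), 0.0, -5.0, label=0)
            b = ChainState(np.array([1.0]), 0.0, -5.0, label=1)
            assert swap_move(a, b, 0.3, 0.7, rng)
            assert a.label == 1 and b.label == 0

    def test_equal_betas_always_swap(self):
        rng = np.random.default_rng(0)
        a = ChainState(np.array([0.0]), 0.0, -50.0, label=0)
        b = ChainState(np.array([1.0]), 0.0, -2.0, label=1)
        assert swap_move(a, b, 0.5, 0.5, rng)

    def test_ladder_marginal_matches_direct_sampling(self):
        """Cold-chain marginal of PT equals direct draws on a conjugate toy.

        Likelihood N(0, 1) in one coordinate with a uniform box prior; the
        beta=1 marginal is a truncated standard normal.
        """
        lo, hi = -8.0, 8.0

        def logpdf_batch(X):
            out = -0.5 * X[:, 0] ** 2
            out[(X[:, 0] < lo) | (X[:, 0] > hi)] = -np.inf
            return out

        target = DensityTarget(lambda x: float(logpdf_batch(x[None])[0]), 1,
                               sample_ref=lambda r: r.uniform(lo, hi, 1),
                               log_density_batch=logpdf_batch)
        out = run_pt(target, make_ladder(6, swap_prob=0.5), burn_in=4000,
                     n_samples=40_000, subsample=40, seed=4)
        ks = stats.kstest(out.draws[:, 0], stats.norm.cdf)
        assert ks.pvalue > 0.01


class TestRunPT:
    def test_bitwise_determinism(self, reduced_problem):
        post, truth, _ = reduced_problem
        lad = make_ladder(6, swap_prob=0.8)
        a = run_pt(post, lad, burn_in=500, n_samples=2000, subsample=10, seed=42)
        b = run_pt(post, lad, burn_in=500, n_samples=2000, subsample=10, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.ledger, b.ledger)
        assert a.swap_accepts == b.swap_accepts

    def test_prior_chain_uniform_in_box(self):
        """With no data the posterior is the prior: draws are uniform."""
        from cyclebayes.model import build_reduced_model, default_prior
        from cyclebayes.likelihood import Posterior

        model = build_reduced_model()
        post = Posterior(model, default_prior(model),
                         fixed={"sigma_tc": -0.7, "sigma_ss": -0.7})
        out = run_pt(post, make_ladder(2, swap_prob=0.3), burn_in=2000,
                     n_samples=60_000, subsample=150, seed=8)
        for j, name in enumerate(post.free_names):
            lo = post.prior.lower[j]
            hi = post.prior.upper[j]
            ks = stats.kstest(out.draws[:, j], stats.uniform(lo, hi - lo).cdf)
            assert ks.pvalue > 0.01, name

    def test_one_d_conjugate_posterior_mean(self):
        """Gaussian likelihood x wide uniform prior: mean within 3 SE."""
        obs = 1.7

        def batch(X):
            out = -0.5 * (X[:, 0] - obs) ** 2
            out[np.abs(X[:, 0]) > 50] = -np.inf
            return out

        target = DensityTarget(lambda x: float(batch(x[None])[0]), 1,
                               sample_ref=lambda r: r.uniform(-50, 50, 1),
                               log_density_batch=batch)
        out = run_pt(target, make_ladder(4, swap_prob=0.5), burn_in=3000,
                     n_samples=30_000, subsample=30, seed=2)
        ess = out.draws.shape[0] / 10
        assert abs(out.draws[:, 0].mean() - obs) < 3 / math.sqrt(ess)

    def test_adaptation_frozen_after_burn_in(self, reduced_problem):
        post, truth, _ = reduced_problem
        lad = make_ladder(4, swap_prob=0.5)
        short = run_pt(post, lad, burn_in=1000, n_samples=1000, subsample=10, seed=5)
        long = run_pt(post, lad, burn_in=1000, n_samples=8000, subsample=10, seed=5)
        # adaptation events happen only during burn-in, so extending the
        # sampling phase must not add scale updates
        assert len(long.scale_history) == len(short.scale_history)

    def test_nan_posterior_raises(self):
        target = DensityTarget(lambda x: float("nan"), 1,
                               sample_ref=lambda r: r.uniform(-1, 1, 1),
                               log_density_batch=lambda X: np.full(X.shape[0], np.nan))
        with pytest.raises(ValueError, match="NaN"):
            run_pt(target, make_ladder(2), burn_in=10, n_samples=10, subsample=1, seed=0)


def brute_force_round_trips(positions):
    """Direct state-machine enumeration over one replica's chain positions."""
    n_top = positions.max()  # top chain index must be C-1; caller guarantees
    count = 0
    state = "seek_bottom"
    for p in positions:
        if state == "seek_bottom" and p == 0:
            state = "seek_top"
        elif state == "seek_top" and p == n_top:
            state = "seek_home"
        elif state == "seek_home" and p == 0:
            count += 1
            state = "seek_top"
    return count


class TestRoundTrips:
    def _ledger_from_positions(self, pos_matrix):
        """positions (T, R) -> ledger (T, C) of labels."""
        T, R = pos_matrix.shape
        ledger = np.empty((T, R), dtype=np.int16)
        for t in range(T):
            for r in range(R):
                ledger[t, pos_matrix[t, r]] = r
        return ledger

    def test_single_cycle(self):
        # replica 0 travels 0 -> top -> 0 once; others fill the ladder
        posm = np.array([
            [0, 1, 2],
            [1, 0, 2],
            [2, 0, 1],
            [1, 0, 2],
            [0, 1, 2],
        ])
        per, total = count_round_trips(self._ledger_from_positions(posm))
        assert per[0] == 1 and total == 1

    def test_never_reaching_top_counts_zero(self):
        posm = np.array([[0, 1, 2]] * 10)
        ledger = self._ledger_from_positions(posm)
        per, total = count_round_trips(ledger)
        assert total == 0

    def test_random_sequences_match_brute_force(self, rng):
        C, T = 5, 400
        for _ in range(10):
            # random adjacent-swap dynamics to generate a valid ledger
            pos = np.arange(C)
            history = [pos.copy()]
            for _t in range(T - 1):
                i = rng.integers(0, C - 1)
                if rng.uniform() < 0.7:
                    j0, j1 = np.flatnonzero(pos == i)[0], np.flatnonzero(pos == i + 1)[0]
                    pos[j0], pos[j1] = pos[j1], pos[j0]
                history.append(pos.copy())
            posm = np.asarray(history)
            ledger = self._ledger_from_positions(posm)
            per, total = count_round_trips(ledger)
            for r in range(C):
                assert per[r] == brute_force_round_trips(posm[:, r])
            assert total == per.sum()


class TestDiagnostics:
    def _output(self, draws):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim == 1:
            draws = draws[:, None]
        n = draws.shape[0]
        return SamplerOutput(
            draws=draws, log_prior=np.zeros(n), log_lik=np.zeros(n),
            names=tuple(f"p{i}" for i in range(draws.shape[1])),
            ledger=np.zeros((n, 2), dtype=np.int16), betas=np.array([0.0, 1.0]),
            acceptance=np.zeros((2, 1)), swap_attempts=0, swap_accepts=0,
            acc_history=[], scale_history=[], plan=None, seed=0, settings={},
        )

    def test_iid_draws_low_lag1(self, rng):
        n = 4000
        d = diagnostics(self._output(rng.standard_normal(n)))
        assert abs(d["p0"]["lag1_acf"]) < 3 / math.sqrt(n)

    def test_ar1_ess_ratio(self, rng):
        rho, n = 0.9, 20000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        d = diagnostics(self._output(x))
        expected = n * (1 - rho) / (1 + rho)
        assert abs(d["p0"]["ess"] - expected) / expected < 0.3

    def test_constant_chain_flagged(self):
        d = diagnostics(self._output(np.full(100, 3.0)))
        assert d["p0"]["degenerate"]

    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            diagnostics(self._output(rng.standard_normal(5)))
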