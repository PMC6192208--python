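"""Student-t densities, channel likelihoods, prior and tempering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyclebayes.likelihood import (
    DataError,
    Posterior,
    SteadyStateDataset,
    TimeCourseDataset,
    absolute_loglik,
    log_posterior_tempered,
    log_prior,
    log_t_density,
    relative_loglik,
)
from cyclebayes.model import (
    ParameterVector,
    PriorSpec,
    build_reduced_model,
    default_prior,
)
from cyclebayes.simulate import integrate, time_average
from cyclebayes.synth import SynthDesign, gen_steady_state, gen_time_course, preset_truth


class TestLogTDensity:
    def test_mode_closed_form(self):
        """Standard t(3) density at the mode is 2 / (pi sqrt(3))."""
        assert log_t_density(0.0, 0.0, 1.0) == pytest.approx(math.log(2.0 / (math.pi * math.sqrt(3.0))))

    def test_symmetry(self):
        for d in (0.1, 1.0, 7.3):
            assert log_t_density(2.0 + d, 2.0, 0.5) == pytest.approx(
                log_t_density(2.0 - d, 2.0, 0.5)
            )

    def test_scale_change_of_variables(self, rng):
        x = rng.normal(size=20)
        s, c = 0.37, 1.2
        direct = log_t_density(x, c, s)
        standard = log_t_density((x - c) / s, 0.0, 1.0) - math.log(s)
        assert np.allclose(direct, standard, atol=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=50)
        ours = log_t_density(x, 0.3, 0.8, df=3)
        ref = stats.t.logpdf(x, df=3, loc=0.3, scale=0.8)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_t_density(0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def reduced_data():
    model = build_reduced_model()
    truth = preset_truth(model)
    design = SynthDesign(model=model, truth=truth, seed=42)
    tc = gen_time_course(design)
    ss = gen_steady_state(design)
    traj = integrate(model, truth, eval_times=tc.records["time_min"].to_numpy() * 60.0)
    return model, truth, tc, ss, traj


def naive_relative_loglik(traj, data, sigma):
    """Brute-force per-record loop with scipy's t density."""
    total = 0.0
    for rec in data.records.itertuples(index=False):
        species = f"mRNA_{rec.gene}"
        mbar = time_average(traj, species)
        m = float(traj.at_times(species, np.array([rec.time_min * 60.0]))[0])
        total += stats.t.logpdf(rec.log_ratio, df=3, loc=math.log(m / mbar), scale=sigma)
    return total


def naive_absolute_loglik(traj, data, sigma):
    total = 0.0
    for rec in data.records.itertuples(index=False):
        avg = time_average(traj, f"{rec.kind}_{rec.gene}")
        total += stats.t.logpdf(rec.log10_conc_uM, df=3, loc=math.log10(avg), scale=sigma)
    return total


class TestChannelLikelihoods:
    def test_relative_matches_naive_loop(self, reduced_data):
        model, truth, tc, ss, traj = reduced_data
        ours = relative_loglik(traj, tc, 0.2)
        assert ours == pytest.approx(naive_relative_loglik(traj, tc, 0.2), abs=1e-10)

    def test_absolute_matches_naive_loop(self, reduced_data):
        model, truth, tc, ss, traj = reduced_data
        ours = absolute_loglik(traj, ss, 0.3)
        assert ours == pytest.approx(naive_absolute_loglik(traj, ss, 0.3), abs=1e-10)

    def test_record_order_invariance(self, reduced_data, rng):
        model, truth, tc, ss, traj = reduced_data
        shuffled = TimeCourseDataset(
            tc.records.sample(frac=1.0, random_state=7), tc.native_periods
        )
        assert relative_loglik(traj, shuffled, 0.2) == pytest.approx(
            relative_loglik(traj, tc, 0.2), rel=1e-12
        )

    def test_relative_invariant_to_trajectory_scaling(self, reduced_data):
        """Log-ratio to the trajectory's own time average cancels scale."""
        model, truth, tc, ss, traj = reduced_data
        scaled = type(traj)(t=traj.t, y=traj.y * 37.5, species=traj.species,
                            period=traj.period)
        assert relative_loglik(scaled, tc, 0.2) == pytest.approx(
            relative_loglik(traj, tc, 0.2), rel=1e-12
        )

    def test_constant_trajectory_zero_centers(self, reduced_data):
        model, truth, tc, ss, traj = reduced_data
        const = type(traj)(t=traj.t, y=np.full_like(traj.y, 2.0),
                           species=traj.species, period=traj.period)
        y = tc.records["log_ratio"].to_numpy()
        expected = float(np.sum(log_t_density(y, 0.0, 0.2)))
        assert relative_loglik(const, tc, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_unknown_gene_named_in_error(self, reduced_data):
        model, truth, tc, ss, traj = reduced_data
        bad = tc.records.copy()
        bad.loc[0, "gene"] = "NOPE"
        with pytest.raises(DataError, match="NOPE"):
            relative_loglik(traj, TimeCourseDataset(bad, tc.native_periods), 0.2)

    def test_failed_simulation_gives_minus_inf(self, reduced_data):
        model, truth, tc, ss, traj = reduced_data
        failed = type(traj)(t=traj.t, y=np.full_like(traj.y, np.nan),
                            species=traj.species, period=traj.period, success=False)
        assert relative_loglik(failed, tc, 0.2) == -math.inf
        assert absolute_loglik(failed, ss, 0.2) == -math.inf


class TestLogPrior:
    def test_constant_inside_box(self):
        prior = PriorSpec(("a", "b"), np.array([0.0, -1.0]), np.array([4.0, 1.0]))
        pv1 = ParameterVector(("a", "b"), np.array([0.5, 0.0]))
        pv2 = ParameterVector(("a", "b"), np.array([3.9, -0.9]))
        expected = -(math.log(4.0) + math.log(2.0))
        assert log_prior(pv1, prior) == pytest.approx(expected)
        assert log_prior(pv2, prior) == pytest.approx(expected)

    def test_outside_box_minus_inf(self):
        prior = PriorSpec(("a",), np.array([0.0]), np.array([1.0]))
        assert log_prior(ParameterVector(("a",), np.array([1.01])), prior) == -math.inf


class TestTemperedPosterior:
    def test_beta_endpoints_and_linearity(self, reduced_data):
        model, truth, tc, ss, _ = reduced_data
        prior = default_prior(model)
        lp0 = log_posterior_tempered(truth, model, prior, tc, ss, beta=0.0)
        lp1 = log_posterior_tempered(truth, model, prior, tc, ss, beta=1.0)
        lph = log_posterior_tempered(truth, model, prior, tc, ss, beta=0.5)
        assert lp0 == pytest.approx(log_prior(truth, prior))
        assert lph == pytest.approx((lp0 + lp1) / 2.0, rel=1e-9)

    def test_invalid_beta_rejected(self, reduced_data):
        model, truth, tc, ss, _ = reduced_data
        with pytest.raises(ValueError, match="beta"):
            log_posterior_tempered(truth, model, default_prior(model), tc, ss, beta=1.5)


class TestFastPosterior:
    def test_matches_reference_composition(self, reduced_data):
        """Vectorized posterior equals prior + sum of channel likelihoods."""
        model, truth, tc, ss, traj = reduced_data
        prior = default_prior(model)
        post = Posterior(model, prior, tc_data=tc, ss_data=ss)
        theta = np.array([truth[n] for n in post.free_names])
        lp, ll = post.logp(theta)
        lin = truth.to_linear()
        ref_ll = relative_loglik(traj, tc, lin["sigma_tc"]) + absolute_loglik(
            traj, ss, lin["sigma_ss"]
        )
        assert ll == pytest.approx(ref_ll, rel=1e-9)
        assert lp == pytest.approx(log_prior(truth, prior))

    def test_channel_separability(self, reduced_data):
        model, truth, tc, ss, _ = reduced_data
        prior = default_prior(model)
        both = Posterior(model, prior, tc_data=tc, ss_data=ss)
        only_tc = Posterior(model, prior, tc_data=tc)
        only_ss = Posterior(model, prior, ss_data=ss)
        theta = np.array([truth[n] for n in both.free_names])
        # grids differ slightly (data times are merged into the quadrature
        # grid only when the channel is present), so match to quadrature
        # accuracy rather than machine precision
        assert both.logp(theta)[1] == pytest.approx(
            only_tc.logp(theta)[1] + only_ss.logp(theta)[1], rel=1e-6
        )

    def test_outside_prior_minus_inf(self, reduced_data):
        model, truth, tc, ss, _ = reduced_data
        post = Posterior(model, default_prior(model), tc_data=tc)
        theta = np.array([truth[n] for n in post.free_names])
        theta[0] = 99.0
        lp, ll = post.logp(theta)
        assert lp == -math.inf

    def test_batch_matches_single(self, reduced_data, rng):
        model, truth, tc, ss, _ = reduced_data
        post = Posterior(model, default_prior(model), tc_data=tc, ss_data=ss)
        thetas = post.sample_prior(rng, 8)
        lps, lls = post.logp_batch(thetas)
        for i in range(8):
            lp, ll = post.logp(thetas[i])
            assert lp == pytest.approx(lps[i])
            assert ll == pytest.approx(lls[i], rel=1e-12)
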