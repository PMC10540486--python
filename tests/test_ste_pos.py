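import math

import numpy as np
import pytest
from scipy import stats

from ste_trials import (
    alpha_from_prior_mean,
    conditional_mles,
    conditional_power_exact,
    probability_of_success,
    sample_prior_product,
    transition_posterior,
)
from ste_trials.datasets import example_design
from ste_trials.ste_pos import TransitionPosterior, TransitionPrior, decide_pos
from ste_trials.trial_core import StePosRule

from test_ste_cp import make_snapshot


def posterior_mean_oracle(shape, rate, n, x):
    """Closed-form posterior mean, independent of the grid implementation.

    Expanding ``(1 - e^{-u})^{n-x}`` binomially turns the posterior of
    ``u = -log p`` into a signed mixture of Gamma(shape, rate + x + j)
    terms, so E[p] = E[e^{-u}] is a ratio of alternating sums.  Stable for
    the small ``n - x`` used in these tests.
    """
    num = den = 0.0
    for j in range(n - x + 1):
        c = (-1.0) ** j * math.comb(n - x, j)
        num += c * (rate + x + j + 1.0) ** (-shape)
        den += c * (rate + x + j) ** (-shape)
    return num / den


class TestAlphaFromPriorMean:
    def test_scenario_values(self):
        assert round(alpha_from_prior_mean(0.317), 3) == 0.464
        assert alpha_from_prior_mean(0.5) == pytest.approx(1.0)
        assert alpha_from_prior_mean(0.8) == pytest.approx(4.0)

    def test_round_trip(self):
        assert 0.464 / 1.464 == pytest.approx(0.317, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_degenerate(self, bad):
        with pytest.raises(ValueError):
            alpha_from_prior_mean(bad)


class TestTransitionPrior:
    def test_for_long_term_mean(self):
        prior = TransitionPrior.for_long_term_mean(4, 0.317)
        assert prior.shape == pytest.approx(0.25)
        assert prior.rate == pytest.approx(0.317 / 0.683)

    def test_unit_rate(self):
        prior = TransitionPrior.unit_rate(4)
        assert prior.rate == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            TransitionPrior(shape=0.0, rate=1.0)
        with pytest.raises(ValueError):
            TransitionPrior(shape=0.25, rate=0.0)


class TestTransitionPosterior:
    def test_zero_data_equals_prior(self):
        prior = TransitionPrior.unit_rate(4)
        post = transition_posterior(prior, 0, 0)
        # prior mean of one transition: E[e^{-u}], u ~ Gamma(s, rate)
        expected = (prior.rate / (prior.rate + 1.0)) ** prior.shape
        assert post.mean == pytest.approx(expected, abs=1e-6)

    def test_normalization(self):
        prior = TransitionPrior.unit_rate(4)
        for n, x in [(0, 0), (18, 12), (3, 3), (11, 6)]:
            post = transition_posterior(prior, n, x)
            assert post.total_mass() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "n,x,expected_paper",
        [(18, 12, 0.679), (11, 6, 0.584), (5, 3, 0.659), (3, 3, 0.946)],
    )
    def test_worked_example_means_unit_rate(self, n, x, expected_paper):
        prior = TransitionPrior.unit_rate(4)
        post = transition_posterior(prior, n, x)
        oracle = posterior_mean_oracle(0.25, 1.0, n, x)
        assert post.mean == pytest.approx(oracle, abs=1e-5)
        # published values carry MCMC noise of a few 1e-3
        assert post.mean == pytest.approx(expected_paper, abs=3e-3)

    def test_mean_oracle_other_rate(self):
        prior = TransitionPrior.for_long_term_mean(4, 0.317)
        for n, x in [(18, 12), (5, 3), (3, 3), (0, 0)]:
            post = transition_posterior(prior, n, x)
            oracle = posterior_mean_oracle(prior.shape, prior.rate, n, x)
            assert post.mean == pytest.approx(oracle, abs=1e-5)

    def test_pull_toward_per_step_prior_mean(self):
        # (18, 12) with the scenario prior: posterior mean above the MLE
        # 0.667, pulled toward the per-step prior mean 0.317**0.25 = 0.750
        prior = TransitionPrior.for_long_term_mean(4, 0.317)
        post = transition_posterior(prior, 18, 12)
        assert 12 / 18 < post.mean < 0.317**0.25

    def test_posterior_concentration(self):
        prior = TransitionPrior.unit_rate(4)
        post = transition_posterior(prior, 10_000, 7_000)
        assert post.mean == pytest.approx(0.7, abs=1e-3)

    def test_sampler_matches_moments(self):
        prior = TransitionPrior.unit_rate(4)
        post = transition_posterior(prior, 11, 6)
        draws = post.sample(200_000, rng=np.random.default_rng(0))
        se = math.sqrt(post.variance / draws.size)
        assert draws.mean() == pytest.approx(post.mean, abs=4 * se)
        assert draws.var() == pytest.approx(post.variance, rel=0.05)

    def test_invalid_counts(self):
        prior = TransitionPrior.unit_rate(4)
        with pytest.raises(ValueError):
            transition_posterior(prior, 3, 4)

    def test_point_mass(self):
        post = TransitionPosterior.point_mass(0.6)
        assert post.mean == 0.6
        assert np.all(post.sample(10, rng=np.random.default_rng(0)) == 0.6)


class TestPriorProductLaw:
    @pytest.mark.parametrize("alpha", [0.464, 1.0, 4.0])
    def test_product_is_beta(self, alpha):
        prior = TransitionPrior(shape=0.25, rate=alpha)
        draws = sample_prior_product(prior, 4, 100_000, seed=7)
        stat = stats.kstest(draws, stats.beta(alpha, 1.0).cdf).statistic
        # critical value at level 1e-3 for n = 1e5
        assert stat < 1.95 / math.sqrt(draws.size)

    def test_uniform_special_case(self):
        prior = TransitionPrior.unit_rate(4)
        draws = sample_prior_product(prior, 4, 100_000, seed=3)
        stat = stats.kstest(draws, stats.uniform.cdf).statistic
        assert stat < 1.95 / math.sqrt(draws.size)

    @pytest.mark.parametrize("alpha,mean", [(0.464, 0.317), (4.0, 0.8)])
    def test_empirical_means(self, alpha, mean):
        prior = TransitionPrior(shape=0.25, rate=alpha)
        draws = sample_prior_product(prior, 4, 100_000, seed=11)
        se = draws.std() / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(alpha / (alpha + 1.0), abs=4 * se)
        assert draws.mean() == pytest.approx(mean, abs=4 * se + 1e-3)


class TestProbabilityOfSuccess:
    def test_worked_example(self, example_snapshot):
        pos = probability_of_success(
            example_snapshot,
            TransitionPrior.unit_rate(4),
            r_final=6,
            n_draws=100_000,
            seed=5,
        )
        # published Monte Carlo summary: 0.7784
        assert pos == pytest.approx(0.7784, abs=0.02)

    def test_known_survivors_guarantee(self, example_snapshot):
        assert (
            probability_of_success(
                example_snapshot, TransitionPrior.unit_rate(4), 2, 2_000, seed=0
            )
            == 1.0
        )

    def test_degenerate_posteriors_reduce_to_cp(self, example_snapshot):
        estimate = conditional_mles(example_snapshot, plug_in_rate=0.317)
        posteriors = [TransitionPosterior.point_mass(p) for p in estimate.step_probs]
        pos = probability_of_success(
            example_snapshot,
            None,
            r_final=6,
            n_draws=200_000,
            seed=9,
            posteriors=posteriors,
        )
        exact_cp = conditional_power_exact(example_snapshot, estimate, 6)
        assert pos == pytest.approx(exact_cp, abs=4 * math.sqrt(0.25 / 200_000))

    def test_shrinkage_from_extreme_cp(self):
        # all observed patients survived: the MLE-based CP is 1, the
        # posterior-predictive value lies strictly between the prior-only
        # value and the CP
        snap = make_snapshot([(8, 8), (8, 8), (8, 8), (8, 8)], [4, 0, 0, 0], 8)
        estimate = conditional_mles(snap, plug_in_rate=0.317)
        cp = conditional_power_exact(snap, estimate, r_final=9)
        assert cp == 1.0
        prior = TransitionPrior.for_long_term_mean(4, 0.317)
        pos = probability_of_success(snap, prior, 9, 100_000, seed=1)
        prior_snap = make_snapshot(
            [(0, 0), (0, 0), (0, 0), (0, 0)], [4, 0, 0, 0], 8, n_total=12
        )
        pos_prior_only = probability_of_success(prior_snap, prior, 9, 100_000, seed=2)
        assert pos_prior_only < pos < cp

    def test_missing_priors_rejected(self, example_snapshot):
        with pytest.raises(ValueError, match="one prior per transition"):
            probability_of_success(
                example_snapshot, [TransitionPrior.unit_rate(4)] * 3, 6, 100
            )

    def test_invalid_draws(self, example_snapshot):
        with pytest.raises(ValueError):
            probability_of_success(
                example_snapshot, TransitionPrior.unit_rate(4), 6, 0
            )


class TestDecidePos:
    def test_example_continues_at_reference_cutoff(self, example_snapshot):
        design = example_design(StePosRule(cutoff=0.734, prior_rate=1.0))
        result = decide_pos(example_snapshot, design, n_draws=50_000, seed=1)
        assert result.continue_flag
        assert result.statistic == pytest.approx(0.7784, abs=0.02)
        assert result.method_label == "ste_pos"

    def test_cutoff_one_never_continues(self, example_snapshot):
        design = example_design(StePosRule(cutoff=1.0, prior_rate=1.0))
        result = decide_pos(example_snapshot, design, n_draws=2_000, seed=1)
        assert not result.continue_flag
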