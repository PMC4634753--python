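"""ABC-MCMC kernel: distance, proposals, acceptance, HPD, prior recovery."""

import hashlib
import math

import numpy as np
import pytest
from scipy import stats

from serialfreq.abcmcmc import (
    AbcConfig,
    ChainAbortError,
    abc_distance,
    acceptance_ratio,
    effective_sample_size,
    hpd,
    propose_block,
    run_chain,
)
from serialfreq.sitefreq import SamplingDesign
from serialfreq.suffstats import SufficientStatisticModel
from serialfreq.summaries import SummaryVector, summary_schema


def dummy_model(design, n_bounds=(10.0, 1e5), mu_bounds=(1e-6, 1.0)):
    """A zero-coefficient model whose training box spans the given bounds."""
    schema = summary_schema(design)
    train_params = np.array([[n_bounds[0], mu_bounds[0]],
                             [n_bounds[1], mu_bounds[1]]])
    return SufficientStatisticModel(
        schema=schema,
        schema_hash=hashlib.sha256("\t".join(schema).encode()).hexdigest()[:16],
        transform="log10",
        intercept_N=3.0, coef_N=np.zeros(len(schema)),
        intercept_mu=-5.0, coef_mu=np.zeros(len(schema)),
        k_train=2, r2_N=0.0, r2_mu=0.0,
        train_params=train_params,
        train_projections=np.array([[3.0, -5.0], [3.0, -5.0]]),
    )


def dummy_summary(design):
    schema = summary_schema(design)
    return SummaryVector(values=np.zeros(len(schema)), schema=schema)


class TestDistance:
    def test_identity_zero(self):
        assert abc_distance((3.2, -5.0), (3.2, -5.0)) == 0.0

    def test_hand_arithmetic(self):
        assert abc_distance((2, 3), (1, 1)) == pytest.approx(5.0)

    def test_denominator_guard_floors_small_entries(self):
        # |S_obs| below 1e-3 is floored at 1e-3 in the denominator
        d = abc_distance((0.1, 2.0), (1e-6, 2.0))
        expected = (0.1 - 1e-6) ** 2 / 1e-3
        assert d == pytest.approx(expected)

    def test_negative_reference_uses_absolute_value(self):
        d = abc_distance((-4.0, 0.0), (-5.0, 0.0))
        assert d == pytest.approx(1.0 / 5.0)

    def test_non_finite_fatal(self):
        with pytest.raises(ValueError):
            abc_distance((np.nan, 1.0), (1.0, 1.0))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            abc_distance((1.0,), (1.0, 2.0))


class TestProposals:
    def test_zero_scales_identity(self, rng):
        assert propose_block((1000.0, 1e-5), (0.0, 0.0), rng) == (1000.0, 1e-5)

    def test_log_walk_symmetry(self, rng):
        state = (2000.0, 1e-5)
        diffs = np.array([
            math.log(propose_block(state, (0.4, 0.4), rng)[0]) - math.log(2000.0)
            for _ in range(30_000)
        ])
        se = diffs.std() / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * se

    def test_reproducible_stream(self):
        a = [propose_block((100.0, 1e-4), (0.5, 0.5), np.random.default_rng(3))
             for _ in range(1)]
        b = [propose_block((100.0, 1e-4), (0.5, 0.5), np.random.default_rng(3))
             for _ in range(1)]
        assert a == b


class TestAcceptanceRatio:
    def test_proposal_equals_current_is_one(self):
        assert acceptance_ratio((500.0, 1e-5), (500.0, 1e-5), (1, 1e7)) == 1.0

    def test_raw_scale_symmetric_gives_one_over_n_ratio(self):
        # with a symmetric raw-scale proposal (density ratio 1) the 1/N prior
        # yields alpha = min(1, N_i / N*)
        a = acceptance_ratio((1000.0, 1e-5), (2000.0, 1e-5), (1, 1e7),
                             proposal_density_ratio=1.0)
        assert a == pytest.approx(0.5)
        assert acceptance_ratio((2000.0, 1e-5), (1000.0, 1e-5), (1, 1e7),
                                proposal_density_ratio=1.0) == 1.0

    def test_log_walk_cancellation(self):
        # log-scale walk: density ratio (N* mu*)/(N_i mu_i) times prior ratio
        # (N_i/N*) leaves alpha = min(1, mu*/mu_i)
        cur, prop = (1000.0, 1e-5), (4000.0, 2e-5)
        assert acceptance_ratio(cur, prop, (1, 1e7)) == pytest.approx(
            min(1.0, prop[1] / cur[1]))

    def test_out_of_support_zero(self):
        assert acceptance_ratio((1000.0, 1e-5), (0.5, 1e-5), (1, 1e7)) == 0.0
        assert acceptance_ratio((1000.0, 1e-5), (1000.0, 1.5), (1, 1e7)) == 0.0


class TestRunChain:
    DESIGN = SamplingDesign.from_times([0, 200])

    def _config(self, **kw):
        base = dict(n_iterations=50_000, thin=5, burnin_fraction=0.1,
                    epsilon=float("inf"), proposal_scale_logN=1.2,
                    proposal_scale_logmu=1.2, adapt_proposals=False,
                    n_prior_bounds=(10.0, 1e5), seed=8, n_chains=1)
        base.update(kw)
        return AbcConfig(**base)

    def test_prior_recovery_at_infinite_epsilon(self):
        # with an infinite threshold every proposal passes the gate, so the
        # chain must sample the prior: log N uniform on the bounds, mu U[0,1]
        model = dummy_model(self.DESIGN)
        trace = run_chain(dummy_summary(self.DESIGN), model, self.DESIGN,
                          10, 100, self._config())
        post = trace.post_burnin()
        lo, hi = np.log(10.0), np.log(1e5)
        ks_N = stats.kstest(np.log(post.N), stats.uniform(lo, hi - lo).cdf)
        assert ks_N.statistic < 0.05
        ks_mu = stats.kstest(post.mu, stats.uniform(0, 1).cdf)
        assert ks_mu.statistic < 0.05

    def test_detailed_balance_smoke(self):
        # under the prior target, transitions between the two halves of the
        # log N range must be symmetric
        model = dummy_model(self.DESIGN)
        trace = run_chain(dummy_summary(self.DESIGN), model, self.DESIGN,
                          10, 100, self._config(thin=1, n_iterations=40_000))
        bins = (np.log(trace.N) > (np.log(10) + np.log(1e5)) / 2).astype(int)
        ab = int(np.sum((bins[:-1] == 0) & (bins[1:] == 1)))
        ba = int(np.sum((bins[:-1] == 1) & (bins[1:] == 0)))
        assert stats.binomtest(ab, ab + ba, 0.5).pvalue > 0.01

    def test_recorded_iterations_are_thin_multiples(self):
        model = dummy_model(self.DESIGN)
        trace = run_chain(dummy_summary(self.DESIGN), model, self.DESIGN,
                          10, 100, self._config(n_iterations=2000, thin=100))
        assert trace.iterations.tolist() == list(range(100, 2001, 100))
        assert np.all((trace.N >= 10) & (trace.N <= 1e5))
        assert np.all((trace.mu > 0) & (trace.mu <= 1))

    def test_zero_epsilon_aborts(self):
        # continuous statistics never hit distance exactly 0: the acceptance
        # monitor must abort with guidance
        model = dummy_model(self.DESIGN, n_bounds=(50.0, 500.0),
                            mu_bounds=(1e-5, 1e-4))
        # weight on the spectrum statistic: simulated data give ~19 there
        # while the observed (zero) vector gives 0, so d > 0 at every step
        model.coef_mu[list(model.schema).index("chisq_spectrum_t0")] = 1.0
        cfg = self._config(epsilon=0.0, n_iterations=3000,
                           acceptance_check_iter=1500)
        with pytest.raises(ChainAbortError, match="epsilon"):
            run_chain(dummy_summary(self.DESIGN), model, self.DESIGN,
                      5, 50, cfg)

    def test_same_seed_identical_trace(self):
        model = dummy_model(self.DESIGN)
        cfg = self._config(n_iterations=5000, thin=10)
        t1 = run_chain(dummy_summary(self.DESIGN), model, self.DESIGN, 10, 100, cfg)
        t2 = run_chain(dummy_summary(self.DESIGN), model, self.DESIGN, 10, 100, cfg)
        np.testing.assert_array_equal(t1.N, t2.N)
        np.testing.assert_array_equal(t1.mu, t2.mu)


class TestHpd:
    def test_uniform_grid_leftmost_window(self):
        samples = np.arange(1, 101, dtype=float)
        interval = hpd(samples, 0.95)
        assert (interval.lower, interval.upper) == (1.0, 95.0)

    def test_identical_samples_zero_width(self):
        interval = hpd(np.full(200, 7.5), 0.95)
        assert interval.lower == interval.upper == 7.5

    def test_matches_normal_quantiles(self):
        x = np.random.default_rng(0).normal(size=100_000)
        interval = hpd(x, 0.95)
        assert interval.lower == pytest.approx(-1.96, abs=0.05)
        assert interval.upper == pytest.approx(1.96, abs=0.05)
        assert interval.mean == pytest.approx(0.0, abs=0.02)

    def test_empirical_mass_at_least_nominal(self):
        x = np.random.default_rng(1).gamma(2.0, size=5000)
        interval = hpd(x, 0.9)
        mass = np.mean((x >= interval.lower) & (x <= interval.upper))
        assert mass >= 0.9 - 1 / x.size

    def test_too_few_samples_fatal(self):
        with pytest.raises(ValueError):
            hpd(np.arange(50), 0.95)


class TestEss:
    def test_iid_close_to_n(self):
        x = np.random.default_rng(2).normal(size=4000)
        assert effective_sample_size(x) > 2000

    def test_correlated_chain_reduced(self):
        rng = np.random.default_rng(3)
        x = np.zeros(4000)
        for i in range(1, 4000):  # AR(1), rho=0.95 -> ESS ~ n/39
            x[i] = 0.95 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 500
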