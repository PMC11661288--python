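"""The relaxed Poisson sampler: truncation, distributional correctness,
annealing, and pathwise gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pvae import autodiff as ad
from pvae import relaxed_poisson as rp
from pvae.errors import ContractError, InvalidRateError


def cdf_oracle(lam: float, quantile: float) -> int:
    """Brute-force Poisson CDF summation: smallest n with CDF >= quantile."""
    total, k, term = 0.0, 0, np.exp(-lam)
    while True:
        total += term
        if total >= quantile:
            return k
        k += 1
        term *= lam / k


class TestTruncation:
    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 4.0, 10.0, 50.0])
    def test_matches_cdf_summation_oracle(self, lam):
        expected = cdf_oracle(lam, 0.99999)
        assert rp.required_exponential_samples(lam) == expected

    def test_unit_rate_needs_eight_draws(self):
        assert rp.required_exponential_samples(1.0, 0.99999) == 8

    def test_vanishing_rate_needs_none(self):
        # CDF(0) = exp(-1e-9) ~ 1 already exceeds the quantile
        assert rp.required_exponential_samples(1e-9) == 0

    def test_cap_applies_with_warning(self, caplog):
        uncapped = cdf_oracle(50.0, 0.99999)
        assert uncapped > 64
        with caplog.at_level("WARNING"):
            assert rp.required_exponential_samples(50.0, cap=64) == 64
        assert any("cap" in r.message for r in caplog.records)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidRateError):
            rp.required_exponential_samples(0.0)
        with pytest.raises(ContractError):
            rp.required_exponential_samples(1.0, quantile=1.5)
        with pytest.raises(ContractError):
            rp.required_exponential_samples(1.0, cap=0)

    def test_truncation_mass_bound(self):
        """Mass beyond n_exp is < 1e-5; empirical max stays below n_exp."""
        for lam in (0.5, 2.0, 8.0):
            n = rp.required_exponential_samples(lam)
            assert 1.0 - stats.poisson.cdf(n, lam) < 1e-5
            draws = rp.sample_exact(np.full((20000, 1), lam), rng=0)
            assert np.mean(draws <= n) >= 0.9999


def gof_pvalue(counts: np.ndarray, lam: float) -> float:
    """Chi-square goodness of fit against Poisson(lam), merging sparse bins."""
    kmax = int(stats.poisson.ppf(1 - 1e-9, lam)) + 1
    observed = np.bincount(counts.astype(int).ravel(), minlength=kmax + 1)[:kmax + 1]
    expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
    expected[-1] = counts.size - expected[:-1].sum()  # fold the tail in
    # merge bins with expected < 5 from the right
    while expected.size > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]; expected = expected[:-1]
        observed[-2] += observed[-1]; observed = observed[:-1]
    while expected.size > 2 and expected[0] < 5:
        expected[1] += expected[0]; expected = expected[1:]
        observed[1] += observed[0]; observed = observed[1:]
    return stats.chisquare(observed, expected).pvalue


class TestSampling:
    def test_hard_count_from_known_arrival_times(self):
        """Wait times {0.3, 0.5, 0.6} -> arrivals {0.3, 0.8, 1.4} -> count 2."""

        class FixedRng:
            def random(self, size=None):
                return np.exp(-np.array([0.3, 0.5, 0.6])).reshape(size)

        s = rp.rsample(np.array([[1.0]]), 3, 0.0, rng=FixedRng())
        assert s.counts.data[0, 0] == 2.0

    def test_moments_match_poisson_at_t0(self):
        s = rp.rsample(np.full((100_000, 1), 1.0), 8, 0.0, rng=1)
        m, v = s.counts.data.mean(), s.counts.data.var()
        assert abs(m - 1.0) < 3.5 * np.sqrt(1.0 / 100_000)
        assert abs(v - 1.0) < 0.03

    def test_rsample_t0_equals_exact_distribution(self):
        p = gof_pvalue(rp.rsample(np.full((100_000, 1), 4.0),
                                  rp.required_exponential_samples(4.0),
                                  0.0, rng=2).counts.data, 4.0)
        assert p > 0.001

    @pytest.mark.parametrize("lam", [0.1, 1.0, 4.0, 10.0])
    def test_sample_exact_goodness_of_fit(self, lam):
        counts = rp.sample_exact(np.full((100_000, 1), lam), rng=3)
        assert gof_pvalue(counts, lam) > 0.001

    def test_tiny_rate_gives_all_zeros(self):
        counts = rp.sample_exact(np.full((10_000, 1), 1e-8), rng=4)
        assert counts.sum() == 0

    def test_seeded_determinism(self):
        a = rp.sample_exact(np.full((100, 5), 2.0), rng=7)
        b = rp.sample_exact(np.full((100, 5), 2.0), rng=7)
        np.testing.assert_array_equal(a, b)
        ra = rp.rsample(np.full((50, 4), 1.5), 10, 0.3, rng=9).counts.data
        rb = rp.rsample(np.full((50, 4), 1.5), 10, 0.3, rng=9).counts.data
        np.testing.assert_array_equal(ra, rb)

    def test_relaxation_approaches_poisson_as_temperature_drops(self):
        """Total-variation distance to the exact pmf decreases through
        T = 1.0, 0.1, 0.01 (binned to integers)."""
        lam, n = 1.0, 100_000
        n_exp = rp.required_exponential_samples(lam)
        kmax = 12
        pmf = stats.poisson.pmf(np.arange(kmax + 1), lam)
        pmf[-1] = 1.0 - pmf[:-1].sum()
        tvs = []
        for i, T in enumerate([1.0, 0.1, 0.01]):
            z = rp.rsample(np.full((n, 1), lam), n_exp, T, rng=10 + i).counts.data
            binned = np.clip(np.round(z).astype(int), 0, kmax).ravel()
            emp = np.bincount(binned, minlength=kmax + 1) / n
            tvs.append(0.5 * np.abs(emp - pmf).sum())
        assert tvs[0] > tvs[1] > tvs[2]
        assert tvs[2] < 0.01

    def test_counts_bounded_by_truncation(self):
        s = rp.rsample(np.full((1000, 3), 2.0), 12, 0.5, rng=11)
        assert np.all(s.counts.data >= 0)
        assert np.all(s.counts.data <= s.n_exp)

    def test_invalid_rates_and_temperature_rejected(self):
        with pytest.raises(InvalidRateError):
            rp.rsample(np.array([[0.0]]), 4, 0.1, rng=0)
        with pytest.raises(InvalidRateError):
            rp.rsample(np.array([[np.nan]]), 4, 0.1, rng=0)
        with pytest.raises(ContractError):
            rp.rsample(np.array([[1.0]]), 4, -0.1, rng=0)
        with pytest.raises(InvalidRateError):
            rp.sample_exact(np.array([[-1.0]]), rng=0)


class TestGradients:
    def test_pathwise_gradient_of_mean_count_is_one(self):
        """dE[z]/dlambda = 1; the averaged pathwise gradient at T = 0.05
        recovers it within 5% over >= 1e5 effective draws."""
        lam = ad.Parameter(np.full((500, 40), 1.0))
        total, n_rep = 0.0, 6
        for i in range(n_rep):
            s = rp.rsample(lam, 10, 0.05, rng=100 + i)
            lam.grad = None
            s.counts.sum().backward()
            total += lam.grad.mean()
        assert abs(total / n_rep - 1.0) < 0.05

    def test_fused_gradient_matches_elementary_chain(self):
        """The fused sampling node and the explicit op-by-op chain produce
        identical gradients for the same underlying uniforms."""
        lam0 = np.array([[0.7, 1.3, 2.1]])
        T, n_exp = 0.2, 10
        lam_a = ad.Parameter(lam0.copy())
        s = rp.rsample(lam_a, n_exp, T, rng=5)
        s.counts.sum().backward()

        lam_b = ad.Parameter(lam0.copy())
        times = rp._draw_wait_times(lam_b, n_exp,
                                    np.random.default_rng(5)).cumsum(axis=0)
        z = ad.sigmoid((1.0 - times) * (1.0 / T)).sum(axis=0)
        z.sum().backward()
        np.testing.assert_allclose(s.counts.data, z.data, rtol=1e-12)
        np.testing.assert_allclose(lam_a.grad, lam_b.grad, rtol=1e-9)


class TestHardForward:
    def test_forward_is_hard_count_gradient_is_relaxed(self):
        lam0 = np.full((200, 8), 1.5)
        lam_h = ad.Parameter(lam0.copy())
        hard = rp.rsample_hard_forward(lam_h, 10, 0.3, rng=21)
        lam_s = ad.Parameter(lam0.copy())
        soft = rp.rsample(lam_s, 10, 0.3, rng=21)
        # same draws: forward is the hard threshold of the same arrival times
        assert np.all(hard.counts.data == np.floor(hard.counts.data))
        hard.counts.sum().backward()
        soft.counts.sum().backward()
        np.testing.assert_allclose(lam_h.grad, lam_s.grad, rtol=1e-12)

    def test_requires_positive_temperature(self):
        with pytest.raises(ContractError):
            rp.rsample_hard_forward(np.array([[1.0]]), 4, 0.0, rng=0)


class TestAnnealing:
    def test_default_schedule_endpoints(self):
        sched = rp.AnnealSchedule()
        assert rp.temperature_at(0, 1000, sched) == 1.0
        assert rp.temperature_at(1000, 1000, sched) == 0.05
        # holds at t_final from the anneal point onward
        assert rp.temperature_at(500, 1000, sched) == pytest.approx(0.05)

    def test_linear_midpoint(self):
        sched = rp.AnnealSchedule(t_start=1.0, t_final=0.0, anneal_fraction=1.0)
        assert rp.temperature_at(500, 1000, sched) == pytest.approx(0.5)

    def test_exponential_is_log_linear(self):
        sched = rp.AnnealSchedule(t_start=1.0, t_final=0.01,
                                  anneal_fraction=1.0, mode="exponential")
        assert rp.temperature_at(500, 1000, sched) == pytest.approx(0.1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200),
           st.sampled_from(["linear", "exponential"]))
    def test_monotone_nonincreasing(self, s1, s2, mode):
        sched = rp.AnnealSchedule(mode=mode)
        lo, hi = sorted((s1, s2))
        assert rp.temperature_at(lo, 200, sched) >= \
            rp.temperature_at(hi, 200, sched)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ContractError):
            rp.AnnealSchedule(t_start=0.01, t_final=0.5)
        with pytest.raises(ContractError):
            rp.AnnealSchedule(anneal_fraction=0.0)
        with pytest.raises(ContractError):
            rp.AnnealSchedule(mode="cosine")
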