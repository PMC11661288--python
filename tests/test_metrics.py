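"""Sparsity, dead-neuron, KNN, shattering, and seed-protocol statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from pvae.errors import ContractError
from pvae.metrics import (active_fraction, extract_representation,
                          knn_protocol, lifetime_sparsity,
                          seed_protocol_stats, shattering_dimensionality)


class TestLifetimeSparsity:
    def test_one_hot_column_scores_one(self):
        z = np.zeros((100, 1))
        z[37, 0] = 4.2
        s, mean = lifetime_sparsity(z)
        assert s[0] == 1.0 and mean == 1.0

    def test_constant_column_scores_zero(self):
        s, _ = lifetime_sparsity(np.full((100, 1), 2.5))
        assert s[0] == 0.0

    def test_matches_direct_formula_on_random_column(self):
        rng = np.random.default_rng(0)
        z = rng.random((50, 3))
        s, _ = lifetime_sparsity(z)
        N = 50
        direct = (1 - (z.sum(0) ** 2) / (N * (z ** 2).sum(0))) / (1 - 1 / N)
        np.testing.assert_allclose(s, direct, rtol=1e-12)

    def test_all_zero_column_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            s, _ = lifetime_sparsity(np.zeros((10, 2)))
        np.testing.assert_array_equal(s, 0.0)
        assert any("all-zero" in r.message for r in caplog.records)

    def test_signed_responses_use_magnitudes(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((200, 4))
        s_signed, _ = lifetime_sparsity(z, signed=True)
        s_abs, _ = lifetime_sparsity(np.abs(z))
        np.testing.assert_array_equal(s_signed, s_abs)
        with pytest.raises(ContractError):
            lifetime_sparsity(z)  # negative without signed flag

    def test_gaussian_noise_floor(self):
        """A unit-variance Gaussian noise latent scores about 1 - 2/pi."""
        z = np.random.default_rng(2).standard_normal((200_000, 1))
        s, _ = lifetime_sparsity(z, signed=True)
        assert s[0] == pytest.approx(1 - 2 / np.pi, abs=0.005)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(arrays(float, (17, 3), elements=st.floats(0, 1e6)))
    def test_bounded_in_unit_interval(self, z):
        s, _ = lifetime_sparsity(z)
        assert np.all(s >= 0.0) and np.all(s <= 1.0)

    def test_needs_two_stimuli(self):
        with pytest.raises(ContractError):
            lifetime_sparsity(np.ones((1, 4)))


class TestActiveFraction:
    def test_clean_bimodal_split(self):
        kl = np.concatenate([np.full(100, 1e-9), np.full(100, 0.5)])
        frac, thr = active_fraction(kl)
        assert frac == 0.5
        assert 1e-9 < thr < 0.5

    def test_unimodal_uses_fallback_threshold(self):
        frac, thr = active_fraction(np.full(64, 0.5))
        assert frac == 1.0
        assert thr == 0.01

    def test_threshold_lands_in_planted_gap(self):
        rng = np.random.default_rng(3)
        kl = np.concatenate([10 ** rng.normal(-4, 0.2, 120),
                             10 ** rng.normal(-1, 0.2, 120)])
        frac, thr = active_fraction(kl)
        assert 10 ** -3.2 > thr > 10 ** -2.8 or 10 ** -3.5 < thr < 10 ** -1.6
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_all_zero_kl(self):
        frac, _ = active_fraction(np.zeros(10))
        assert frac == 0.0

    def test_negative_kl_rejected(self):
        with pytest.raises(ContractError):
            active_fraction(np.array([-0.1]))


class TestRepresentation:
    def test_poisson_representation_is_log_deviation(self, tiny_pvae, patch_ds):
        X = patch_ds.val[:6]
        rep = extract_representation(tiny_pvae, X)
        state = tiny_pvae.encode_state(X)
        np.testing.assert_array_equal(rep, state.log_deviation.data)

    def test_repeated_calls_identical(self, tiny_pvae, patch_ds):
        X = patch_ds.val[:4]
        np.testing.assert_array_equal(extract_representation(tiny_pvae, X),
                                      extract_representation(tiny_pvae, X))


def two_blob_pools(rng, n=600, d=5, sep=8.0):
    y = rng.integers(0, 2, size=n)
    X = rng.standard_normal((n, d)) + sep * y[:, None]
    return X[: n // 2], y[: n // 2], X[n // 2:], y[n // 2:]


class TestKNN:
    def test_separated_blobs_reach_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        Xtr, ytr, Xte, yte = two_blob_pools(rng)
        report = knn_protocol(Xtr, ytr, Xte, yte, n_train_grid=(20, 100),
                              rng=rng)
        assert np.all(report["accuracy"] == 1.0)

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(5)
        Xtr, ytr, Xte, yte = two_blob_pools(rng)
        ytr_shuffled = rng.permutation(ytr)
        report = knn_protocol(Xtr, ytr_shuffled, Xte, yte,
                              n_train_grid=(200,), n_resamples=10, rng=rng)
        assert report["accuracy"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_accuracy_increases_with_labels_on_structured_data(self):
        rng = np.random.default_rng(6)
        n, d = 2400, 8
        y = rng.integers(0, 4, size=n)
        centers = rng.standard_normal((4, d)) * 1.5
        X = centers[y] + rng.standard_normal((n, d))
        report = knn_protocol(X[:1200], y[:1200], X[1200:], y[1200:],
                              n_train_grid=(20, 100, 800), rng=rng)
        acc = report["accuracy"].to_numpy()
        assert acc[0] <= acc[1] + 0.02 and acc[1] <= acc[2] + 0.02
        assert acc[2] > acc[0]

    def test_pool_size_contract(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ContractError):
            knn_protocol(np.zeros((10, 2)), np.zeros(10), np.zeros((5, 2)),
                         np.zeros(5), n_train_grid=(50,), rng=rng)


class TestShattering:
    @pytest.mark.parametrize("n_classes,expected", [(2, 2), (4, 6), (10, 252)])
    def test_dichotomy_count(self, n_classes, expected):
        rng = np.random.default_rng(8)
        y = np.repeat(np.arange(n_classes), 8)
        X = np.eye(n_classes)[y] + 0.01 * rng.standard_normal(
            (y.size, n_classes))
        _, count = shattering_dimensionality(X, y)
        assert count == expected

    def test_one_hot_representations_are_fully_shattered(self):
        y = np.repeat(np.arange(4), 10)
        X = np.eye(4)[y]
        acc, _ = shattering_dimensionality(X, y)
        assert acc == 1.0

    def test_odd_class_count_rejected(self):
        y = np.repeat(np.arange(3), 5)
        with pytest.raises(ContractError):
            shattering_dimensionality(np.eye(3)[y], y)


class TestSeedProtocol:
    def make_df(self, a_vals, b_vals):
        rows = []
        for s, (a, b) in enumerate(zip(a_vals, b_vals)):
            rows.append({"model": "a", "seed": s, "mse": a})
            rows.append({"model": "b", "seed": s, "mse": b})
        return pd.DataFrame(rows)

    def test_identical_samples_give_p_one(self):
        df = self.make_df([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            out = seed_protocol_stats(df, "mse", baseline_model="a")
        assert out.loc[out["model"] == "b", "p_value"].iloc[0] == 1.0

    def test_constant_offset_is_significant_and_survives_fdr(self):
        rng = np.random.default_rng(9)
        base = rng.normal(10, 0.01, size=5)
        df = self.make_df(base, base + 1.0 + rng.normal(0, 0.01, size=5))
        out = seed_protocol_stats(df, "mse", baseline_model="a")
        row = out.loc[out["model"] == "b"].iloc[0]
        assert row["p_value"] < 0.01
        assert bool(row["significant"])

    def test_benjamini_hochberg_adjustment_matches_hand_step_up(self):
        """Multi-model comparison: adjusted p-values equal the hand-computed
        BH step-up of the raw paired-test p-values, and only comparisons
        passing q = 0.01 are flagged."""
        rng = np.random.default_rng(11)
        base = rng.normal(10, 0.05, size=5)
        rows = []
        offsets = {"a": 0.0, "b": 2.0, "c": 0.08, "d": 0.001}
        for m, off in offsets.items():
            noise = rng.normal(0, 0.04, size=5) if m != "a" else 0.0
            for s in range(5):
                val = base[s] + off + (noise[s] if m != "a" else 0.0)
                rows.append({"model": m, "seed": s, "mse": val})
        out = seed_protocol_stats(pd.DataFrame(rows), "mse",
                                  baseline_model="a").set_index("model")
        p = out.loc[["b", "c", "d"], "p_value"].to_numpy()
        # hand BH step-up: p_(i) * m / i, cumulative min from the largest
        order = np.argsort(p)
        m_tests = p.size
        adj_sorted = np.minimum.accumulate(
            (p[order] * m_tests / np.arange(1, m_tests + 1))[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(
            out.loc[["b", "c", "d"], "p_adjusted"].to_numpy(), expected,
            rtol=1e-9)
        np.testing.assert_array_equal(
            out.loc[["b", "c", "d"], "significant"].to_numpy(),
            expected < 0.01)

    def test_confidence_interval_covers_mean(self):
        rng = np.random.default_rng(10)
        df = self.make_df(rng.normal(5, 1, 5), rng.normal(7, 1, 5))
        out = seed_protocol_stats(df, "mse")
        for _, row in out.iterrows():
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_unpaired_design_rejected(self):
        df = pd.DataFrame([{"model": "a", "seed": 0, "mse": 1.0},
                           {"model": "b", "seed": 1, "mse": 2.0}])
        with pytest.raises(ContractError):
            seed_protocol_stats(df, "mse", baseline_model="a")
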