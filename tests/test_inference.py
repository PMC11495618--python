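"""Feature transform, model fits, Bayes factors, improver rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myolearn import inference as inf
from conftest import model_feature_frame

FAST = inf.SamplerConfig(burn=1200, min_kept_steps=200, seed=0)


class TestStandardize:
    def test_hand_computed_example(self):
        tr = inf.standardize_feature(np.array([1.0, np.e**2, np.e**4]))
        np.testing.assert_allclose(tr.values, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_unit_sample_sd(self, rng):
        tr = inf.standardize_feature(rng.lognormal(1.0, 0.7, 500))
        assert tr.values.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert tr.values.mean() == pytest.approx(0.0, abs=1e-12)

    def test_inverse_recovers_inputs(self, rng):
        x = rng.lognormal(0, 1, 100)
        tr = inf.standardize_feature(x)
        np.testing.assert_allclose(tr.inverse(tr.values), x, rtol=1e-12)

    def test_rejections(self):
        with pytest.raises(ValueError):
            inf.standardize_feature(np.array([1.0, -2.0, 3.0]))
        with pytest.raises(ValueError):
            inf.standardize_feature(np.full(10, 3.0))


class TestHierarchicalModel:
    def test_cell_means_recovered(self, rng):
        df, true = model_feature_frame(rng, trials_per_cell=50)
        post = inf.fit_hierarchical_model(df, "epsilon", FAST)
        assert post.diagnostics.rhat_max < 1.2
        hits = 0
        for (p, s, d), (mu, _) in true.items():
            tmu = (mu - post.transform.centre) / post.transform.scale
            draws = post.cell_mu(p, s, d)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            hits += lo <= tmu <= hi
        assert hits >= 0.8 * len(true)

    def test_large_n_concentration(self, rng):
        """A single well-populated cell's posterior mean matches the sample
        mean closely (in transformed units)."""
        y = rng.lognormal(0.3, 0.5, 10_000)
        df = pd.DataFrame(dict(
            participant="P1", congruence="congruent", scale=1, day=1,
            order_correct=True, feedback=False, epsilon=y,
        ))
        post = inf.fit_hierarchical_model(df, "epsilon", FAST)
        draws = post.cell_mu("P1", 1, 1)
        sample_mean = post.transform.values.mean()  # 0 by construction
        assert draws.mean() == pytest.approx(sample_mean, abs=0.02)

    def test_prior_only_sampling_matches_model_prior(self):
        cells = pd.DataFrame({
            "participant": ["P1", "P2"], "scale": [1, 1], "day": [1, 1],
        })
        prior = inf.sample_prior_hierarchical(
            cells, ["congruent"], np.array([0, 0]), n_draws=200_000, seed=3
        )
        assert prior.mu_c.mean() == pytest.approx(0.0, abs=0.01)
        assert prior.mu_c.std() == pytest.approx(0.75, abs=0.01)
        # cell means: Normal(0, 0.75) on top of the group mean
        assert prior.mu[:, 0].std() == pytest.approx(
            0.75 * np.sqrt(2), abs=0.01)
        # sigma ~ HalfNormal(1)
        assert prior.sigma.mean() == pytest.approx(
            np.sqrt(2 / np.pi), abs=0.01)

    def test_feedback_and_order_filtering(self, rng):
        df, _ = model_feature_frame(rng, trials_per_cell=50)
        df.loc[df.index[:200], "feedback"] = True
        df.loc[df.index[-200:], "order_correct"] = False
        post = inf.fit_hierarchical_model(df, "epsilon", FAST)
        n_used = int(post.cells["n"].sum())
        assert n_used == len(df) - 400

    def test_empty_cells_reported(self, rng):
        df, _ = model_feature_frame(rng, trials_per_cell=5)
        df = df[~((df.participant == "C1") & (df.scale == 1) & (df.day == 5))]
        post = inf.fit_hierarchical_model(df, "epsilon", FAST)
        assert ("C1", 1, 5) in post.diagnostics.empty_cells


class TestChannelModel:
    def test_symmetric_under_relabelling(self, rng):
        df, _ = model_feature_frame(rng, trials_per_cell=20)
        a = inf.fit_channel_feature_model(df, "epsilon", FAST)
        b = inf.fit_channel_feature_model(df.copy(), "epsilon", FAST)
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_prior_only_matches_normal_0_1(self):
        cells = pd.DataFrame({"participant": ["P1"], "scale": [1], "day": [1]})
        prior = inf.sample_prior_channel(cells, n_draws=200_000, seed=4)
        assert prior.mu.mean() == pytest.approx(0.0, abs=0.01)
        assert prior.mu.std() == pytest.approx(1.0, abs=0.01)

    def test_marginal_mean_is_average_of_cell_draws(self, rng):
        df, _ = model_feature_frame(rng, trials_per_cell=10)
        post = inf.fit_channel_feature_model(df, "epsilon", FAST)
        sel = post.marginal_mean(scale=1, day=1)
        idx = post.cells.index[
            (post.cells["scale"] == 1) & (post.cells["day"] == 1)
        ].to_numpy()
        np.testing.assert_allclose(sel, post.mu[:, idx].mean(axis=1))


class TestCorrelationModel:
    def test_preprocessing_subtracts_initiation_and_centres(self):
        p1 = np.array([1.0, 1.2, 1.4])
        p2 = np.array([1.3, 1.5, 1.9])
        init = np.array([0.9, 1.0, 1.2])
        pairs = inf.prepare_peak_time_pairs(p1, p2, init)
        np.testing.assert_allclose(pairs.mean(axis=0), 0.0, atol=1e-12)
        raw = np.column_stack([p1 - init, p2 - init])
        np.testing.assert_allclose(pairs, raw - raw.mean(axis=0), atol=1e-12)

    def test_known_correlation_recovered(self, rng):
        pairs = rng.multivariate_normal(
            [0, 0], 0.01 * np.array([[1, 0.6], [0.6, 1]]), 300
        )
        post = inf.fit_correlation_model(pairs, FAST)
        lo, hi = np.percentile(post.r, [2.5, 97.5])
        assert lo < 0.6 < hi
        assert post.r.mean() == pytest.approx(0.6, abs=0.15)

    def test_degenerate_equal_pairs(self, rng):
        x = rng.normal(0, 0.1, 100)
        pairs = np.column_stack([x, x])
        post = inf.fit_correlation_model(pairs, FAST)
        assert np.mean(post.r > 0.95) > 0.9

    def test_independent_pairs_near_zero(self, rng):
        pairs = rng.normal(0, 0.1, size=(500, 2))
        post = inf.fit_correlation_model(pairs, FAST)
        assert abs(post.r.mean()) < 0.15

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            inf.fit_correlation_model(np.zeros((5, 2)))

    def test_covariance_identity(self, rng):
        pairs = rng.normal(0, 0.1, size=(50, 2))
        post = inf.fit_correlation_model(pairs, FAST)
        S = post.covariance()
        np.testing.assert_allclose(
            S[:, 0, 1], post.r * post.sigma[:, 0] * post.sigma[:, 1]
        )


class TestBayesFactors:
    def test_identical_posterior_and_prior_gives_unity(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(0, 1, 5000)
        bf = inf.bayes_factor(a, b, a, b)
        assert bf.bf10 == pytest.approx(1.0)

    def test_exchangeable_prior_probability_half(self, rng):
        a = rng.normal(2.0, 1.5, 100_000)
        b = rng.normal(2.0, 1.5, 100_000)
        bf = inf.bayes_factor(a, b, a.copy(), b.copy())
        assert bf.prior_count / bf.prior_total == pytest.approx(0.5, abs=0.01)

    def test_gaussian_closed_form_oracle(self, rng):
        n = 100_000
        post_a = rng.normal(0.5, 0.3, n)
        post_b = rng.normal(0.1, 0.4, n)
        pri_a = rng.normal(0.0, 1.0, n)
        pri_b = rng.normal(0.0, 1.0, n)
        p = stats.norm.cdf((0.5 - 0.1) / np.hypot(0.3, 0.4))
        expected = (p / (1 - p)) / 1.0  # symmetric prior odds are 1
        bf = inf.bayes_factor(post_a, post_b, pri_a, pri_b)
        assert bf.bf10 == pytest.approx(expected, rel=0.05)

    def test_reciprocal_identity(self, rng):
        bf = inf.bayes_factor(
            rng.normal(1, 1, 5000), rng.normal(0, 1, 5000),
            rng.normal(0, 1, 5000), rng.normal(0, 1, 5000),
        )
        assert bf.bf10 * bf.bf01 == pytest.approx(1.0)

    def test_zero_count_bounded(self, rng):
        post_a = np.full(5000, 10.0)
        post_b = np.full(5000, 0.0)  # reduction always satisfied
        pri = rng.normal(0, 1, 5000)
        bf = inf.bayes_factor(post_a, post_b, pri, rng.normal(0, 1, 5000))
        assert bf.bounded and np.isfinite(bf.bf10)

    def test_draw_shortfall_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        with pytest.raises(ValueError):
            inf.bayes_factor(x, x, x, x)


@pytest.mark.parametrize("bf10,expected", [
    (3.5, "improver"), (3.0, "non-improver"), (0.5, "non-improver"),
])
def test_improver_threshold_is_strict(bf10, expected):
    assert inf.classify_improver(bf10) == expected
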