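"""Similarity, fPCA, distinguishability and direction-bias analyses."""

import numpy as np
import pytest

from myolearn import generalisation as gen, inference as inf
from conftest import model_feature_frame


class TestMinDiff:
    def test_subset_gives_zero(self):
        s1 = np.array([0.2, 0.5, 0.9, 1.4])
        entry = gen.min_diff_p99(s1[[1, 3]], s1)
        assert entry.percentile_value == 0.0

    def test_small_enumerated_example(self):
        entry = gen.min_diff_p99(np.array([0.6, 1.4]),
                                 np.array([0.5, 1.0, 1.5]))
        np.testing.assert_allclose(entry.minima, [0.1, 0.1])
        assert entry.percentile_value == pytest.approx(0.1)

    def test_single_trial_returns_its_minimum(self):
        entry = gen.min_diff_p99(np.array([0.77]), np.array([0.5, 0.7]))
        assert entry.percentile_value == pytest.approx(0.07)
        assert entry.session1_index == 1

    def test_matches_brute_force_enumeration(self, rng):
        s5 = rng.uniform(0, 1, 40)
        s1 = rng.uniform(0, 1, 60)
        entry = gen.min_diff_p99(s5, s1)
        minima = [min(abs(a - b) for b in s1) for a in s5]
        assert entry.percentile_value == pytest.approx(
            np.percentile(minima, 99))

    def test_vector_features_use_euclidean_distance(self, rng):
        s5 = rng.normal(size=(10, 3))
        s1 = rng.normal(size=(20, 3))
        entry = gen.min_diff_p99(s5, s1)
        minima = [min(np.linalg.norm(a - b) for b in s1) for a in s5]
        np.testing.assert_allclose(entry.minima, minima)

    def test_monotone_under_session1_superset(self, rng):
        s5 = rng.uniform(0, 1, 30)
        s1 = rng.uniform(0, 1, 30)
        extra = np.concatenate([s1, rng.uniform(0, 1, 30)])
        assert (gen.min_diff_p99(s5, extra).percentile_value
                <= gen.min_diff_p99(s5, s1).percentile_value + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gen.min_diff_p99(np.array([]), np.array([1.0]))


class TestFPCA:
    def make_low_rank(self, rng, n=60, t=120, k=3, noise=1e-6):
        basis = np.linalg.qr(rng.normal(size=(t, k)))[0].T
        scores = rng.normal(size=(n, k)) * np.array([3.0, 2.0, 1.0])
        x = scores @ basis + rng.normal(0, noise, size=(n, t))
        return x, basis

    def test_low_rank_construction_explained(self, rng):
        x, _ = self.make_low_rank(rng)
        grid = np.arange(x.shape[1]) / 1000
        basis = gen.fit_fpca(x, grid, k=3)
        assert basis.cumulative_explained >= 0.999
        assert np.all(np.diff(basis.explained_variance) <= 1e-12)

    def test_components_orthonormal(self, rng):
        x, _ = self.make_low_rank(rng, noise=0.1)
        basis = gen.fit_fpca(x, np.arange(x.shape[1]), k=3)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_projection_identities(self, rng):
        x, _ = self.make_low_rank(rng, noise=0.01)
        basis = gen.fit_fpca(x, np.arange(x.shape[1]), k=3)
        np.testing.assert_allclose(
            gen.project_fpca(basis.mean, basis), 0.0, atol=1e-9)
        shifted = basis.mean + 2.0 * basis.components[0]
        np.testing.assert_allclose(
            gen.project_fpca(shifted, basis), [2.0, 0.0, 0.0], atol=1e-9)

    def test_scores_match_inner_product_oracle(self, rng):
        x, _ = self.make_low_rank(rng, noise=0.05)
        basis = gen.fit_fpca(x, np.arange(x.shape[1]), k=3)
        prof = x[7]
        expected = [(prof - basis.mean) @ c for c in basis.components]
        np.testing.assert_allclose(gen.project_fpca(prof, basis), expected)

    def test_reconstruction_error_bounded_by_residual_variance(self, rng):
        x, _ = self.make_low_rank(rng, noise=0.2)
        grid = np.arange(x.shape[1])
        basis = gen.fit_fpca(x, grid, k=3)
        centred = x - basis.mean
        recon = gen.project_fpca(x, basis) @ basis.components
        resid = np.sum((centred - recon) ** 2)
        total = np.sum(centred ** 2)
        assert resid / total <= (1 - basis.cumulative_explained) + 1e-9

    def test_identical_profiles_degenerate(self, rng):
        with pytest.raises(ValueError):
            gen.fit_fpca(np.ones((10, 50)), np.arange(50), k=3)

    def test_too_few_profiles_rejected(self, rng):
        with pytest.raises(ValueError):
            gen.fit_fpca(rng.normal(size=(3, 50)), np.arange(50), k=3)


class TestDistinguishability:
    def test_tight_clusters_distinguishable(self, rng):
        amps = {
            ("hand", m): rng.normal(c, 0.02, 40)
            for m, c in ((1, 0.5), (2, 0.8), (3, 1.2))
        }
        res = gen.distinguishability_group("P1", amps)
        assert res.label == "distinguishable"
        assert res.modes[("hand", 1)] == pytest.approx(0.5, abs=0.05)
        assert res.modes[("hand", 3)] == pytest.approx(1.2, abs=0.05)

    def test_small_gap_indistinguishable(self, rng):
        amps = {
            ("hand", m): rng.normal(c, 0.02, 40)
            for m, c in ((1, 0.5), (2, 0.65), (3, 1.2))  # gap 0.15 <= 0.2
        }
        assert gen.distinguishability_group("P1", amps).label == \
            "indistinguishable"

    def test_identical_distributions_indistinguishable(self, rng):
        base = rng.normal(0.8, 0.1, 50)
        amps = {("hand", m): base for m in (1, 2, 3)}
        assert gen.distinguishability_group("P1", amps).label == \
            "indistinguishable"

    def test_any_channel_suffices(self, rng):
        amps = {("hand", m): rng.normal(0.8, 0.05, 40) for m in (1, 2, 3)}
        amps.update({
            ("shin", m): rng.normal(c, 0.02, 40)
            for m, c in ((1, 0.4), (2, 0.8), (3, 1.3))
        })
        assert gen.distinguishability_group("P1", amps).label == \
            "distinguishable"

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            gen.kde_mode(np.array([1.0, 2.0]))


class TestDirectionBias:
    FAST = inf.SamplerConfig(burn=1000, min_kept_steps=150, seed=2)

    def _frame(self, rng, right_shift=0.0):
        df, _ = model_feature_frame(
            rng,
            groups=(("congruent", ("C1", "C2", "C3")),),
            scales=("R", "L"),
            days=(1,),
            trials_per_cell=100,
        )
        df["direction"] = df["scale"]
        df["magnitude"] = 2
        df["session"] = 1
        df.loc[df.direction == "R", "epsilon"] *= np.exp(right_shift)
        return df

    def test_no_bias_interval_contains_zero(self, rng):
        df = self._frame(rng)
        # force identical generative means for both directions
        df["epsilon"] = np.exp(rng.normal(0.0, 0.4, len(df)))
        biases = gen.direction_bias(df, 2, "epsilon", self.FAST)
        cover = [b.ci95[0] <= 0.0 <= b.ci95[1] for b in biases]
        assert np.mean(cover) >= 0.66

    def test_known_shift_recovered(self, rng):
        df = self._frame(rng)
        df["epsilon"] = np.exp(rng.normal(0.0, 0.4, len(df)))
        df.loc[df.direction == "R", "epsilon"] *= np.exp(0.5)
        biases = gen.direction_bias(df, 2, "epsilon", self.FAST)
        # difference is on the pooled-standardised scale
        scale = inf.standardize_feature(df["epsilon"].to_numpy()).scale
        for b in biases:
            assert b.difference_draws.mean() * scale == pytest.approx(
                0.5, abs=0.2)

    def test_swapping_labels_negates_difference(self, rng):
        df = self._frame(rng)
        swapped = df.copy()
        swapped["direction"] = swapped["direction"].map({"R": "L", "L": "R"})
        a = gen.direction_bias(df, 2, "epsilon", self.FAST)
        b = gen.direction_bias(swapped, 2, "epsilon", self.FAST)
        for x, y in zip(a, b):
            assert x.difference_draws.mean() == pytest.approx(
                -y.difference_draws.mean(), abs=0.05)

    def test_missing_direction_rejected(self, rng):
        df = self._frame(rng)
        with pytest.raises(ValueError):
            gen.direction_bias(df[df.direction == "R"], 2, "epsilon",
                               self.FAST)
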