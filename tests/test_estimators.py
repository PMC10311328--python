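"""Prefix moment estimators, streaming exactness, dominance diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wildmoments as wm


def two_pass_prefixes(x):
    """Textbook oracle: recompute mean and n-1 variance from scratch per prefix."""
    means = [np.mean(x[: n + 1]) for n in range(len(x))]
    varis = [np.nan] + [np.var(x[: n + 1], ddof=1) for n in range(1, len(x))]
    return np.array(means), np.array(varis)


class TestPrefixMoments:
    def test_hand_example(self):
        series = wm.prefix_moments([1, 2, 3])
        np.testing.assert_allclose(series.mean_prefix, [1, 1.5, 2])
        assert np.isnan(series.var_prefix[0])
        np.testing.assert_allclose(series.var_prefix[1:], [0.5, 1.0])

    def test_constant_samples(self):
        series = wm.prefix_moments([5, 5, 5, 5])
        np.testing.assert_allclose(series.mean_prefix, 5.0)
        np.testing.assert_allclose(series.var_prefix[1:], 0.0)

    def test_streaming_matches_two_pass_at_scale(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        series = wm.prefix_moments(x)
        mean2, var2 = two_pass_prefixes(x)
        np.testing.assert_allclose(series.mean_prefix, mean2, rtol=1e-10)
        np.testing.assert_allclose(series.var_prefix[1:], var2[1:], rtol=1e-10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=60,
        )
    )
    def test_streaming_exactness_property(self, samples):
        """The single-pass estimates equal their defining finite sums on
        arbitrary inputs."""
        series = wm.prefix_moments(samples)
        mean2, var2 = two_pass_prefixes(np.asarray(samples, dtype=float))
        np.testing.assert_allclose(series.mean_prefix, mean2, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(series.var_prefix[1:], var2[1:], rtol=1e-9, atol=1e-6)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            wm.prefix_moments([])

    def test_poisson_prefix_converges(self):
        """Mild randomness: the mean estimate sits within 5 standard errors of
        the true mean at n = 10^4 in at least 99 of 100 seeded repetitions."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).poisson(10, size=10_000)
            mean = x.mean()
            if abs(mean - 10) < 5 * math.sqrt(10 / len(x)):
                hits += 1
        assert hits >= 99


class TestTimecourse:
    def test_deterministic_start(self, ensemble_P):
        df = wm.timecourse_moments(ensemble_P)
        assert df["mean"].iloc[0] == 1.0
        assert df["variance"].iloc[0] == 0.0
        assert (df["n_excluded"] == 0).all()

    def test_final_mean_matches_closed_form(self, ensemble_P):
        df = wm.timecourse_moments(ensemble_P)
        target = 10 - 9 * math.exp(-5)
        se = math.sqrt(df["variance"].iloc[-1] / df["n"].iloc[-1])
        assert abs(df["mean"].iloc[-1] - target) < 3 * se

    def test_identical_trajectories_have_zero_variance(self):
        dead = wm.ReactionSystem("dead", (wm.Reaction(nu=+1, kind="constant", rate=0.0),))
        ens = wm.run_ensemble(dead, 3, 1.0, 10, base_seed=0)
        df = wm.timecourse_moments(ens)
        assert (df["variance"] == 0.0).all()
        assert (df["mean"] == 3.0).all()

    def test_all_capped_yields_nan(self):
        growth = wm.build_system("pure_growth")
        ens = wm.run_ensemble(growth, 1, 30.0, 5, cap=100, base_seed=3)
        assert ens.capped_flags.all()
        df = wm.timecourse_moments(ens)
        assert df["mean"].isna().all()
        assert (df["n_excluded"] == 5).all()


class TestDominance:
    def test_planted_outlier_flagged(self):
        series = wm.prefix_moments([1, 1, 1, 1000])
        report = wm.dominance_diagnostic(series)
        assert report.index == 4
        assert report.gap > 5  # the estimate jumps by orders of magnitude
        # hand oracle: mean 250.75, so the outlier's squared-deviation share is
        # 749.25^2 / (3 * 249.75^2 + 749.25^2) = 0.75 exactly
        assert report.dominance_ratio == pytest.approx(0.75, abs=1e-12)
        assert report.mean_dominance_ratio == pytest.approx(1000 / 1003, abs=1e-12)

    def test_uniform_samples_are_undominated(self):
        x = np.random.default_rng(2).uniform(size=10_000)
        report = wm.dominance_diagnostic(wm.prefix_moments(x))
        assert report.dominance_ratio < 0.05

    def test_constant_samples_fall_back_to_mean_series(self):
        report = wm.dominance_diagnostic(wm.prefix_moments([5, 5, 5]))
        assert not report.variance_series_valid
        assert report.gap == 0.0

    def test_fat_tailed_samples_dominate_more_than_poisson(self):
        """Wild vs mild: single inverse-square draws take a strictly larger
        share of the mean sum than any Poisson draw does, seed by seed."""
        for seed in range(5):
            wild = wm.sample_reference("inverse_square", 10**5, seed=seed)
            mild = np.random.default_rng(seed).poisson(10, size=10**5)
            dom_wild = wm.dominance_diagnostic(wm.prefix_moments(wild))
            dom_mild = wm.dominance_diagnostic(wm.prefix_moments(mild))
            assert dom_wild.mean_dominance_ratio > dom_mild.mean_dominance_ratio

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            wm.dominance_diagnostic(wm.prefix_moments([1.0]))
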