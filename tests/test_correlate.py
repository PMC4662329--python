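"""Posterior-propagated correlations and the candidate linear models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from beetlecomp import (
    SimulationConfig,
    TraitPosterior,
    fit_candidate_lms,
    pearson_origin,
    posterior_correlation,
)
from beetlecomp.simulate import simulate_tree


class TestPearsonOrigin:
    def test_proportional_vectors_give_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert pearson_origin(x, 2 * x) == pytest.approx(1.0)
        assert pearson_origin(x, -2 * x) == pytest.approx(-1.0)

    def test_origin_orthogonal_vectors_give_zero(self):
        assert pearson_origin([1.0, 1.0], [1.0, -1.0]) == pytest.approx(0.0)

    def test_all_zero_vector_flagged_missing(self):
        assert np.isnan(pearson_origin([0.0, 0.0], [1.0, 2.0]))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=3, max_size=20
        ),
        st.integers(0, 2**16),
    )
    def test_joint_sign_flips_leave_r_unchanged(self, pairs, flip_seed):
        """Contrast signs are arbitrary (daughter order); r must not care."""
        x = np.array([p[0] for p in pairs]) + 0.1
        y = np.array([p[1] for p in pairs]) - 0.1
        signs = np.where(
            np.random.default_rng(flip_seed).random(len(x)) < 0.5, 1.0, -1.0
        )
        assert pearson_origin(x * signs, y * signs) == pytest.approx(
            pearson_origin(x, y), rel=1e-9, abs=1e-12
        )


def tp(name, draws, groups):
    return TraitPosterior(name, np.asarray(draws, float), groups)


class TestPosteriorCorrelation:
    def test_identical_traits_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal((200, 5))
        cp = posterior_correlation(tp("a", d, list("ABCDE")), tp("b", d, list("ABCDE")))
        np.testing.assert_allclose(cp.r_draws, 1.0)
        assert cp.ci_95 == (1.0, 1.0)
        assert cp.significant

    def test_single_draw_collapses_to_plugin_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        groups = [f"G{i}" for i in range(8)]
        cp = posterior_correlation(tp("a", x[None, :], groups), tp("b", y[None, :], groups))
        assert cp.r_draws.shape == (1,)
        assert cp.r_draws[0] == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_draw_misalignment_rejected(self):
        a = tp("a", np.ones((10, 3)), list("ABC"))
        b = tp("b", np.ones((11, 3)), list("ABC"))
        with pytest.raises(ValueError, match="draw-count"):
            posterior_correlation(a, b)

    def test_too_few_shared_groups_rejected(self):
        rng = np.random.default_rng(3)
        a = tp("a", rng.standard_normal((5, 3)), list("ABC"))
        b = tp("b", rng.standard_normal((5, 2)), list("AB"))
        with pytest.raises(ValueError, match="too few"):
            posterior_correlation(a, b)

    def test_groups_missing_one_trait_are_pruned_pairwise(self):
        rng = np.random.default_rng(4)
        a = tp("a", rng.standard_normal((50, 5)), list("ABCDE"))
        b = tp("b", rng.standard_normal((50, 4)), list("ABCD"))  # E lacks trait b
        cp = posterior_correlation(a, b)
        assert cp.groups == list("ABCD")

    def test_pic_variant_needs_tree_and_prunes_it(self):
        rng = np.random.default_rng(5)
        tree = simulate_tree(SimulationConfig(seed=5))
        groups = sorted(tree.tip_labels)
        a = tp("a", rng.standard_normal((50, 16)), groups)
        b = tp("b", rng.standard_normal((50, 15)), groups[:-1])
        with pytest.raises(ValueError, match="tree"):
            posterior_correlation(a, b, variant="pic")
        cp = posterior_correlation(a, b, variant="pic", tree=tree)
        assert len(cp.groups) == 15
        assert np.all(np.abs(cp.r_draws) <= 1 + 1e-12)

    def test_interval_covers_zero_for_independent_noise_traits(self):
        """Traits independent across groups *and* draws: the 95% interval
        should include zero in roughly 95% of replicates."""
        rng = np.random.default_rng(7)
        g = [f"G{i}" for i in range(16)]
        include = 0
        n_rep = 200
        for _ in range(n_rep):
            a = tp("a", rng.standard_normal((300, 16)), g)
            b = tp("b", rng.standard_normal((300, 16)), g)
            include += not posterior_correlation(a, b).significant
        assert include / n_rep > 0.90

    def test_wider_posteriors_do_not_narrow_the_interval(self):
        """Propagation law, checked statistically across seeds."""
        rng = np.random.default_rng(6)
        widths_tight, widths_wide = [], []
        for _ in range(10):
            base_a = rng.standard_normal(10)
            base_b = rng.standard_normal(10)
            tight_a = base_a + 0.05 * rng.standard_normal((400, 10))
            tight_b = base_b + 0.05 * rng.standard_normal((400, 10))
            wide_a = base_a + 0.8 * rng.standard_normal((400, 10))
            wide_b = base_b + 0.8 * rng.standard_normal((400, 10))
            g = [f"G{i}" for i in range(10)]
            ci_t = posterior_correlation(tp("a", tight_a, g), tp("b", tight_b, g)).ci_95
            ci_w = posterior_correlation(tp("a", wide_a, g), tp("b", wide_b, g)).ci_95
            widths_tight.append(ci_t[1] - ci_t[0])
            widths_wide.append(ci_w[1] - ci_w[0])
        assert np.mean(widths_wide) > np.mean(widths_tight)


class TestCandidateModels:
    def _means(self, n=15, seed=0, response=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "delta": rng.normal(0, 0.3, n),
                "log_h": rng.normal(2, 1, n),
            },
            index=[f"G{i:02d}" for i in range(n)],
        )
        df["L"] = (
            response(df) if response is not None else rng.normal(0, 0.3, n)
        )
        return df

    def test_exact_linear_response_crushes_null(self):
        df = self._means(response=lambda d: 0.5 * d["delta"] - 0.1)
        with pytest.warns(UserWarning, match="ignore"):
            table = fit_candidate_lms(df)
        assert table.loc["inbreeding", "lrt_p"] < 1e-6
        assert table.loc["null", "aic_weight"] < 0.01

    def test_weights_sum_to_one_and_k_counts(self):
        df = self._means(seed=1)
        with pytest.warns(UserWarning):
            table = fit_candidate_lms(df)
        assert table["aic_weight"].sum() == pytest.approx(1.0)
        assert list(table["k"]) == [2, 3, 3, 4, 5]
        assert (table["n"] == 15).all()

    def test_complete_cases_only(self):
        df = self._means(seed=2)
        df.loc["G00", "delta"] = np.nan
        with pytest.warns(UserWarning):
            table = fit_candidate_lms(df)
        assert (table["n"] == 14).all()

    def test_null_wins_majority_under_noise(self):
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            df = self._means(seed=100 + seed)
            with pytest.warns(UserWarning):
                table = fit_candidate_lms(df)
            wins += table["aic_weight"].idxmax() == "null"
        assert wins / n_rep > 0.5

    def test_loglik_matches_statsmodels_closed_form(self):
        """Gaussian ML log-likelihood cross-check on the null model."""
        df = self._means(seed=3)
        with pytest.warns(UserWarning):
            table = fit_candidate_lms(df)
        y = df["L"].to_numpy()
        n = len(y)
        s2 = ((y - y.mean()) ** 2).mean()
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        assert table.loc["null", "loglik"] == pytest.approx(ll)

    def test_underdetermined_model_flagged_unfit(self):
        df = self._means(n=4, seed=4)
        with pytest.warns(UserWarning):
            table = fit_candidate_lms(df)
        assert np.isnan(table.loc["interaction", "aic"])
        assert table.loc["null", "aic_weight"] > 0
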