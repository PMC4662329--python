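"""Synthetic-study generator: determinism, design arithmetic, BM correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beetlecomp import Phylogeny, SimulationConfig
from beetlecomp.simulate import (
    _truncated_poisson,
    fixture_tree,
    simulate_dispersal,
    simulate_inbreeding,
    simulate_mating,
    simulate_study,
    simulate_traits,
    simulate_tree,
)


class TestConfig:
    def test_even_patch_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SimulationConfig(n_patches=40)

    def test_non_psd_correlation_rejected(self):
        bad = ((1.0, 0.99, -0.99), (0.99, 1.0, 0.99), (-0.99, 0.99, 1.0))
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(trait_correlations=bad)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_trials=8)
        cfg.to_yaml(tmp_path / "c.yaml")
        again = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert again == cfg


class TestDeterminism:
    def test_identical_seed_gives_identical_tables(self):
        a = simulate_study(SimulationConfig(seed=4))
        b = simulate_study(SimulationConfig(seed=4))
        assert a["tree"].newick() == b["tree"].newick()
        for key in ("true_traits", "dispersal", "crosses", "mating"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_different_seed_changes_tables(self):
        a = simulate_study(SimulationConfig(seed=4))
        b = simulate_study(SimulationConfig(seed=5))
        assert not a["dispersal"].equals(b["dispersal"])


class TestTree:
    def test_sixteen_tips_gives_rooted_binary_tree(self):
        tree = simulate_tree(SimulationConfig(seed=1))
        assert tree.n_tips == 16
        assert tree.is_binary()
        internal = sum(1 for _ in tree.tree.preorder_internal_node_iter())
        assert internal == 15
        edges = sum(
            1
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
        )
        assert edges == 30

    def test_branch_lengths_strictly_positive(self):
        for seed in range(5):
            tree = simulate_tree(SimulationConfig(seed=seed))
            assert all(
                n.edge.length > 0
                for n in tree.tree.preorder_node_iter()
                if n.parent_node is not None
            )

    def test_fixture_tree_matches_study_groups(self):
        tree = fixture_tree()
        assert tree.n_tips == 16
        assert tree.is_binary()
        assert {"ACOB", "CAPH", "ZASU", "MALI", "YEME"} <= set(tree.tip_labels)

    def test_minimum_group_count_enforced(self):
        with pytest.raises(ValueError, match="n_groups"):
            SimulationConfig(n_groups=2)


class TestBrownianTraits:
    def test_zero_rates_pin_tips_to_root(self):
        cfg = SimulationConfig(seed=2, trait_bm_rates=(0.0, 0.0, 0.0))
        tree = simulate_tree(cfg)
        tr = simulate_traits(tree, cfg)
        for col, root in zip(["L", "delta", "log_h"], cfg.trait_root_values):
            np.testing.assert_allclose(tr[col], root)

    def test_perfect_correlation_locks_increments(self):
        R = ((1.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 1.0))
        cfg = SimulationConfig(
            seed=3,
            trait_correlations=R,
            trait_bm_rates=(0.5, 0.2, 0.5),
            trait_root_values=(0.0, 0.0, 0.0),
        )
        tree = simulate_tree(cfg)
        tr = simulate_traits(tree, cfg)
        np.testing.assert_allclose(tr["L"], tr["log_h"], atol=1e-12)

    def test_tip_covariance_matches_shared_path_lengths(self):
        """Monte-Carlo check of the closed-form BM tip covariance."""
        tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        cfg = SimulationConfig(
            seed=0, trait_bm_rates=(1.0, 1.0, 1.0), trait_root_values=(0, 0, 0)
        )
        rng = np.random.default_rng(12)
        n_rep = 4000
        vals = np.empty((n_rep, 4))
        for r in range(n_rep):
            tr = simulate_traits(tree, cfg, rng)
            vals[r] = tr["L"].loc[["A", "B", "C", "D"]].to_numpy()
        emp = np.cov(vals, rowvar=False)
        # shared path length from root, rate 1
        expected = np.array(
            [[3, 2, 1, 0], [2, 3, 1, 0], [1, 1, 3, 0], [0, 0, 0, 3]], dtype=float
        )
        se = 3.0 * expected.max() * np.sqrt(2.0 / n_rep) * 3  # ~3 sigma, crude
        assert np.max(np.abs(emp - expected)) < se


class TestDispersalGenerator:
    def test_no_mortality_gives_thirty_rows_per_sex(self):
        cfg = SimulationConfig(seed=6, mortality_prob=0.0, n_trials=6)
        tt = pd.DataFrame({"L": [0.0, -0.5]}, index=["A", "B"])
        df = simulate_dispersal(tt, cfg)
        counts = df.groupby(["group", "sex"]).size()
        assert (counts == 30).all()

    def test_symmetric_generator_at_zero_bias(self):
        cfg = SimulationConfig(seed=7, mortality_prob=0.0, n_trials=40)
        tt = pd.DataFrame({"L": [0.0]}, index=["A"])
        df = simulate_dispersal(tt, cfg)
        f = df[df.sex == "F"]["distance"].astype(int)
        m = df[df.sex == "M"]["distance"].astype(int)
        _, p = stats.ttest_ind(f, m)
        assert p > 0.01

    def test_truncated_poisson_mean_unaffected_when_tail_negligible(self):
        rng = np.random.default_rng(8)
        draws = _truncated_poisson(rng, 3.0, 100_000, 20)
        se = np.sqrt(3.0 / len(draws))
        # tail mass beyond 20 at mu=3 is ~1e-10: truncation bias invisible
        assert stats.poisson.sf(20, 3.0) < 1e-9
        assert abs(draws.mean() - 3.0) < 3 * se

    def test_truncation_warning_when_tail_substantial(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning, match="array edge"):
            _truncated_poisson(rng, 18.0, 100, 20)

    def test_dead_rows_have_missing_distance(self):
        cfg = SimulationConfig(seed=10, mortality_prob=0.5)
        tt = pd.DataFrame({"L": [0.0]}, index=["A"])
        df = simulate_dispersal(tt, cfg)
        assert df.loc[df["died"], "distance"].isna().all()
        assert df.loc[~df["died"], "distance"].notna().all()


class TestInbreedingGenerator:
    def test_design_arithmetic(self):
        cfg = SimulationConfig(seed=11)
        tt = pd.DataFrame({"delta": np.zeros(16)}, index=[f"G{i}" for i in range(16)])
        df = simulate_inbreeding(tt, cfg)
        assert len(df) == 16 * 3 * 4
        per_block = df.groupby(["group", "block"])["cross_type"].value_counts()
        assert (per_block == 2).all()

    def test_zero_variance_counts_are_poisson(self):
        cfg = SimulationConfig(
            seed=12, sigma_block=0.0, sigma_family=0.0, n_blocks=250
        )
        tt = pd.DataFrame({"delta": [0.0]}, index=["A"])
        df = simulate_inbreeding(tt, cfg)
        lam = np.exp(cfg.baseline_log_mean)
        x = df["offspring_count"]
        assert abs(x.mean() - lam) < 3 * np.sqrt(lam / len(x))
        # Poisson: variance ~ mean
        assert 0.8 < x.var() / lam < 1.25

    def test_inbred_outbred_ratio_matches_delta(self):
        cfg = SimulationConfig(
            seed=13, sigma_block=0.0, sigma_family=0.0, n_blocks=400
        )
        tt = pd.DataFrame({"delta": [-0.3]}, index=["A"])
        df = simulate_inbreeding(tt, cfg)
        m = df.groupby("cross_type")["offspring_count"].mean()
        assert abs(m["inbred"] / m["outbred"] - 0.7) < 0.03

    def test_excluded_group_absent(self):
        cfg = SimulationConfig(seed=14, inbreeding_groups_excluded=("B",))
        tt = pd.DataFrame({"delta": [0.0, 0.0]}, index=["A", "B"])
        df = simulate_inbreeding(tt, cfg)
        assert set(df["group"]) == {"A"}

    def test_extinction_level_delta_rejected(self):
        cfg = SimulationConfig(seed=15)
        tt = pd.DataFrame({"delta": [-1.0]}, index=["A"])
        with pytest.raises(ValueError, match="delta"):
            simulate_inbreeding(tt, cfg)


class TestMatingGenerator:
    def test_design_arithmetic(self):
        cfg = SimulationConfig(seed=16)
        tt = pd.DataFrame({"log_h": [0.0, 1.0]}, index=["A", "B"])
        df = simulate_mating(tt, cfg)
        assert (df.groupby("group").size() == 18).all()
        cells = df.groupby(["group", "females_0", "males_0"]).size()
        assert (cells == 2).all()

    def test_counts_have_poisson_mean(self):
        from beetlecomp import recruitment_mean

        cfg = SimulationConfig(seed=17, mating_replicates=400)
        tt = pd.DataFrame({"log_h": [0.0]}, index=["A"])
        df = simulate_mating(tt, cfg)
        sub = df[(df.females_0 == 5) & (df.males_0 == 5)]
        expected = recruitment_mean(5, 5, cfg.mating_lambda, 1.0)
        assert abs(sub["recruits_1"].mean() - expected) < 3 * np.sqrt(
            expected / len(sub)
        )
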