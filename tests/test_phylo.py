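"""Independent contrasts: pruning oracle, invariances, rooting, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from beetlecomp import (
    Phylogeny,
    SimulationConfig,
    contrast_matrix,
    pic,
    pic_diagnostic,
    root_tree,
)
from beetlecomp.correlate import pearson_origin
from beetlecomp.simulate import simulate_traits, simulate_tree


class TestWorkedExample:
    """Hand-computed pruning on ((A:1,B:1):1,C:2) with A=1, B=3, C=6.

    First contrast (A,B): (1-3)/sqrt(2); ancestral value 2 on a branch
    lengthened to 1 + 1*1/2 = 1.5; second contrast (AB,C): (2-6)/sqrt(3.5).
    """

    def test_contrasts_and_sds(self, three_tip_tree):
        cs = pic(three_tip_tree, {"A": 1.0, "B": 3.0, "C": 6.0})
        np.testing.assert_allclose(
            sorted(cs.contrasts), [-2.13808993, -1.41421356], atol=1e-6
        )
        np.testing.assert_allclose(
            sorted(cs.expected_sds), [np.sqrt(2), np.sqrt(3.5)], atol=1e-12
        )
        assert len(cs) == 2

    def test_constant_tips_give_zero_contrasts(self, three_tip_tree):
        cs = pic(three_tip_tree, {"A": 7.0, "B": 7.0, "C": 7.0})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    def test_linearity_in_tip_values(self, three_tip_tree):
        vals = {"A": 1.0, "B": 3.0, "C": 6.0}
        base = pic(three_tip_tree, vals).contrasts
        scaled = pic(three_tip_tree, {k: 2.5 * v for k, v in vals.items()}).contrasts
        np.testing.assert_allclose(scaled, 2.5 * base, atol=1e-12)

    def test_missing_tip_value_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="without trait values"):
            pic(three_tip_tree, {"A": 1.0, "B": 3.0})


class TestAgainstApe:
    def test_matches_r_ape_pic_on_random_tree(self, tmp_path):
        """Independent oracle: ape::pic in R on one simulated tree."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cfg = SimulationConfig(seed=77)
        tree = simulate_tree(cfg)
        traits = simulate_traits(tree, cfg)
        order = sorted(tree.tip_labels)
        (tmp_path / "t.nwk").write_text(tree.newick() + "\n")
        vals = ",".join(repr(float(traits.loc[g, "L"])) for g in order)
        names = ",".join(f"'{g}'" for g in order)
        script = (
            "suppressMessages(library(ape));"
            f"tr <- read.tree('{tmp_path}/t.nwk');"
            f"x <- c({vals}); names(x) <- c({names});"
            "cat(sort(pic(x, tr)), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        A, _, _ = contrast_matrix(tree, order)
        ours = np.sort(A @ traits.loc[order, "L"].to_numpy())
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestInvariances:
    def test_rotation_flips_signs_but_not_origin_correlation(self):
        t1 = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        t2 = Phylogeny.from_newick("((B:1,A:1):1,C:2);")  # daughters swapped
        x = {"A": 1.0, "B": 3.0, "C": 6.0}
        y = {"A": 2.0, "B": 1.0, "C": 4.0}
        cx1, cx2 = pic(t1, x).contrasts, pic(t2, x).contrasts
        cy1, cy2 = pic(t1, y).contrasts, pic(t2, y).contrasts
        np.testing.assert_allclose(np.abs(cx1), np.abs(cx2))
        assert pearson_origin(cx1, cy1) == pytest.approx(
            pearson_origin(cx2, cy2), abs=1e-12
        )

    def test_contrast_count_is_tips_minus_one(self):
        for seed in range(3):
            tree = simulate_tree(SimulationConfig(seed=seed))
            A, sds, ids = contrast_matrix(tree)
            assert A.shape == (15, 16)
            assert len(sds) == len(ids) == 15

    def test_pruned_tree_loses_one_contrast(self):
        tree = simulate_tree(SimulationConfig(seed=3))
        keep = sorted(tree.tip_labels)[:-1]
        sub = tree.prune_to(keep)
        A, _, _ = contrast_matrix(sub)
        assert A.shape == (14, 15)

    def test_zero_length_branch_nudged_with_warning(self):
        t = Phylogeny.from_newick("((A:0,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="zero-length"):
            cs = pic(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert np.all(np.isfinite(cs.contrasts))


class TestRooting:
    def test_midpoint_preserves_tip_to_tip_distance(self):
        tree = Phylogeny.from_newick("((A:1,B:4):1,C:2);")
        rooted = root_tree(tree, "midpoint")
        pdm = rooted.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in rooted.tree.taxon_namespace}
        assert pdm.patristic_distance(taxa["A"], taxa["B"]) == pytest.approx(5.0)
        assert rooted.is_binary()

    def test_two_tip_tree_rooted_at_edge_midpoint(self):
        rooted = root_tree(Phylogeny.from_newick("(A:1,B:3);"), "midpoint")
        lengths = sorted(
            n.edge.length
            for n in rooted.tree.preorder_node_iter()
            if n.parent_node is not None
        )
        assert lengths == pytest.approx([2.0, 2.0])

    def test_outgroup_rooting_places_outgroup_at_root(self):
        from beetlecomp.simulate import fixture_tree

        rooted = root_tree(fixture_tree(), "outgroup", outgroup="ACOB")
        root_children = rooted.tree.seed_node.child_nodes()
        labels = [c.taxon.label for c in root_children if c.is_leaf()]
        assert "ACOB" in labels

    def test_absent_outgroup_rejected(self, three_tip_tree):
        with pytest.raises(Exception, match="not found"):
            root_tree(three_tip_tree, "outgroup", outgroup="ZZZZ")


class TestDiagnostic:
    def test_brownian_traits_usually_adequate(self):
        verdicts = []
        for seed in range(60):
            cfg = SimulationConfig(seed=500 + seed)
            tree = simulate_tree(cfg)
            tr = simulate_traits(tree, cfg)
            verdicts.append(pic_diagnostic(pic(tree, tr["L"]))["verdict"])
        rate = np.mean([v == "adequate" for v in verdicts])
        assert rate > 0.85  # nominal 95%, binomial noise at n=60

    def test_non_brownian_variance_structure_rejected_more_often(self):
        """Traits with variance ~ branch-length^2 violate the standardization."""
        rng = np.random.default_rng(99)
        rejected = 0
        n = 60
        for seed in range(n):
            tree = simulate_tree(SimulationConfig(seed=800 + seed))
            vals = {}
            for leaf in tree.tree.leaf_node_iter():
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length**2 * 25  # variance ∝ length^2
                    node = node.parent_node
                vals[leaf.taxon.label] = rng.normal(0, np.sqrt(d))
            if pic_diagnostic(pic(tree, vals))["verdict"] == "inadequate":
                rejected += 1
        assert rejected / n > 0.15

    def test_equal_contrasts_adequate(self, three_tip_tree):
        from beetlecomp import ContrastSet

        cs = ContrastSet(np.ones(6), np.ones(6), list("abcdef"))
        rep = pic_diagnostic(cs)
        assert rep["verdict"] == "adequate"

    def test_too_few_contrasts_insufficient(self, three_tip_tree):
        cs = pic(three_tip_tree, {"A": 1.0, "B": 3.0, "C": 6.0})
        assert pic_diagnostic(cs)["verdict"] == "insufficient"
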