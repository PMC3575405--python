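"""ARG data model: validation, marginal trees, material, breakpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from argsample.arg import (
    Arg,
    COALESCENT,
    RECOMBINATION,
    annotate_ancestral_material,
    enumerate_breakpoints,
    extract_marginal_tree,
    interval_span_gaps,
    intersect_intervals,
    marginal_trees,
    merge_intervals,
    tmrca_profile_of_arg,
    union_intervals,
    validate,
)
from argsample.simulate import SimulationSpec, simulate_arg


class TestValidate:
    def test_minimal_valid_arg(self, two_tip_tree):
        assert validate(two_tip_tree) == []

    def test_negative_height_reported(self, two_tip_tree):
        two_tip_tree.root.height = -0.1
        msgs = validate(two_tip_tree)
        assert any("height" in m for m in msgs)

    def test_recombination_arity_violation(self, two_tip_tree):
        arg = two_tip_tree
        bad = arg.new_node(0.5, RECOMBINATION, breakpoint=3)
        # give the recombination two children (and wire parents loosely)
        t1, t2 = arg.tips()
        bad.children = [t1, t2]
        msgs = validate(arg)
        assert any("recombination has 2 children" in m for m in msgs)

    def test_simulated_args_valid(self):
        for seed in range(5):
            arg = simulate_arg(SimulationSpec(n=6, L=300, theta=0.5, rho=2.0), seed)
            assert validate(arg) == []


class TestMarginalTrees:
    def test_no_recombination_tree_matches_arg(self, two_tip_tree):
        tree = extract_marginal_tree(two_tip_tree, 0)
        assert tree.tmrca == 0.3
        assert tree.leaf_labels() == {"a", "b"}

    def test_site_out_of_range(self, two_tip_tree):
        with pytest.raises(ValueError):
            extract_marginal_tree(two_tip_tree, 10)

    def test_hand_built_routing(self, three_tip_recombinant):
        left = extract_marginal_tree(three_tip_recombinant, 0)
        right = extract_marginal_tree(three_tip_recombinant, 9)
        # site 0: ((A,B),C) rooted at the grand MRCA
        assert left.tmrca == 0.3
        ab = [c for c in left.root.children if c.children][0]
        assert {l.label for l in ab.children} == {"A", "B"}
        assert ab.height == 0.2
        # site 9: ((A,C),B) with TMRCA 0.2 (root-ward unary suppressed)
        assert right.tmrca == 0.2
        ac = [c for c in right.root.children if c.children][0]
        assert {l.label for l in ac.children} == {"A", "C"}
        assert ac.height == 0.15

    @pytest.mark.parametrize("seed", range(4))
    def test_intervals_match_per_site_extraction(self, seed):
        arg = simulate_arg(SimulationSpec(n=5, L=120, theta=0.5, rho=2.0), seed)
        mts = marginal_trees(arg)
        assert mts[0][0].start == 0 and mts[-1][0].end == 120
        for (iv1, _), (iv2, _) in zip(mts, mts[1:]):
            assert iv1.end == iv2.start  # exact partition, no gaps
        for site in range(120):
            tree = extract_marginal_tree(arg, site)
            (interval_tree,) = [t for iv, t in mts if iv.start <= site < iv.end]
            assert tree == interval_tree

    def test_every_marginal_tree_ultrametric_binary(self):
        arg = simulate_arg(SimulationSpec(n=6, L=80, theta=0.5, rho=2.0), 7)
        for site in range(0, 80, 7):
            tree = extract_marginal_tree(arg, site)
            assert tree.n_leaves() == 6

            def check(node):
                if node.children:
                    assert len(node.children) == 2
                    for c in node.children:
                        assert c.height < node.height
                        check(c)
                else:
                    assert node.height == 0.0

            check(tree.root)


class TestAncestralMaterial:
    def test_tip_edges_carry_everything(self, three_tip_recombinant):
        for tip in three_tip_recombinant.tips():
            assert tip.ancestral_material == ((0, 10),)

    def test_recombination_split(self, three_tip_recombinant):
        rec = three_tip_recombinant.recombination_nodes()[0]
        arg = three_tip_recombinant
        assert arg.edge_material(rec, 0) == ((0, 5),)
        assert arg.edge_material(rec, 1) == ((5, 10),)

    def test_idempotent(self):
        arg = simulate_arg(SimulationSpec(n=5, L=100, theta=0.5, rho=1.5), 3)
        before = {n.id: n.ancestral_material for n in arg.nodes.values()}
        annotate_ancestral_material(arg)
        after = {n.id: n.ancestral_material for n in arg.nodes.values()}
        assert before == after

    @pytest.mark.parametrize("seed", range(3))
    def test_material_covers_every_site_until_mrca(self, seed):
        """At any time level, the edges crossing it jointly cover each
        site at least once (and at least twice below the site's MRCA)."""
        arg = simulate_arg(SimulationSpec(n=5, L=60, theta=0.5, rho=2.0), seed)
        heights = sorted(n.height for n in arg.nodes.values() if n.kind != "tip")
        for h_lo, h_hi in zip([0.0] + heights[:-1], heights):
            level = 0.5 * (h_lo + h_hi)
            cover = np.zeros(60, dtype=int)
            for c, j, p in arg.edges():
                if c.height <= level < p.height:
                    for s, e in arg.edge_material(c, j):
                        cover[s:e] += 1
            for site in range(60):
                mrca_h = extract_marginal_tree(arg, site).tmrca
                if level < mrca_h:
                    assert cover[site] >= 2
                else:
                    assert cover[site] >= 1


class TestBreakpointEnumeration:
    def test_zero_recombination_empty(self, two_tip_tree):
        assert enumerate_breakpoints(two_tip_tree) == []

    def test_classes(self, undetectable_arg):
        recs = {r.site: r.detectability for r in enumerate_breakpoints(undetectable_arg)}
        assert recs == {1000: "trivial", 500: "non_ancestral", 1500: "detectable"}

    def test_undetectable_sides_identical(self, undetectable_arg):
        for b in (500, 1000):
            assert (extract_marginal_tree(undetectable_arg, b - 1)
                    == extract_marginal_tree(undetectable_arg, b))
        assert (extract_marginal_tree(undetectable_arg, 1499)
                != extract_marginal_tree(undetectable_arg, 1500))

    def test_merged_intervals_skip_undetectable(self, undetectable_arg):
        mts = marginal_trees(undetectable_arg)
        assert [tuple(iv) for iv, _ in mts] == [(0, 1500), (1500, 2000)]

    def test_tmrca_profile_constant_when_roots_agree(self, undetectable_arg):
        # both marginal trees happen to root at the grand MRCA, so the
        # TMRCA step function collapses to a single constant interval
        prof = tmrca_profile_of_arg(undetectable_arg)
        assert [(iv.start, iv.end, h) for iv, h in prof] == [(0, 2000, 0.05)]

    def test_tmrca_profile_matches_marginal_roots(self):
        arg = simulate_arg(SimulationSpec(n=5, L=100, theta=0.5, rho=2.0), 11)
        prof = tmrca_profile_of_arg(arg)
        for site in range(100):
            (h,) = [h for iv, h in prof if iv.start <= site < iv.end]
            assert h == extract_marginal_tree(arg, site).tmrca


class TestSerialization:
    def test_json_round_trip(self, three_tip_recombinant):
        arg2 = Arg.from_json(three_tip_recombinant.to_json())
        annotate_ancestral_material(arg2)
        assert validate(arg2) == []
        assert arg2.to_json() == three_tip_recombinant.to_json()
        for site in (0, 9):
            assert (extract_marginal_tree(arg2, site)
                    == extract_marginal_tree(three_tip_recombinant, site))

    def test_graphml_contains_nodes_and_breakpoint(self, three_tip_recombinant):
        xml = three_tip_recombinant.to_graphml()
        assert "graphml" in xml and "breakpoint" in xml

    def test_newick_deterministic_and_parseable(self, three_tip_recombinant):
        import dendropy

        nwk = extract_marginal_tree(three_tip_recombinant, 0).newick()
        assert nwk == extract_marginal_tree(three_tip_recombinant, 0).newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B", "C"}


class TestIntervalOps:
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_merge_invariants(self, raw):
        merged = merge_intervals(raw)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert s1 < e1 and s2 < e2
            assert e1 < s2  # sorted, non-overlapping, non-adjacent
        covered = {x for s, e in raw if e > s for x in range(s, e)}
        covered2 = {x for s, e in merged for x in range(s, e)}
        assert covered == covered2

    @given(
        st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)), max_size=5),
        st.integers(0, 30), st.integers(0, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_intersection_subset(self, raw, lo, hi):
        base = merge_intervals(raw)
        cut = intersect_intervals(base, lo, hi)
        pts = {x for s, e in cut for x in range(s, e)}
        base_pts = {x for s, e in base for x in range(s, e)}
        assert pts == {x for x in base_pts if lo <= x < hi}

    def test_span_gaps_counts_holes(self):
        assert interval_span_gaps(((0, 10),)) == 9
        assert interval_span_gaps(((0, 1),)) == 0
        assert interval_span_gaps(()) == 0
        assert interval_span_gaps(((0, 5), (20, 30))) == 29
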