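"""Collectors: breakpoint density, TMRCA bands, consensus trees, ESS."""

import math

import numpy as np
import pytest

from argsample.arg import Arg, COALESCENT, annotate_ancestral_material, extract_marginal_tree
from argsample.collect import (
    BreakpointDensity2D,
    TmrcaProfileAccumulator,
    consensus_tree_at_site,
    effective_sample_size,
)
from argsample.arg import MarginalTree, TreeNode
from argsample.simulate import SimulationSpec, simulate_arg


def chain_tree(order, heights):
    """Caterpillar tree over labels in `order` with given merge heights."""
    node = TreeNode(0.0, label=order[0])
    for label, h in zip(order[1:], heights):
        node = TreeNode(h, children=[node, TreeNode(0.0, label=label)])
    return MarginalTree(node)


class TestBreakpointDensity:
    def test_single_breakpoint_single_bin(self):
        arg = simulate_arg(SimulationSpec(n=2, L=1000, theta=1.0, rho=0.0), 1)
        # splice one recombination in by hand is unnecessary: use a
        # simulated ARG with exactly one breakpoint
        seed = 0
        while True:
            arg = simulate_arg(SimulationSpec(n=3, L=1000, theta=1.0, rho=0.5), seed)
            if len(arg.recombination_nodes()) == 1:
                break
            seed += 1
        density = BreakpointDensity2D(1000, max_height=10.0)
        density.add(arg)
        assert density.total == 1
        assert (density.counts > 0).sum() == 1

    def test_zero_recombination_unchanged(self):
        arg = simulate_arg(SimulationSpec(n=4, L=100, theta=0.5, rho=0.0), 2)
        density = BreakpointDensity2D(100, 5.0)
        density.add(arg)
        assert density.total == 0

    def test_count_conservation_and_clamping(self):
        density = BreakpointDensity2D(200, max_height=0.001)  # tiny range
        expected = 0
        for seed in range(10):
            arg = simulate_arg(SimulationSpec(n=5, L=200, theta=1.0, rho=2.0), seed)
            expected += len(arg.recombination_nodes())
            density.add(arg)
        assert density.total == expected  # overflow heights clamp, not drop

    def test_merge_equals_concatenation(self):
        args = [simulate_arg(SimulationSpec(n=5, L=200, theta=1.0, rho=2.0), s)
                for s in range(8)]
        full = BreakpointDensity2D(200, 5.0)
        a, b = BreakpointDensity2D(200, 5.0), BreakpointDensity2D(200, 5.0)
        for arg in args:
            full.add(arg)
        for arg in args[:3]:
            a.add(arg)
        for arg in args[3:]:
            b.add(arg)
        a.merge(b)
        assert np.array_equal(a.counts, full.counts)


class TestTmrcaAccumulator:
    def test_identical_args_zero_width_band(self):
        arg = simulate_arg(SimulationSpec(n=5, L=100, theta=0.5, rho=1.0), 3)
        acc = TmrcaProfileAccumulator(100, n_grid=50)
        for _ in range(5):
            acc.add(arg)
        sites, mean, lo, hi = acc.summary()
        assert np.array_equal(lo, hi) and np.array_equal(lo, mean)
        for i, s in enumerate(sites):
            assert mean[i] == extract_marginal_tree(arg, int(s)).tmrca

    def test_two_constant_profiles(self):
        def flat_arg(h):
            arg = Arg(10)
            a, b = arg.add_tip("a"), arg.add_tip("b")
            root = arg.new_node(h, COALESCENT)
            Arg.connect(a, 0, root)
            Arg.connect(b, 0, root)
            return annotate_ancestral_material(arg)

        acc = TmrcaProfileAccumulator(10, n_grid=10)
        acc.add(flat_arg(0.2))
        acc.add(flat_arg(0.6))
        _, mean, lo, hi = acc.summary(lower=0.0, upper=1.0)
        assert np.allclose(mean, 0.4)
        assert np.allclose(lo, 0.2) and np.allclose(hi, 0.6)

    def test_prior_mean_matches_closed_form(self):
        n, theta = 10, 1.0
        acc = TmrcaProfileAccumulator(50, n_grid=5)
        for seed in range(800):
            acc.add(simulate_arg(SimulationSpec(n=n, L=50, theta=theta, rho=0.0),
                                 seed))
        _, mean, _, _ = acc.summary()
        samples = np.vstack(acc.samples)[:, 0]
        se = samples.std(ddof=1) / math.sqrt(len(samples))
        assert abs(mean[0] - theta * (1 - 1 / n)) < 3 * se


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = chain_tree("abcd", [0.1, 0.2, 0.3])
        cons = consensus_tree_at_site([t, t, t])
        # same topology; heights agree up to float summation error
        assert cons.tree.newick(precision=9) == t.newick(precision=9)
        assert all(v == 1.0 for v in cons.supports.values())

    def test_two_thirds_clade_retained(self):
        t1 = chain_tree("abcd", [0.1, 0.2, 0.3])   # ((a,b),c),d
        t2 = chain_tree("abdc", [0.1, 0.2, 0.3])   # ((a,b),d),c
        t3 = chain_tree("cdab", [0.1, 0.2, 0.3])   # no (a,b) clade... but (c,d)
        cons = consensus_tree_at_site([t1, t2, t3])
        ab = frozenset({"a", "b"})
        assert cons.supports[ab] == pytest.approx(2 / 3)
        # mean height over the supporting trees only
        clades = cons.supports.keys()
        assert ab in clades

    def test_exact_half_dropped(self):
        t1 = chain_tree("abcd", [0.1, 0.2, 0.3])
        t2 = chain_tree("acbd", [0.1, 0.2, 0.3])
        cons = consensus_tree_at_site([t1, t2])
        assert frozenset({"a", "b"}) not in cons.supports
        assert frozenset({"a", "c"}) not in cons.supports

    def test_tip_set_mismatch(self):
        with pytest.raises(ValueError, match="tip sets"):
            consensus_tree_at_site([
                chain_tree("abc", [0.1, 0.2]),
                chain_tree("abd", [0.1, 0.2]),
            ])

    def test_newick_includes_support(self):
        t = chain_tree("abc", [0.1, 0.2])
        nwk = consensus_tree_at_site([t, t]).newick_with_support()
        assert "support=1.000" in nwk


class TestESS:
    def test_iid_near_n(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert 0.9 * 10_000 <= effective_sample_size(x) <= 1.1 * 10_000

    def test_ar1_closed_form(self):
        phi, n = 0.9, 100_000
        rng = np.random.default_rng(1)
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert abs(effective_sample_size(x) - expected) < 0.2 * expected

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            effective_sample_size([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            effective_sample_size([2.0] * 100)

    def test_agrees_with_arviz_on_mcmc_like_trace(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz

        phi, n = 0.7, 20_000
        rng = np.random.default_rng(5)
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        ours = effective_sample_size(x)
        theirs = float(arviz.ess(x))
        assert abs(ours - theirs) / theirs < 0.25
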