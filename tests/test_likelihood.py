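"""Alignment aliasing and the ARG Felsenstein likelihood engine."""

import itertools
import math

import numpy as np
import pytest

from argsample.arg import Arg, COALESCENT, annotate_ancestral_material
from argsample.likelihood import (
    Alignment,
    ArgLikelihood,
    alias_columns,
    arg_log_likelihood,
)
from argsample.proposals import ARG_KERNELS
from argsample.simulate import SimulationSpec, simulate_arg, simulate_sequences
from argsample.substitution import F84, BaseFrequencies
from argsample.validation import tree_log_likelihood
from argsample.arg import extract_marginal_tree


class TestAlignment:
    def test_identical_columns_share_pattern(self):
        aln = Alignment.from_strings(["x", "y"], ["AAAA", "CCCC"])
        assert aln.n_patterns == 1
        assert aln.pattern_counts.tolist() == [4]

    def test_distinct_columns(self):
        aln = Alignment.from_strings(["x", "y"], ["ACGT", "TGCA"])
        assert aln.n_patterns == 4
        assert aln.pattern_counts.sum() == aln.L

    def test_ragged_rejected_with_names(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment.from_strings(["x", "y"], ["ACGT", "ACG"])

    def test_illegal_character_located(self):
        with pytest.raises(ValueError, match="column 3"):
            Alignment.from_strings(["x"], ["AC!T"])

    def test_ambiguity_codes_accepted(self):
        aln = Alignment.from_strings(["x"], ["ACGTNRY-"])
        tips = aln.pattern_tip_partials()
        # N and '-' give all-ones; R = A|G
        n_col = int(aln.alias[4])
        np.testing.assert_array_equal(tips[0, n_col], [1, 1, 1, 1])
        r_col = int(aln.alias[5])
        np.testing.assert_array_equal(tips[0, r_col], [1, 0, 1, 0])

    def test_alias_is_pure_relabeling(self, f84_model):
        arg = simulate_arg(SimulationSpec(n=6, L=50, theta=0.3, rho=1.0), 5)
        aln = simulate_sequences(arg, f84_model, 6)
        ll = arg_log_likelihood(arg, aln, f84_model)
        ll_plain = arg_log_likelihood(arg, aln.without_aliasing(), f84_model)
        assert ll == pytest.approx(ll_plain, abs=1e-9)
        realiased = alias_columns(aln)
        assert arg_log_likelihood(arg, realiased, f84_model) == pytest.approx(ll, abs=1e-12)


class TestArgLogLikelihood:
    def test_zero_branch_limit_is_log_pi(self, f84_model):
        arg = Arg(1)
        a, b = arg.add_tip("a"), arg.add_tip("b")
        root = arg.new_node(1e-9, COALESCENT)
        Arg.connect(a, 0, root)
        Arg.connect(b, 0, root)
        annotate_ancestral_material(arg)
        aln = Alignment.from_strings(["a", "b"], ["A", "A"])
        ll = arg_log_likelihood(arg, aln, f84_model)
        assert ll == pytest.approx(math.log(f84_model.freqs.pi[0]), abs=1e-6)

    def test_three_tip_exhaustive_state_sum(self, f84_model):
        """Brute-force sum over internal-state assignments on a 1-site,
        3-tip tree equals pruning."""
        arg = Arg(1)
        tips = [arg.add_tip(s) for s in "abc"]
        inner = arg.new_node(0.2, COALESCENT)
        root = arg.new_node(0.5, COALESCENT)
        Arg.connect(tips[0], 0, inner)
        Arg.connect(tips[1], 0, inner)
        Arg.connect(inner, 0, root)
        Arg.connect(tips[2], 0, root)
        annotate_ancestral_material(arg)
        aln = Alignment.from_strings(["a", "b", "c"], ["A", "C", "G"])
        pi = f84_model.freqs.as_array()
        p_inner = f84_model.transition_matrix(0.2)
        p_tip_root = f84_model.transition_matrix(0.5)
        p_inner_root = f84_model.transition_matrix(0.3)
        brute = 0.0
        for u, v in itertools.product(range(4), repeat=2):
            brute += (pi[v] * p_inner_root[v, u] * p_tip_root[v, 2]
                      * p_inner[u, 0] * p_inner[u, 1])
        assert arg_log_likelihood(arg, aln, f84_model) == pytest.approx(
            math.log(brute), abs=1e-12)

    def test_label_mismatch_rejected(self, f84_model, two_tip_tree):
        aln = Alignment.from_strings(["a", "zzz"], ["ACGTACGTAC"] * 2)
        with pytest.raises(ValueError, match="labels"):
            ArgLikelihood(two_tip_tree, aln, f84_model)

    def test_length_mismatch_rejected(self, f84_model, two_tip_tree):
        aln = Alignment.from_strings(["a", "b"], ["ACG", "ACG"])
        with pytest.raises(ValueError, match="L="):
            ArgLikelihood(two_tip_tree, aln, f84_model)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_marginal_tree_sum(self, f84_model, seed):
        arg = simulate_arg(SimulationSpec(n=5, L=200, theta=0.3, rho=1.5), seed)
        aln = simulate_sequences(arg, f84_model, seed + 50)
        full = arg_log_likelihood(arg, aln, f84_model)
        from argsample.arg import marginal_trees

        marginal_sum = sum(
            tree_log_likelihood(tree, aln, f84_model, range(iv.start, iv.end))
            for iv, tree in marginal_trees(arg)
        )
        assert full == pytest.approx(marginal_sum, abs=1e-6)

    def test_probability_conservation_over_columns(self, f84_model):
        """Summing the single-column likelihood over all 4^n tip
        assignments gives exactly 1 for a fixed marginal tree."""
        arg = simulate_arg(SimulationSpec(n=4, L=1, theta=0.4, rho=0.0), 9)
        names = [arg.tip_labels[t.id] for t in arg.tips()]
        total = 0.0
        for combo in itertools.product("ACGT", repeat=4):
            aln = Alignment.from_strings(names, list(combo))
            total += math.exp(arg_log_likelihood(arg, aln, f84_model))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestIncrementalRecomputation:
    def test_clean_recompute_is_cached(self, f84_model):
        arg = simulate_arg(SimulationSpec(n=5, L=60, theta=0.3, rho=1.0), 2)
        aln = simulate_sequences(arg, f84_model, 3)
        lik = ArgLikelihood(arg, aln, f84_model)
        v1 = lik.recompute()
        before = lik.stats["node_recomputes"]
        assert lik.recompute() == v1
        assert lik.stats["node_recomputes"] == before  # zero work when clean

    def test_mark_tip_parent_dirties_rootward_path(self, f84_model, two_tip_tree):
        aln = Alignment.from_strings(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        lik = ArgLikelihood(two_tip_tree, aln, f84_model)
        lik.recompute()
        tip = two_tip_tree.tips()[0]
        lik.mark_dirty([tip.id], [(0, 10)])
        assert set(lik._dirty) == {tip.id, two_tip_tree.root.id}

    def test_unknown_node_rejected(self, f84_model, two_tip_tree):
        aln = Alignment.from_strings(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        lik = ArgLikelihood(two_tip_tree, aln, f84_model)
        with pytest.raises(KeyError):
            lik.mark_dirty([999])

    @pytest.mark.parametrize("seed", [11, 12])
    def test_fuzzed_proposals_incremental_equals_full(self, f84_model, seed):
        """Random kernel perturbations: incremental update equals a
        from-scratch recomputation, and rejection restores the caches
        bit-exactly."""
        rng = np.random.default_rng(seed)
        arg = simulate_arg(SimulationSpec(n=5, L=80, theta=0.3, rho=1.5),
                           seed)
        aln = simulate_sequences(arg, f84_model, seed + 1)
        lik = ArgLikelihood(arg, aln, f84_model)
        base = lik.recompute()
        kernels = list(ARG_KERNELS.items())
        applied = 0
        while applied < 40:
            name, (fn, needs_theta) = kernels[rng.integers(len(kernels))]
            prop = fn(arg, rng, 0.3) if needs_theta else (
                fn(arg, rng) if name == "subtree_regraft" else fn(arg, rng, 0.3))
            if prop.auto_reject:
                continue
            annotate_ancestral_material(arg)
            inc, stash = lik.update(prop.dirty)
            full = arg_log_likelihood(arg, aln, f84_model)
            assert inc == pytest.approx(full, abs=1e-9)
            prop.revert()
            annotate_ancestral_material(arg)
            lik.restore(stash)
            assert lik.recompute() == base
            applied += 1
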