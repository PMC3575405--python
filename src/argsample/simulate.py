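"""Backward-time simulation of neutral ARGs and sequences.

:func:`simulate_arg` draws ARGs from exactly the density evaluated by
:func:`argsample.prior.arg_log_prior` (shared rate convention), tracking
ancestral material per lineage and stopping at the grand MRCA.
:func:`simulate_sequences` then drops nucleotides down the ARG: root
states are drawn from the stationary frequencies and mutated along each
edge via P(t), so linked sites are correlated exactly as the ARG
dictates (adjacent marginal trees share the mutation history of their
shared branches).  A seq-gen-style mode simulating each marginal tree
independently is available via ``per_interval_independent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .arg import (
    Arg,
    COALESCENT,
    RECOMBINATION,
    SiteInterval,
    annotate_ancestral_material,
    intersect_intervals,
    interval_span_gaps,
    marginal_trees,
    tmrca_profile_of_arg,  # re-exported: the step-function TMRCA profile
    union_intervals,
)
from .prior import PopulationModel, RecombinationModel
from .substitution import SubstitutionModel

__all__ = [
    "SimulationSpec",
    "simulate_arg",
    "simulate_sequences",
    "tmrca_profile_of_arg",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset.

    Defaults are the simulated-data conditions used throughout the
    package's validation work: 10 sequences of 10,000 sites with
    theta = 0.02 and rho = 1.0 under a constant-size population.
    ``emit_non_ancestral`` additionally generates recombinations whose
    breakpoints may fall outside a lineage's ancestral material (they
    are invisible to inference and excluded by default)."""

    n: int = 10
    L: int = 10_000
    theta: float = 0.02
    rho: float = 1.0
    growth: float = 0.0
    emit_non_ancestral: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.L < 1:
            raise ValueError("need L >= 1 sites")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")

    def population_model(self) -> PopulationModel:
        kind = "constant" if self.growth == 0.0 else "exponential_growth"
        return PopulationModel(self.theta, self.growth, kind)

    def recombination_model(self) -> RecombinationModel:
        return RecombinationModel(self.rho)


def _draw_waiting_time(rng, k: int, rec_rate: float, pop: PopulationModel,
                       t0: float) -> float:
    """Waiting time to the next event from time t0 with k lineages and
    total (time-constant) recombination rate rec_rate."""
    coal = k * (k - 1)
    if pop.growth == 0.0:
        total = coal / pop.theta0 + rec_rate
        return rng.exponential(1.0 / total)
    target = rng.exponential(1.0)

    def cumulative(dt: float) -> float:
        return rec_rate * dt + coal * pop.inverse_theta_integral(t0, t0 + dt)

    hi = 1.0
    while cumulative(hi) < target:
        hi *= 2.0
    return brentq(cumulative_minus(cumulative, target), 0.0, hi, xtol=1e-14)


def cumulative_minus(fn, target):
    return lambda dt: fn(dt) - target


def simulate_arg(spec: SimulationSpec, rng: np.random.Generator | int) -> Arg:
    """Simulate one ARG backward in time until the grand MRCA.

    Lineages carry their ancestral material; coalescences merge it and
    recombinations split it at a breakpoint drawn uniformly over the
    lineage's eligible gaps (or over all L-1 gaps when
    ``emit_non_ancestral`` is set).  The returned ARG is annotated."""
    rng = np.random.default_rng(rng)
    pop = spec.population_model()
    arg = Arg(spec.L)
    # lineage = [node, slot, material, eligible_gap_count]
    lineages: list[list] = []
    for i in range(spec.n):
        tip = arg.add_tip(f"t{i}")
        lineages.append([tip, 0, (SiteInterval(0, spec.L),), spec.L - 1])
    full_gaps = spec.L - 1
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        if spec.rho > 0 and full_gaps > 0:
            if spec.emit_non_ancestral:
                rates = [spec.rho / pop.theta0] * k
            else:
                rates = [
                    spec.rho / pop.theta0 * lin[3] / full_gaps for lin in lineages
                ]
        else:
            rates = [0.0] * k
        rec_total = sum(rates)
        t += _draw_waiting_time(rng, k, rec_total, pop, t)
        coal_rate = k * (k - 1) / pop.theta_at(t)
        if rng.uniform() < coal_rate / (coal_rate + rec_total):
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            li, lj = lineages[j], lineages[i]  # pop higher index first
            lineages.pop(j)
            lineages.pop(i)
            node = arg.new_node(t, COALESCENT)
            Arg.connect(li[0], li[1], node)
            Arg.connect(lj[0], lj[1], node)
            mat = union_intervals(li[2], lj[2])
            lineages.append([node, 0, mat, interval_span_gaps(mat)])
        else:
            probs = np.asarray(rates) / rec_total
            i = int(rng.choice(k, p=probs))
            lin = lineages.pop(i)
            mat = lin[2]
            if spec.emit_non_ancestral:
                b = int(rng.integers(1, spec.L))
            else:
                first, last = mat[0].start, mat[-1].end - 1
                b = int(rng.integers(first + 1, last + 1))
            node = arg.new_node(t, RECOMBINATION, breakpoint=b)
            Arg.connect(lin[0], lin[1], node)
            left = intersect_intervals(mat, 0, b)
            right = intersect_intervals(mat, b, spec.L)
            lineages.append([node, 0, left, interval_span_gaps(left)])
            lineages.append([node, 1, right, interval_span_gaps(right)])
    return annotate_ancestral_material(arg)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _mutate_along_edge(states: np.ndarray, p: np.ndarray, rng) -> np.ndarray:
    """Sample child states given parent states and a 4x4 transition
    matrix, vectorized over sites."""
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.uniform(size=states.shape[0])
    return (u[:, None] > cum[states]).sum(axis=1).astype(np.int8)


def simulate_sequences(
    arg: Arg,
    model: SubstitutionModel,
    rng: np.random.Generator | int,
    per_interval_independent: bool = False,
):
    """Simulate an alignment on an ARG.

    Default mode drops states down the ARG itself (tree-consistent:
    sites on shared branches share the realized mutation history).
    ``per_interval_independent`` instead simulates each marginal tree
    with fresh randomness (the classical one-tree-at-a-time pipeline),
    which preserves every marginal distribution but not cross-interval
    correlation.  Returns an :class:`argsample.likelihood.Alignment`.
    """
    from .likelihood import Alignment

    rng = np.random.default_rng(rng)
    pi = model.freqs.as_array()
    L = arg.L
    tips = arg.tips()
    names = [arg.tip_labels.get(t.id, str(t.id)) for t in tips]
    if per_interval_independent:
        matrix = np.empty((len(tips), L), dtype=np.int8)
        for iv, tree in marginal_trees(arg):
            width = iv.end - iv.start
            block = _simulate_tree_block(tree, model, width, rng)
            for r, name in enumerate(names):
                matrix[r, iv.start:iv.end] = block[name]
        return Alignment.from_codes(names, matrix)

    # states propagate down: every node's state vector over all L sites,
    # routed through recombination breakpoints (height-descending order)
    order = arg.nodes_ascending()[::-1]
    states: dict[int, np.ndarray] = {}
    root = order[0]
    states[root.id] = rng.choice(4, size=L, p=pi).astype(np.int8)
    for node in order:
        if node is root:
            continue
        if node.kind == RECOMBINATION:
            b = node.breakpoint
            parts = []
            for slot, (lo, hi) in ((0, (0, b)), (1, (b, L))):
                parent = node.parents[slot]
                t = parent.height - node.height
                p = model.transition_matrix(t)
                seg = _mutate_along_edge(states[parent.id][lo:hi], p, rng)
                parts.append(seg)
            states[node.id] = np.concatenate(parts)
        else:
            parent = node.parents[0]
            t = parent.height - node.height
            p = model.transition_matrix(t)
            states[node.id] = _mutate_along_edge(states[parent.id], p, rng)
    matrix = np.vstack([states[t.id] for t in tips])
    return Alignment.from_codes(names, matrix)


def _simulate_tree_block(tree, model, width: int, rng) -> dict[str, np.ndarray]:
    """Simulate ``width`` iid sites down one marginal tree; returns
    {leaf label: states}."""
    pi = model.freqs.as_array()
    out: dict[str, np.ndarray] = {}

    def down(node, parent_states):
        for child in node.children:
            p = model.transition_matrix(node.height - child.height)
            child_states = _mutate_along_edge(parent_states, p, rng)
            if child.children:
                down(child, child_states)
            else:
                out[child.label] = child_states

    root_states = rng.choice(4, size=width, p=pi).astype(np.int8)
    if not tree.root.children:
        out[tree.root.label] = root_states
    else:
        down(tree.root, root_states)
    return out
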