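"""Posterior collectors over sampled ARGs and scalar traces.

All collectors are order-insensitive and exactly mergeable: merging two
accumulators equals accumulating the concatenated sample stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .arg import Arg, MarginalTree, TreeNode, tmrca_profile_of_arg

__all__ = [
    "BreakpointDensity2D",
    "TmrcaProfileAccumulator",
    "ConsensusTree",
    "consensus_tree_at_site",
    "effective_sample_size",
]


class BreakpointDensity2D:
    """2-D histogram of sampled recombination breakpoints: position
    along the sequence on one axis, node height (time) on the other.

    Heights above ``max_height`` clamp into the top bin so the total
    count always equals the number of breakpoints seen."""

    def __init__(self, L: int, max_height: float,
                 n_site_bins: int = 100, n_time_bins: int = 50):
        self.site_edges = np.linspace(0, L, n_site_bins + 1)
        self.time_edges = np.linspace(0.0, max_height, n_time_bins + 1)
        self.counts = np.zeros((n_site_bins, n_time_bins), dtype=np.int64)
        self.n_args = 0

    def add(self, arg: Arg) -> "BreakpointDensity2D":
        self.n_args += 1
        for node in arg.recombination_nodes():
            i = min(
                np.searchsorted(self.site_edges, node.breakpoint, side="right") - 1,
                len(self.site_edges) - 2,
            )
            j = min(
                max(np.searchsorted(self.time_edges, node.height, side="right") - 1, 0),
                len(self.time_edges) - 2,
            )
            self.counts[i, j] += 1
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def site_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def merge(self, other: "BreakpointDensity2D") -> "BreakpointDensity2D":
        if not (np.array_equal(self.site_edges, other.site_edges)
                and np.array_equal(self.time_edges, other.time_edges)):
            raise ValueError("bin edges differ; cannot merge")
        self.counts += other.counts
        self.n_args += other.n_args
        return self

    def to_tsv(self) -> str:
        lines = ["site_bin_start\tsite_bin_end\ttime_bin_start\ttime_bin_end\tcount"]
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                if self.counts[i, j]:
                    lines.append(
                        f"{self.site_edges[i]:g}\t{self.site_edges[i + 1]:g}\t"
                        f"{self.time_edges[j]:g}\t{self.time_edges[j + 1]:g}\t"
                        f"{self.counts[i, j]}"
                    )
        return "\n".join(lines) + "\n"


class TmrcaProfileAccumulator:
    """Per-site posterior TMRCA profile (mean and quantile band).

    Stores per-grid-site samples exactly up to ``max_store`` sampled
    ARGs, then switches to reservoir subsampling so quantiles stay
    unbiased with bounded memory."""

    def __init__(self, L: int, n_grid: int = 200, max_store: int = 100_000,
                 seed: int = 0):
        self.L = L
        step = max(1, L // n_grid)
        self.sites = np.arange(0, L, step)
        self.samples: list[np.ndarray] = []
        self.max_store = max_store
        self.n_seen = 0
        self._rng = np.random.default_rng(seed)

    def add(self, arg: Arg) -> "TmrcaProfileAccumulator":
        prof = tmrca_profile_of_arg(arg)
        vals = np.empty(len(self.sites))
        idx = 0
        for i, s in enumerate(self.sites):
            while prof[idx][0].end <= s:
                idx += 1
            vals[i] = prof[idx][1]
        self.n_seen += 1
        if len(self.samples) < self.max_store:
            self.samples.append(vals)
        else:
            j = int(self._rng.integers(self.n_seen))
            if j < self.max_store:
                self.samples[j] = vals
        return self

    def summary(self, lower: float = 0.025, upper: float = 0.975):
        """(sites, mean, lo, hi) arrays; lower <= mean <= upper per site."""
        if not self.samples:
            raise ValueError("no ARGs accumulated")
        m = np.vstack(self.samples)
        return (
            self.sites,
            m.mean(axis=0),
            np.quantile(m, lower, axis=0),
            np.quantile(m, upper, axis=0),
        )

    def merge(self, other: "TmrcaProfileAccumulator") -> "TmrcaProfileAccumulator":
        if not np.array_equal(self.sites, other.sites):
            raise ValueError("site grids differ; cannot merge")
        self.samples.extend(other.samples)
        self.n_seen += other.n_seen
        return self

    def to_tsv(self, lower: float = 0.025, upper: float = 0.975) -> str:
        sites, mean, lo, hi = self.summary(lower, upper)
        lines = ["site\tmean_tmrca\tq_lower\tq_upper"]
        for s, m, a, b in zip(sites, mean, lo, hi):
            lines.append(f"{s + 1}\t{m:.8g}\t{a:.8g}\t{b:.8g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# consensus trees
# ---------------------------------------------------------------------------

@dataclass
class ConsensusTree:
    """Majority-rule consensus with per-clade support and mean heights."""

    tree: MarginalTree
    supports: dict
    n_trees: int

    def newick_with_support(self, precision: int = 6) -> str:
        def fmt(node: TreeNode, parent_height):
            if node.children:
                kids = sorted(node.children, key=lambda c: c.canonical())
                inner = ",".join(fmt(c, node.height) for c in kids)
                clade = frozenset(_leafset(node))
                sup = self.supports.get(clade, 1.0)
                core = f"({inner})[&support={sup:.3f}]"
            else:
                core = node.label
            if parent_height is None:
                return core
            return f"{core}:{parent_height - node.height:.{precision}g}"

        return fmt(self.tree.root, None) + ";"


def _leafset(node: TreeNode) -> set:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.children:
            out.add(n.label)
        stack.extend(n.children)
    return out


def _clades_with_heights(tree: MarginalTree):
    """{clade leafset -> node height} for internal nodes (incl. root)."""
    out = {}

    def walk(node: TreeNode) -> set:
        if not node.children:
            return {node.label}
        leaves = set()
        for c in node.children:
            leaves |= walk(c)
        out[frozenset(leaves)] = node.height
        return leaves

    walk(tree.root)
    return out


def consensus_tree_at_site(trees: Sequence[MarginalTree]) -> ConsensusTree:
    """Strict-majority-rule consensus: a clade is retained iff present
    in more than half the trees (exactly half is dropped); clade support
    is its frequency and node heights are means over supporting trees."""
    if not trees:
        raise ValueError("need at least one tree")
    tipsets = {frozenset(t.leaf_labels()) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("trees have differing tip sets")
    (tips,) = tipsets
    n = len(trees)
    counts: dict = {}
    heights: dict = {}
    for t in trees:
        for clade, h in _clades_with_heights(t).items():
            counts[clade] = counts.get(clade, 0) + 1
            heights[clade] = heights.get(clade, 0.0) + h
    kept = {c for c, k in counts.items() if k * 2 > n}
    kept.add(frozenset(tips))
    mean_h = {c: heights[c] / counts[c] for c in kept}
    supports = {c: counts[c] / n for c in kept}

    # kept clades are pairwise compatible (majority rule); build top-down
    def build(clade) -> TreeNode:
        inner = [c for c in kept if c < clade]
        maximal = [c for c in inner if not any(c < d for d in inner)]
        covered = set().union(*maximal) if maximal else set()
        children = [build(c) for c in sorted(maximal, key=sorted)]
        children += [TreeNode(0.0, label=l) for l in sorted(clade - covered)]
        return TreeNode(mean_h[clade], children=children)

    root = build(frozenset(tips))
    return ConsensusTree(MarginalTree(root), supports, n)


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------

def effective_sample_size(trace: Sequence[float]) -> float:
    """ESS = N / (1 + 2 sum_k gamma_k) with Geyer's initial monotone
    positive sequence truncation of the autocorrelations."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short for ESS (need >= 10 points)")
    if np.ptp(x) == 0:
        raise ValueError("constant trace: ESS undefined")
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sums of adjacent autocorrelation pairs must stay positive
    # and non-increasing
    pair_sums = []
    k = 1
    while k + 1 < n:
        s = rho[k] + rho[k + 1]
        if s <= 0:
            break
        pair_sums.append(s)
        k += 2
    for i in range(1, len(pair_sums)):
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = 1.0 + 2.0 * sum(pair_sums)
    return float(n / max(tau, 1e-12))
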