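"""Full Felsenstein likelihood of an alignment given an ARG.

The pruning recursion runs on the ARG itself.  For a given site, a
node's partial vector includes exactly the tips whose root-ward path
for that site passes the node: at a recombination node the single child
vector is propagated through P(t); at a coalescent node the vectors of
the child edges that *arrive* for that site (routing decided by the
breakpoints below) are propagated and multiplied.  Because the models
are stationary and Chapman-Kolmogorov holds, evaluating pi . partial at
the grand root equals the sum over marginal trees of the standard tree
likelihoods restricted to their intervals.

Identical alignment columns are computed once (global column aliasing);
per-node subtree-pattern deduplication is deliberately not layered on
top — the per-(node, site-range) storage already confines work to the
affected ranges.  Per-node per-range scaling factors keep partials away
from underflow.  Partial results live in a per-node table with dirty
flags so that an MCMC proposal only triggers recomputation of the
touched nodes and their root-ward closure; state moves by reference
swap, so a rejected proposal restores the previous table entries
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .arg import Arg, ArgNode, RECOMBINATION, TIP
from .substitution import BaseFrequencies, SubstitutionModel

__all__ = ["Alignment", "alias_columns", "ArgLikelihood", "arg_log_likelihood"]


# IUPAC nucleotide codes as 4-bit base masks (A=1, C=2, G=4, T=8)
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "-": 15, "?": 15,
}
_MASK_TO_CHAR = {1: "A", 2: "C", 4: "G", 8: "T", 15: "N"}
_CODE_TO_MASK = np.array([1, 2, 4, 8], dtype=np.uint8)


class Alignment:
    """Sequences x sites with a column-aliasing map.

    ``matrix`` stores IUPAC base masks (uint8); ``alias`` maps each
    column to its unique-pattern index and ``pattern_counts`` holds the
    multiplicities (sum = L).  Aliasing is a pure relabeling: the
    likelihood is identical with or without it.
    """

    def __init__(self, names: list[str], matrix: np.ndarray,
                 alias: Optional[np.ndarray] = None,
                 invariant_pad: Optional[dict[str, int]] = None):
        if matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(names) != matrix.shape[0]:
            raise ValueError("one name per row required")
        self.names = list(names)
        self.matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
        self.invariant_pad = invariant_pad  # optional VCF variant-only bookkeeping
        if alias is None:
            self._build_alias()
        else:
            self.alias = alias
            self.patterns = self.matrix
            self.pattern_counts = np.ones(matrix.shape[1], dtype=np.int64)

    def _build_alias(self) -> None:
        patterns, alias, counts = np.unique(
            self.matrix, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = np.ascontiguousarray(patterns)
        self.alias = alias.astype(np.int64).ravel()
        self.pattern_counts = counts.astype(np.int64)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_strings(cls, names: list[str], seqs: list[str]) -> "Alignment":
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            detail = ", ".join(f"{n}:{len(s)}" for n, s in zip(names, seqs))
            raise ValueError(f"ragged sequence lengths ({detail})")
        mat = np.empty((len(seqs), len(seqs[0])), dtype=np.uint8)
        for r, s in enumerate(seqs):
            for c, ch in enumerate(s.upper()):
                mask = IUPAC_MASKS.get(ch)
                if mask is None:
                    raise ValueError(
                        f"illegal character {ch!r} in sequence {names[r]!r} column {c + 1}"
                    )
                mat[r, c] = mask
        return cls(names, mat)

    @classmethod
    def from_codes(cls, names: list[str], codes: np.ndarray) -> "Alignment":
        """From 0..3 = ACGT integer codes (>= 4 treated as missing)."""
        codes = np.asarray(codes)
        mat = np.where(codes < 4, _CODE_TO_MASK[np.clip(codes, 0, 3)], 15).astype(np.uint8)
        return cls(names, mat)

    # -- basic properties ---------------------------------------------
    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def sequence_str(self, row: int) -> str:
        return "".join(_MASK_TO_CHAR.get(int(m), "N") for m in self.matrix[row])

    def empirical_frequencies(self) -> BaseFrequencies:
        counts = np.array(
            [(self.matrix == m).sum() for m in (1, 2, 4, 8)], dtype=float
        )
        counts += 0.5
        return BaseFrequencies(tuple(counts / counts.sum()))

    def without_aliasing(self) -> "Alignment":
        """Identity alias (every column its own pattern) — used to show
        aliasing never changes the likelihood."""
        return Alignment(
            self.names, self.matrix, alias=np.arange(self.L, dtype=np.int64)
        )

    def pattern_tip_partials(self) -> np.ndarray:
        """(n_seqs, n_patterns, 4) indicator partials; ambiguity codes
        (incl. N and gaps) become the union of compatible bases."""
        masks = self.patterns  # (n, n_pat)
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        return ((masks[:, :, None] & bits[None, None, :]) > 0).astype(float)


def alias_columns(alignment: Alignment) -> Alignment:
    """(Re)compute the column-aliasing map; identical columns share one
    pattern index."""
    return Alignment(alignment.names, alignment.matrix,
                     invariant_pad=alignment.invariant_pad)


# ---------------------------------------------------------------------------
# ARG likelihood with partial-result tables
# ---------------------------------------------------------------------------

@dataclass
class _NodeTable:
    """Partial likelihoods for one node, stored per routing-constant
    site range: ``breaks`` are the site-dependence points of the partial
    below the node; ``partials[i]``/``logscales[i]`` cover
    [bounds[i], bounds[i+1])."""

    breaks: tuple[int, ...]
    bounds: tuple[int, ...]
    partials: list[np.ndarray]            # each (n_patterns, 4)
    logscales: list                       # (n_patterns,) arrays or None (= all zero)
    tips_below: int = 0

    def lookup(self, lo: int, hi: int):
        """Entry whose range contains [lo, hi)."""
        for i in range(len(self.bounds) - 1):
            if self.bounds[i] <= lo and hi <= self.bounds[i + 1]:
                return self.partials[i], self.logscales[i]
        raise KeyError(f"range [{lo},{hi}) not covered by node table")


class ArgLikelihood:
    """Stateful ARG likelihood with incremental recomputation.

    ``mark_dirty`` + ``recompute`` implement the partial-update
    contract; ``update``/``restore`` wrap them with reference-swapped
    stashes for MCMC accept/reject."""

    def __init__(self, arg: Arg, alignment: Alignment, model: SubstitutionModel):
        if arg.L != alignment.L:
            raise ValueError(
                f"ARG has L={arg.L} but alignment has L={alignment.L}"
            )
        labels = sorted(arg.tip_labels.values())
        if labels != sorted(alignment.names):
            raise ValueError(
                "tip labels do not match alignment names: "
                f"{labels} vs {sorted(alignment.names)}"
            )
        self.arg = arg
        self.alignment = alignment
        self.model = model
        row = {name: i for i, name in enumerate(alignment.names)}
        self._tip_row = {
            nid: row[label] for nid, label in arg.tip_labels.items()
        }
        self._tip_partials = alignment.pattern_tip_partials()
        self._pi = model.freqs.as_array()
        self.tables: dict[int, _NodeTable] = {}
        self._dirty: dict[int, list[tuple[int, int]]] = {}
        self.stats = {"node_recomputes": 0}
        self._counts_cache: dict[tuple[int, int], np.ndarray] = {}
        self._cached_loglik: Optional[float] = None
        self.mark_dirty([n.id for n in arg.nodes.values()])
        self.recompute()

    # -- dirty bookkeeping --------------------------------------------
    def mark_dirty(self, node_ids: Iterable[int],
                   intervals: Optional[list[tuple[int, int]]] = None) -> None:
        """Flag nodes (over the given site intervals, default all
        sites) and their root-ward closure along routed intervals."""
        L = self.arg.L
        if intervals is None:
            intervals = [(0, L)]
        for nid in node_ids:
            if nid not in self.arg.nodes:
                raise KeyError(f"unknown node id {nid}")
        self._cached_loglik = None
        work = [
            (self.arg.nodes[i], [iv for iv in intervals if iv[1] > iv[0]])
            for i in node_ids
        ]
        while work:
            node, ivs = work.pop()
            cur = self._dirty.get(node.id)
            first = cur is None
            if first:
                cur = self._dirty[node.id] = []
            new = [
                iv for iv in ivs
                if not any(c[0] <= iv[0] and iv[1] <= c[1] for c in cur)
            ]
            if not new and not first:
                continue
            cur.extend(new)
            if not new:
                continue
            if node.kind == RECOMBINATION:
                b = node.breakpoint
                left = [(lo, min(hi, b)) for lo, hi in new if lo < b]
                right = [(max(lo, b), hi) for lo, hi in new if hi > b]
                if node.parents and node.parents[0] is not None and left:
                    work.append((node.parents[0], left))
                if len(node.parents) > 1 and node.parents[1] is not None and right:
                    work.append((node.parents[1], right))
            elif node.parents and node.parents[0] is not None:
                work.append((node.parents[0], new))

    @property
    def n_dirty(self) -> int:
        return len(self._dirty)

    # -- recomputation ------------------------------------------------
    def _node_breaks(self, node: ArgNode) -> tuple[int, ...]:
        """Site-dependence points of the partial below ``node``."""
        if node.kind == TIP:
            return ()
        pts: set[int] = set()
        for c, _j in self.arg.incoming_edges(node):
            pts.update(self.tables[c.id].breaks)
            if c.kind == RECOMBINATION:
                pts.add(c.breakpoint)
        return tuple(sorted(pts))

    # rescale partials once this many tips accumulate below a node;
    # products of >= ~1e-4-scale entries stay far from underflow below it
    RESCALE_TIPS = 32

    def _compute_node(self, node: ArgNode) -> _NodeTable:
        n_pat = self.alignment.n_patterns
        if node.kind == TIP:
            part = self._tip_partials[self._tip_row[node.id]]
            return _NodeTable((), (0, self.arg.L), [part], [None], tips_below=1)
        breaks = self._node_breaks(node)
        bounds = (0,) + breaks + (self.arg.L,)
        partials, logscales = [], []
        edges = self.arg.incoming_edges(node)
        pmats = {}
        tips_below = 0
        for c, j in edges:
            pmats[(c.id, j)] = self.model.transition_matrix(
                node.height - c.height).T
            tips_below += self.tables[c.id].tips_below
        rescale = tips_below >= self.RESCALE_TIPS
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            acc = None
            ls = None
            for c, j in edges:
                if c.kind == RECOMBINATION:
                    arrives = (hi <= c.breakpoint) if j == 0 else (lo >= c.breakpoint)
                    if not arrives:
                        continue
                cpart, cls = self.tables[c.id].lookup(lo, hi)
                prop = cpart @ pmats[(c.id, j)]
                acc = prop if acc is None else acc * prop
                if cls is not None:
                    ls = cls if ls is None else ls + cls
            if acc is None:
                acc = np.ones((n_pat, 4))
            elif rescale:
                mx = acc.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                acc = acc / safe[:, None]
                with np.errstate(divide="ignore"):
                    extra = np.log(safe) + np.where(mx > 0, 0.0, -np.inf)
                ls = extra if ls is None else ls + extra
            partials.append(acc)
            logscales.append(ls)
        return _NodeTable(breaks, bounds, partials, logscales, tips_below)

    def recompute(self) -> float:
        """Recompute flagged nodes bottom-up, clear all dirty flags and
        return the log-likelihood (cached value if nothing is dirty)."""
        if not self._dirty:
            if self._cached_loglik is None:
                self._cached_loglik = self._root_loglik()
            return self._cached_loglik
        for node in self.arg.nodes_ascending():
            if node.id in self._dirty:
                self.tables[node.id] = self._compute_node(node)
                self.stats["node_recomputes"] += 1
        # drop tables for nodes no longer present
        for nid in list(self._dirty):
            if nid not in self.arg.nodes and nid in self.tables:
                del self.tables[nid]
        self._dirty.clear()
        self._cached_loglik = self._root_loglik()
        return self._cached_loglik

    def _interval_pattern_counts(self, lo: int, hi: int) -> np.ndarray:
        counts = self._counts_cache.get((lo, hi))
        if counts is None:
            if len(self._counts_cache) > 20000:
                self._counts_cache.clear()
            counts = np.bincount(self.alignment.alias[lo:hi],
                                 minlength=self.alignment.n_patterns)
            self._counts_cache[(lo, hi)] = counts
        return counts

    def _root_loglik(self) -> float:
        root = self.arg.root
        table = self.tables[root.id]
        total = 0.0
        for i in range(len(table.bounds) - 1):
            lo, hi = table.bounds[i], table.bounds[i + 1]
            counts = self._interval_pattern_counts(lo, hi)
            present = counts > 0
            if not present.any():
                continue
            with np.errstate(divide="ignore"):
                site_log = np.log(table.partials[i][present] @ self._pi)
            if table.logscales[i] is not None:
                site_log = site_log + table.logscales[i][present]
            total += float(counts[present] @ site_log)
        return total

    # -- MCMC accept/reject support ------------------------------------
    def update(self, node_ids: Iterable[int],
               intervals: Optional[list[tuple[int, int]]] = None):
        """Mark + recompute, returning (loglik, stash); pass the stash
        to :meth:`restore` to undo on rejection (reference swap, no
        copies)."""
        prev_loglik = self._cached_loglik
        self.mark_dirty(node_ids, intervals)
        stash = {nid: self.tables.get(nid) for nid in self._dirty}
        stash["__loglik__"] = prev_loglik
        loglik = self.recompute()
        return loglik, stash

    def drop_nodes(self, node_ids: Iterable[int]) -> None:
        """Discard table entries for nodes removed by an *accepted*
        proposal (their caches are otherwise kept for rejection
        restore)."""
        for nid in node_ids:
            self.tables.pop(nid, None)

    def restore(self, stash: dict) -> None:
        for nid, entry in stash.items():
            if nid == "__loglik__":
                continue
            if entry is None:
                self.tables.pop(nid, None)
            else:
                self.tables[nid] = entry
        self._dirty.clear()
        self._cached_loglik = stash["__loglik__"]


def arg_log_likelihood(arg: Arg, alignment: Alignment,
                       model: SubstitutionModel) -> float:
    """Natural-log full likelihood of ``alignment`` given ``arg`` —
    equal to the sum over marginal-tree intervals of the standard tree
    log-likelihoods restricted to those intervals."""
    return ArgLikelihood(arg, alignment, model).recompute()
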