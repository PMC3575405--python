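"""Proposal kernels over ARGs and scalar parameters.

Each kernel mutates the ARG in place and returns a :class:`Proposal`
carrying the log Hastings(-Green) ratio, the dirty node set for partial
likelihood recomputation, and a ``revert`` closure that restores the
pre-proposal state bit-exactly.  Kernels never raise on unlucky draws:
impossible moves (death with no recombinations, exchange with no
contemporaneous edge) come back flagged ``auto_reject``.

The reversible-jump pair works on (recombination node R, coalescent
node C) units: a birth picks an edge, splits it at a new R with a
breakpoint drawn uniformly over the edge's eligible gaps, routes one
side (fair coin) up a fresh lineage that re-coalesces at C — at an
exponentially distributed height on an edge drawn uniformly among those
crossing it, or above the root — while a death removes such a pair and
heals both edges.  The acceptance ratio multiplies the prior ratio by
q_death/q_birth with every factor evaluated on the state the reverse
move would see; the (h_R, h_C) coordinates are proposed directly, so
the dimension-matching Jacobian is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .arg import (
    Arg,
    ArgNode,
    COALESCENT,
    RECOMBINATION,
    TIP,
    interval_span_gaps,
)

__all__ = [
    "Proposal",
    "propose_node_height",
    "propose_root_scale",
    "propose_subtree_regraft",
    "propose_add_recombination",
    "propose_remove_recombination",
    "propose_breakpoint_shift",
    "propose_arg_scale",
    "propose_scalar",
    "ARG_KERNELS",
]

NEG_INF = float("-inf")


@dataclass
class Proposal:
    """State delta + Hastings ratio + dirty set for one proposed move."""

    name: str
    log_hastings: float = 0.0
    dirty: list[int] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)
    revert: Callable[[], None] = lambda: None
    auto_reject: bool = False
    param: Optional[tuple[str, float, float]] = None  # (name, old, new)
    params_dirty: bool = False  # substitution parameters changed

    @classmethod
    def rejected(cls, name: str) -> "Proposal":
        return cls(name=name, log_hastings=NEG_INF, auto_reject=True)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold x into (lo, hi) by reflection at both bounds."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _multiplier(rng, lam: float) -> tuple[float, float]:
    """Scale factor m = exp(lam (u - 1/2)); returns (m, log m)."""
    logm = lam * (rng.uniform() - 0.5)
    return math.exp(logm), logm


# ---------------------------------------------------------------------------
# height moves
# ---------------------------------------------------------------------------

def propose_node_height(arg: Arg, rng, window: float = 0.05) -> Proposal:
    """Reflected uniform window on one non-root internal node's height
    (bounds: highest child, lowest parent).  Symmetric: log HR = 0."""
    candidates = [
        n for n in arg.nodes.values() if n.kind != TIP and n.parents
    ]
    if not candidates:
        return Proposal.rejected("node_height")
    node = candidates[rng.integers(len(candidates))]
    lo = max(c.height for c in node.children)
    hi = min(p.height for p in node.parents)
    old = node.height
    new = _reflect(old + window * (rng.uniform() - 0.5), lo, hi)
    node.height = new

    def revert():
        node.height = old

    return Proposal("node_height", 0.0, dirty=[node.id], revert=revert)


def propose_root_scale(arg: Arg, rng, lam: float = 0.7) -> Proposal:
    """Multiplier move on the grand MRCA's height above its highest
    child: h' = lo + (h - lo) m, m ~ exp(Uniform); log HR = log m."""
    root = arg.root
    lo = max(c.height for c in root.children)
    m, logm = _multiplier(rng, lam)
    old = root.height
    root.height = lo + (old - lo) * m

    def revert():
        root.height = old

    return Proposal("root_scale", logm, dirty=[root.id], revert=revert)


def propose_arg_scale(arg: Arg, rng, lam: float = 0.3) -> Proposal:
    """Scale every internal node height by a common multiplier;
    log HR = (number of scaled heights) * log m."""
    internal = [n for n in arg.nodes.values() if n.kind != TIP]
    m, logm = _multiplier(rng, lam)
    olds = [(n, n.height) for n in internal]
    for n, h in olds:
        n.height = h * m

    def revert():
        for n, h in olds:
            n.height = h

    return Proposal(
        "arg_scale", len(internal) * logm,
        dirty=[n.id for n in internal], revert=revert,
    )


# ---------------------------------------------------------------------------
# topology move
# ---------------------------------------------------------------------------

def _crossing_edges(arg: Arg, h: float):
    """Edges (child, slot, parent) whose span strictly contains h."""
    out = []
    for c, j, p in arg.edges():
        if c.height < h < p.height:
            out.append((c, j, p))
    return out


def propose_subtree_regraft(arg: Arg, rng, window: float = 0.0) -> Proposal:
    """Exchange a child edge of one coalescent node with a
    contemporaneous edge (both cross the node's height): the two
    subtrees swap attachment points.  The crossing-edge count is
    invariant under the swap, so the move is symmetric."""
    coals = [n for n in arg.nodes.values() if n.kind == COALESCENT]
    p = coals[rng.integers(len(coals))]
    edges_in = arg.incoming_edges(p)
    c, jc = edges_in[rng.integers(len(edges_in))]
    crossing = _crossing_edges(arg, p.height)
    if not crossing:
        return Proposal.rejected("subtree_regraft")
    a, ja, b = crossing[rng.integers(len(crossing))]
    Arg.disconnect(c, jc)
    Arg.disconnect(a, ja)
    Arg.connect(a, ja, p)
    Arg.connect(c, jc, b)

    def revert():
        Arg.disconnect(a, ja)
        Arg.disconnect(c, jc)
        Arg.connect(c, jc, p)
        Arg.connect(a, ja, b)

    return Proposal("subtree_regraft", 0.0, dirty=[p.id, b.id], revert=revert)


# ---------------------------------------------------------------------------
# reversible-jump birth / death of a recombination
# ---------------------------------------------------------------------------

def _removable_pairs(arg: Arg):
    """(recombination node, parent slot) pairs whose parent on that slot
    is a coalescent node — the death kernel's choice set."""
    out = []
    for r in arg.recombination_nodes():
        for s in (0, 1):
            if r.parents[s].kind == COALESCENT:
                out.append((r, s))
    return out


def propose_add_recombination(arg: Arg, rng, theta: float,
                              lam_scale: float = 2.0) -> Proposal:
    edges = arg.edges()
    n_edges = len(edges)
    c, slot, p = edges[rng.integers(n_edges)]
    mat = arg.edge_material(c, slot)
    g = interval_span_gaps(mat)
    if g == 0:
        return Proposal.rejected("add_recombination")
    first, last = mat[0].start, mat[-1].end - 1
    b = int(rng.integers(first + 1, last + 1))
    h_lo, h_hi = c.height, p.height
    h_r = h_lo + (h_hi - h_lo) * rng.uniform()
    z = int(rng.integers(2))  # parent slot routed up the new lineage
    lam = lam_scale / theta
    delta = rng.exponential(1.0 / lam)
    h_n = h_r + delta
    old_root = arg.root
    root_h = old_root.height

    log_q_birth = (
        -math.log(n_edges)
        - math.log(h_hi - h_lo)
        - math.log(g)
        - math.log(2.0)
        + math.log(lam) - lam * delta
    )

    target = None
    if h_n < root_h:
        crossing = _crossing_edges(arg, h_n)
        target = crossing[rng.integers(len(crossing))]
        log_q_birth -= math.log(len(crossing))

    # ---- apply ----
    Arg.disconnect(c, slot)
    r_node = arg.new_node(h_r, RECOMBINATION, breakpoint=b)
    Arg.connect(c, slot, r_node)
    c_node = arg.new_node(h_n, COALESCENT)
    if target is None:
        # re-coalesce above the old root: C becomes the new grand MRCA
        Arg.connect(r_node, 1 - z, p)
        Arg.connect(r_node, z, c_node)
        Arg.connect(old_root, 0, c_node)
        undo = ("above", old_root)
    else:
        x, jx, y = target
        if x is c and jx == slot:
            # target was the split edge itself: C lands on the
            # continuation segment (R -> p), creating a bubble
            Arg.connect(r_node, 1 - z, c_node)
            Arg.connect(r_node, z, c_node)
            Arg.connect(c_node, 0, p)
            undo = ("bubble", None)
        else:
            Arg.connect(r_node, 1 - z, p)
            Arg.disconnect(x, jx)
            Arg.connect(x, jx, c_node)
            Arg.connect(c_node, 0, y)
            Arg.connect(r_node, z, c_node)
            undo = ("edge", (x, jx, y))

    # reverse-death choice count in the proposed state
    d_count = len(_removable_pairs(arg))
    log_q_death = -math.log(d_count)

    def revert():
        kind_u, payload = undo
        if kind_u == "above":
            top = payload
            Arg.disconnect(top, 0)
            Arg.disconnect(r_node, z)
            Arg.disconnect(r_node, 1 - z)
        elif kind_u == "bubble":
            Arg.disconnect(c_node, 0)
            Arg.disconnect(r_node, z)
            Arg.disconnect(r_node, 1 - z)
        else:
            x, jx, y = payload
            Arg.disconnect(r_node, z)
            Arg.disconnect(x, jx)
            Arg.disconnect(c_node, 0)
            Arg.connect(x, jx, y)
            Arg.disconnect(r_node, 1 - z)
        Arg.disconnect(c, slot)
        arg.remove_node(r_node)
        arg.remove_node(c_node)
        Arg.connect(c, slot, p)

    # dirty: the new nodes plus every pre-existing node whose incoming
    # edge set changed (it loses/gains arrivals on re-routed sites)
    dirty = [r_node.id, c_node.id, p.id]
    if undo[0] == "edge":
        dirty.append(undo[1][2].id)
    return Proposal(
        "add_recombination",
        log_q_death - log_q_birth,
        dirty=list(dict.fromkeys(dirty)),
        revert=revert,
    )


def propose_remove_recombination(arg: Arg, rng, theta: float,
                                 lam_scale: float = 2.0) -> Proposal:
    pairs = _removable_pairs(arg)
    if not pairs:
        return Proposal.rejected("remove_recombination")
    d_count = len(pairs)
    r_node, s = pairs[rng.integers(d_count)]
    c_node = r_node.parents[s]
    cont = r_node.parents[1 - s]
    bubble = cont is c_node
    if bubble and not c_node.parents:
        # a root bubble cannot be produced by a single birth move
        return Proposal.rejected("remove_recombination")
    child = r_node.children[0]
    jc = child.parents.index(r_node)
    b = r_node.breakpoint
    h_r, h_n = r_node.height, c_node.height
    grandparent = c_node.parents[0] if c_node.parents else None

    # ---- apply ----
    Arg.disconnect(child, jc)
    Arg.disconnect(r_node, 0)
    Arg.disconnect(r_node, 1)
    arg.remove_node(r_node)
    if bubble:
        jg = 0
        Arg.disconnect(c_node, 0)
        arg.remove_node(c_node)
        Arg.connect(child, jc, grandparent)
        heal_parent = grandparent
        other = None
    else:
        (other, jo), = arg.incoming_edges(c_node)
        Arg.disconnect(other, jo)
        if grandparent is not None:
            Arg.disconnect(c_node, 0)
            Arg.connect(other, jo, grandparent)
        arg.remove_node(c_node)
        Arg.connect(child, jc, cont)
        heal_parent = cont

    # ---- reverse birth density, evaluated on the healed state ----
    n_edges = len(arg.edges())
    mat = arg.edge_material(child, jc)
    g = interval_span_gaps(mat)
    ok = g > 0 and mat and (mat[0].start < b <= mat[-1].end - 1)
    lam = lam_scale / theta
    if ok:
        log_q_birth = (
            -math.log(n_edges)
            - math.log(heal_parent.height - child.height)
            - math.log(g)
            - math.log(2.0)
            + math.log(lam) - lam * (h_n - h_r)
        )
        if h_n < arg.root.height:
            m = len(_crossing_edges(arg, h_n))
            log_q_birth -= math.log(m)
        log_hr = log_q_birth + math.log(d_count)
    else:
        log_hr = NEG_INF

    def revert():
        r_new = ArgNode(r_node.id, h_r, RECOMBINATION, b)
        c_new = ArgNode(c_node.id, h_n, COALESCENT)
        arg.nodes[r_new.id] = r_new
        arg.nodes[c_new.id] = c_new
        Arg.disconnect(child, jc)
        if bubble:
            Arg.connect(child, jc, r_new)
            Arg.connect(r_new, 0, c_new)
            Arg.connect(r_new, 1, c_new)
            Arg.connect(c_new, 0, grandparent)
        else:
            if grandparent is not None:
                Arg.disconnect(other, jo)
            Arg.connect(child, jc, r_new)
            Arg.connect(r_new, 1 - s, cont)
            Arg.connect(r_new, s, c_new)
            Arg.connect(other, jo, c_new)
            if grandparent is not None:
                Arg.connect(c_new, 0, grandparent)

    dirty = [heal_parent.id] if heal_parent is not None else []
    if not bubble and grandparent is not None:
        dirty.append(grandparent.id)
    dirty = list(dict.fromkeys(d for d in dirty if d in arg.nodes))
    return Proposal(
        "remove_recombination",
        log_hr,
        dirty=dirty,
        removed=[r_node.id, c_node.id],
        revert=revert,
    )


# ---------------------------------------------------------------------------
# breakpoint move
# ---------------------------------------------------------------------------

def propose_breakpoint_shift(arg: Arg, rng, window: int = 50) -> Proposal:
    """Shift one recombination's breakpoint by a uniform step in
    [-window, window] \\ {0}; proposals leaving [1, L-1] auto-reject
    (symmetric otherwise)."""
    recs = arg.recombination_nodes()
    if not recs:
        return Proposal.rejected("breakpoint_shift")
    node = recs[rng.integers(len(recs))]
    window = max(1, int(window))
    step = 0
    while step == 0:
        step = int(rng.integers(-window, window + 1))
    old = node.breakpoint
    new = old + step
    if not (1 <= new <= arg.L - 1):
        return Proposal.rejected("breakpoint_shift")
    node.breakpoint = new

    def revert():
        node.breakpoint = old

    # both parents' arrival sets change over the shifted site range
    dirty = list(dict.fromkeys(
        [node.id, node.parents[0].id, node.parents[1].id]
    ))
    return Proposal("breakpoint_shift", 0.0, dirty=dirty, revert=revert)


# ---------------------------------------------------------------------------
# scalar parameters
# ---------------------------------------------------------------------------

def propose_scalar(params: dict, name: str, rng, lam: float = 0.5) -> Proposal:
    """Multiplier move on one positive scalar parameter."""
    old = params[name]
    m, logm = _multiplier(rng, lam)
    new = old * m
    params[name] = new

    def revert():
        params[name] = old

    return Proposal(
        f"scale_{name}", logm, param=(name, old, new), revert=revert,
        params_dirty=name not in ("theta", "rho"),
    )


#: ARG-state kernels in their default mixture (name -> callable, needs_theta)
ARG_KERNELS = {
    "node_height": (propose_node_height, False),
    "root_scale": (propose_root_scale, False),
    "subtree_regraft": (propose_subtree_regraft, False),
    "add_recombination": (propose_add_recombination, True),
    "remove_recombination": (propose_remove_recombination, True),
    "breakpoint_shift": (propose_breakpoint_shift, False),
    "arg_scale": (propose_arg_scale, False),
}
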