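"""The ARG data model.

An ancestral recombination graph (ARG) is a rooted directed graph of
timed nodes: sampled sequences are *tips* at height 0, *coalescent*
nodes merge two lineages, and *recombination* nodes split one lineage
into two parental lineages at an inter-site breakpoint.  Site
coordinates are 0-based and intervals half-open; a breakpoint ``b``
means sites ``< b`` follow parent 0 (the "left" parent) and sites
``>= b`` follow parent 1.  Node heights are measured in expected
substitutions per site.

This module owns construction, validation, ancestral-material
annotation, marginal-tree extraction, breakpoint enumeration and
classification, and serialization (JSON / GraphML for the graph,
Newick for marginal trees).
"""

from __future__ import annotations

import json
from typing import Iterable, NamedTuple, Optional

__all__ = [
    "SiteInterval",
    "ArgNode",
    "Arg",
    "MarginalTree",
    "TreeNode",
    "validate",
    "annotate_ancestral_material",
    "extract_marginal_tree",
    "marginal_trees",
    "enumerate_breakpoints",
    "tmrca_profile_of_arg",
    "BreakpointRecord",
    "merge_intervals",
    "intersect_intervals",
    "union_intervals",
    "interval_span_gaps",
]

TIP = "tip"
COALESCENT = "coalescent"
RECOMBINATION = "recombination"


class SiteInterval(NamedTuple):
    """Half-open run of sites ``[start, end)``."""

    start: int
    end: int


# ---------------------------------------------------------------------------
# interval arithmetic (material sets are sorted, maximally merged tuples)
# ---------------------------------------------------------------------------

def merge_intervals(ivals: Iterable[tuple[int, int]]) -> tuple[SiteInterval, ...]:
    """Sort and maximally merge (overlapping or adjacent runs collapse)."""
    ivs = sorted((s, e) for s, e in ivals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple(SiteInterval(s, e) for s, e in out)


def intersect_intervals(
    ivals: tuple[SiteInterval, ...], lo: int, hi: int
) -> tuple[SiteInterval, ...]:
    out = []
    for s, e in ivals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append(SiteInterval(s2, e2))
    return tuple(out)


def union_intervals(
    a: tuple[SiteInterval, ...], b: tuple[SiteInterval, ...]
) -> tuple[SiteInterval, ...]:
    if not a:
        return b
    if not b:
        return a
    # both inputs sorted and maximally merged: linear merge-walk
    out: list[list[int]] = []
    i = j = 0
    na, nb = len(a), len(b)
    while i < na or j < nb:
        if j >= nb or (i < na and a[i][0] <= b[j][0]):
            s, e = a[i]
            i += 1
        else:
            s, e = b[j]
            j += 1
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1][1] = e
        else:
            out.append([s, e])
    return tuple(SiteInterval(s, e) for s, e in out)


def interval_span_gaps(ivals: tuple[SiteInterval, ...]) -> int:
    """Number of eligible recombination gaps: gaps strictly inside the
    [leftmost, rightmost] ancestral site (Hudson-style).  Breakpoint b is
    eligible iff first_site < b <= last_site, so the count is
    last_site - first_site (0 for empty or single-site material)."""
    if not ivals:
        return 0
    first = ivals[0][0]
    last = ivals[-1][1] - 1
    return last - first


class ArgNode:
    """A timed ARG node.

    ``parents`` holds 0 (grand MRCA), 1 (tip/coalescent) or 2
    (recombination) references; for a recombination node ``parents[0]``
    receives sites ``< breakpoint`` and ``parents[1]`` sites
    ``>= breakpoint``.  ``ancestral_material`` is the union of sampled
    sites routed into this node from below (set by
    :func:`annotate_ancestral_material`).
    """

    __slots__ = (
        "id",
        "height",
        "kind",
        "children",
        "parents",
        "breakpoint",
        "ancestral_material",
    )

    def __init__(
        self,
        id: int,
        height: float,
        kind: str,
        breakpoint: Optional[int] = None,
    ):
        self.id = id
        self.height = height
        self.kind = kind
        self.children: list[ArgNode] = []
        self.parents: list[ArgNode] = []
        self.breakpoint = breakpoint
        self.ancestral_material: Optional[tuple[SiteInterval, ...]] = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ArgNode({self.id}, {self.kind}, h={self.height:.5g})"

    @property
    def is_root(self) -> bool:
        return not self.parents

    def routed_parent(self, site: int) -> Optional["ArgNode"]:
        """Parent this node's lineage follows for ``site`` (None at root)."""
        if not self.parents:
            return None
        if self.kind == RECOMBINATION:
            return self.parents[0] if site < self.breakpoint else self.parents[1]
        return self.parents[0]


class Arg:
    """A rooted ARG over ``n_tips`` sequences of ``L`` sites."""

    def __init__(self, L: int, tip_labels: Optional[dict[int, str]] = None):
        self.L = L
        self.nodes: dict[int, ArgNode] = {}
        self.tip_labels: dict[int, str] = dict(tip_labels or {})
        self._next_id = 0

    # -- construction -------------------------------------------------
    def new_node(self, height: float, kind: str, breakpoint: Optional[int] = None) -> ArgNode:
        node = ArgNode(self._next_id, height, kind, breakpoint)
        self.nodes[node.id] = node
        self._next_id += 1
        return node

    def add_tip(self, label: str) -> ArgNode:
        node = self.new_node(0.0, TIP)
        self.tip_labels[node.id] = label
        return node

    def remove_node(self, node: ArgNode) -> None:
        del self.nodes[node.id]

    @staticmethod
    def connect(child: ArgNode, slot: int, parent: ArgNode) -> None:
        """Attach ``child``'s parent slot ``slot`` to ``parent``."""
        while len(child.parents) <= slot:
            child.parents.append(None)  # type: ignore[arg-type]
        if child.parents[slot] is not None:
            raise ValueError("slot occupied; disconnect first")
        child.parents[slot] = parent
        parent.children.append(child)

    @staticmethod
    def disconnect(child: ArgNode, slot: int) -> ArgNode:
        parent = child.parents[slot]
        child.parents[slot] = None  # type: ignore[assignment]
        parent.children.remove(child)
        while child.parents and child.parents[-1] is None:
            child.parents.pop()
        return parent

    # -- inspection ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == TIP)

    def tips(self) -> list[ArgNode]:
        return sorted(
            (n for n in self.nodes.values() if n.kind == TIP), key=lambda n: n.id
        )

    @property
    def root(self) -> ArgNode:
        roots = [n for n in self.nodes.values() if not n.parents]
        if len(roots) != 1:
            raise ValueError(f"ARG has {len(roots)} parentless nodes, expected 1")
        return roots[0]

    def nodes_ascending(self) -> list[ArgNode]:
        """All nodes sorted by (height, id); the id tie-break makes
        traversal order deterministic for exactly tied heights."""
        return sorted(self.nodes.values(), key=lambda n: (n.height, n.id))

    def recombination_nodes(self) -> list[ArgNode]:
        return [n for n in self.nodes_ascending() if n.kind == RECOMBINATION]

    def breakpoints(self) -> list[int]:
        return sorted({n.breakpoint for n in self.nodes.values() if n.kind == RECOMBINATION})

    def incoming_edges(self, node: ArgNode) -> list[tuple[ArgNode, int]]:
        """Edges arriving at ``node`` from below as (child, parent_slot)."""
        out = []
        seen = set()
        for c in node.children:
            if c.id in seen:
                continue
            seen.add(c.id)
            for j, p in enumerate(c.parents):
                if p is node:
                    out.append((c, j))
        return out

    def edges(self) -> list[tuple[ArgNode, int, ArgNode]]:
        """All edges as (child, slot, parent), deterministic order."""
        out = []
        for c in self.nodes_ascending():
            for j, p in enumerate(c.parents):
                if p is not None:
                    out.append((c, j, p))
        return out

    def edge_material(self, child: ArgNode, slot: int) -> tuple[SiteInterval, ...]:
        """Ancestral material carried on the edge from ``child`` up
        through parent slot ``slot`` (requires annotation)."""
        m = child.ancestral_material
        if m is None:
            raise ValueError("ARG is not annotated; call annotate_ancestral_material")
        if child.kind == RECOMBINATION:
            b = child.breakpoint
            return intersect_intervals(m, 0, b) if slot == 0 else intersect_intervals(m, b, self.L)
        return m

    # -- serialization ------------------------------------------------
    def to_json_dict(self) -> dict:
        nodes = []
        for n in self.nodes_ascending():
            nodes.append(
                {
                    "id": n.id,
                    "height": n.height,
                    "kind": n.kind,
                    "parents": [p.id for p in n.parents],
                    **({"breakpoint": n.breakpoint} if n.kind == RECOMBINATION else {}),
                }
            )
        return {
            "L": self.L,
            "n_tips": self.n_tips,
            "tip_labels": {str(k): v for k, v in self.tip_labels.items()},
            "nodes": nodes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    @classmethod
    def from_json_dict(cls, d: dict) -> "Arg":
        arg = cls(int(d["L"]))
        raw = d["nodes"]
        for nd in raw:
            node = ArgNode(int(nd["id"]), float(nd["height"]), nd["kind"], nd.get("breakpoint"))
            arg.nodes[node.id] = node
        for nd in raw:
            child = arg.nodes[int(nd["id"])]
            for j, pid in enumerate(nd["parents"]):
                cls.connect(child, j, arg.nodes[int(pid)])
        arg.tip_labels = {int(k): v for k, v in d.get("tip_labels", {}).items()}
        arg._next_id = 1 + max(arg.nodes) if arg.nodes else 0
        return arg

    @classmethod
    def from_json(cls, s: str) -> "Arg":
        return cls.from_json_dict(json.loads(s))

    def to_graphml(self) -> str:
        import io as _io

        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes_ascending():
            attrs = {"height": n.height, "kind": n.kind}
            if n.kind == TIP:
                attrs["label"] = self.tip_labels.get(n.id, str(n.id))
            if n.kind == RECOMBINATION:
                attrs["breakpoint"] = n.breakpoint
            g.add_node(n.id, **attrs)
        for c, j, p in self.edges():
            g.add_edge(c.id, p.id, slot=j)
        buf = _io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()

    def copy(self) -> "Arg":
        return Arg.from_json_dict(self.to_json_dict())


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(arg: Arg) -> list[str]:
    """Return human-readable descriptions of every invariant violation
    (empty list iff the ARG is valid).  Diagnostics, never exceptions."""
    v: list[str] = []
    roots = 0
    for n in arg.nodes.values():
        nc, np_ = len(n.children), len(n.parents)
        if n.kind == TIP:
            if nc != 0:
                v.append(f"node {n.id}: tip has {nc} children, expected 0")
            if np_ > 1:
                v.append(f"node {n.id}: tip has {np_} parents, expected <=1")
            if n.height != 0.0:
                v.append(f"node {n.id}: tip height {n.height} != 0")
        elif n.kind == COALESCENT:
            if nc != 2:
                v.append(f"node {n.id}: coalescent has {nc} children, expected 2")
            if np_ > 1:
                v.append(f"node {n.id}: coalescent has {np_} parents, expected <=1")
        elif n.kind == RECOMBINATION:
            if nc != 1:
                v.append(f"node {n.id}: recombination has {nc} children, expected 1")
            if np_ != 2:
                v.append(f"node {n.id}: recombination has {np_} parents, expected 2")
            if n.breakpoint is None or not (1 <= n.breakpoint <= arg.L - 1):
                v.append(
                    f"node {n.id}: breakpoint {n.breakpoint} outside [1, {arg.L - 1}]"
                )
        else:
            v.append(f"node {n.id}: unknown kind {n.kind!r}")
        if n.height < 0:
            v.append(f"node {n.id}: negative height {n.height}")
        for p in n.parents:
            if p is not None and not (p.height > n.height):
                v.append(
                    f"node {n.id}: parent {p.id} height {p.height} not above {n.height}"
                )
        if not n.parents:
            roots += 1
        for c in n.children:
            if c.parents.count(n) < 1:
                v.append(f"node {n.id}: child {c.id} does not list it as parent")
    if roots != 1:
        v.append(f"ARG has {roots} parentless nodes (grand MRCA), expected exactly 1")
    else:
        # connectivity: everything must reach the single root
        reach = set()
        stack = [arg.root]
        while stack:
            n = stack.pop()
            if n.id in reach:
                continue
            reach.add(n.id)
            stack.extend(n.children)
        missing = set(arg.nodes) - reach
        if missing:
            v.append(f"nodes not connected to root: {sorted(missing)}")
    return v


# ---------------------------------------------------------------------------
# ancestral material
# ---------------------------------------------------------------------------

def annotate_ancestral_material(arg: Arg, seeds: Optional[Iterable[int]] = None) -> Arg:
    """Set ``ancestral_material`` on every node: the union over
    descendant tips of sites routed into the node.  Tips carry
    ``[0, L)``; at a recombination node material splits at the
    breakpoint on the two parent edges; at a coalescent node the
    incoming edges' material unions.  Idempotent (pure function of
    structure).

    With ``seeds`` only the given nodes and their root-ward closure are
    refreshed (material of a node depends only on its descendants, so
    this is exact when everything outside the closure is current)."""
    if seeds is None:
        nodes = arg.nodes_ascending()
    else:
        closure: set[int] = set()
        stack = [arg.nodes[i] for i in seeds if i in arg.nodes]
        while stack:
            n = stack.pop()
            if n.id in closure:
                continue
            closure.add(n.id)
            for p in n.parents:
                if p is not None:
                    stack.append(p)
        nodes = sorted((arg.nodes[i] for i in closure),
                       key=lambda n: (n.height, n.id))
    for n in nodes:
        if n.kind == TIP:
            n.ancestral_material = (SiteInterval(0, arg.L),)
        else:
            m: tuple[SiteInterval, ...] = ()
            for c, j in arg.incoming_edges(n):
                m = union_intervals(m, arg.edge_material(c, j))
            n.ancestral_material = m
    return arg


# ---------------------------------------------------------------------------
# marginal trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a marginal tree: leaf (label, height 0) or internal
    (two children, height = coalescence time)."""

    __slots__ = ("height", "label", "children", "_canon")

    def __init__(self, height: float, label: Optional[str] = None,
                 children: Optional[list["TreeNode"]] = None):
        self.height = height
        self.label = label
        self.children = children or []
        self._canon = None

    def canonical(self):
        """Hashable canonical form including heights; used for exact
        tree identity (topology + node times)."""
        if self._canon is None:
            if not self.children:
                self._canon = (self.height, self.label)
            else:
                self._canon = (
                    self.height,
                    tuple(sorted(c.canonical() for c in self.children)),
                )
        return self._canon


class MarginalTree:
    """The rooted binary timed tree ancestral to one site (or to a run
    of sites sharing it); ultrametric with all tips at height 0."""

    def __init__(self, root: TreeNode, site: Optional[int] = None):
        self.root = root
        self.site = site

    @property
    def tmrca(self) -> float:
        return self.root.height

    def n_leaves(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.children:
                count += 1
            stack.extend(n.children)
        return count

    def leaf_labels(self) -> set[str]:
        labels = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.children:
                labels.add(n.label)
            stack.extend(n.children)
        return labels

    def canonical(self):
        return self.root.canonical()

    def __eq__(self, other) -> bool:
        return isinstance(other, MarginalTree) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def newick(self, precision: int = 10) -> str:
        """Deterministic Newick with branch lengths in subs/site;
        children ordered canonically."""

        def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.children:
                kids = sorted(node.children, key=lambda c: c.canonical())
                inner = ",".join(fmt(c, node.height) for c in kids)
                core = f"({inner})"
            else:
                core = node.label or ""
            if parent_height is None:
                return core
            return f"{core}:{parent_height - node.height:.{precision}g}"

        return fmt(self.root, None) + ";"


def extract_marginal_tree(arg: Arg, site: int) -> MarginalTree:
    """Route every tip root-ward for ``site`` — at recombination nodes
    choosing parent 0 when ``site < breakpoint`` else parent 1 — and
    suppress unary pass-through nodes.  The returned tree's root height
    is the marginal TMRCA at ``site``."""
    if not (0 <= site < arg.L):
        raise ValueError(f"site {site} out of range [0, {arg.L})")
    # active: ARG node id -> subtree for the lineage leaving that node
    active: dict[int, TreeNode] = {}
    for t in arg.tips():
        active[t.id] = TreeNode(0.0, label=arg.tip_labels.get(t.id, str(t.id)))
    for u in arg.nodes_ascending():
        if u.kind == TIP:
            continue
        arrivals = [
            vid for vid in active if arg.nodes[vid].routed_parent(site) is u
        ]
        if not arrivals:
            continue
        if u.kind == COALESCENT and len(arrivals) == 2:
            a, b = sorted(arrivals)
            node = TreeNode(u.height, children=[active[a], active[b]])
            del active[a], active[b]
            active[u.id] = node
        else:
            # pass-through (unary): lineage continues, no tree node
            (vid,) = arrivals
            active[u.id] = active.pop(vid)
        if len(active) == 1:
            break
    if len(active) != 1:
        raise ValueError("tips did not fully coalesce; invalid ARG")
    (root,) = active.values()
    return MarginalTree(root, site=site)


def marginal_trees(arg: Arg) -> list[tuple[SiteInterval, MarginalTree]]:
    """Decompose the ARG into runs of sites sharing one marginal tree.

    The returned intervals partition ``[0, L)``; adjacent intervals with
    identical trees (topology and heights) are merged, so breakpoints of
    trivial or non-ancestral recombinations do not create intervals."""
    cuts = sorted({b for b in arg.breakpoints() if 0 < b < arg.L})
    bounds = [0] + cuts + [arg.L]
    out: list[tuple[SiteInterval, MarginalTree]] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        tree = extract_marginal_tree(arg, lo)
        tree.site = None
        if out and out[-1][1] == tree:
            prev_iv, prev_tree = out.pop()
            out.append((SiteInterval(prev_iv.start, hi), prev_tree))
        else:
            out.append((SiteInterval(lo, hi), tree))
    return out


def tmrca_profile_of_arg(arg: Arg) -> list[tuple[SiteInterval, float]]:
    """Marginal TMRCA as a step function over [0, L)."""
    out = []
    for iv, tree in marginal_trees(arg):
        if out and out[-1][1] == tree.tmrca:
            piv = out.pop()
            out.append((SiteInterval(piv[0].start, iv.end), tree.tmrca))
        else:
            out.append((iv, tree.tmrca))
    return out


# ---------------------------------------------------------------------------
# breakpoint enumeration
# ---------------------------------------------------------------------------

class BreakpointRecord(NamedTuple):
    site: int
    height: float
    detectability: str  # "detectable" | "trivial" | "non_ancestral"
    node_id: int


def enumerate_breakpoints(arg: Arg) -> list[BreakpointRecord]:
    """One record per recombination node, classified by detectability.

    ``non_ancestral``: the breakpoint falls outside the edge's ancestral
    material span, so one parental lineage carries no sampled sites and
    no data are affected.  ``trivial``: the two recombination-created
    lineages coalesce with each other before meeting any other lineage
    (both parents are one coalescent node), leaving every marginal tree
    unchanged.  Everything else is ``detectable``."""
    out = []
    for n in arg.recombination_nodes():
        m = n.ancestral_material
        if m is None:
            raise ValueError("ARG is not annotated; call annotate_ancestral_material")
        b = n.breakpoint
        if not m or not (m[0].start < b <= m[-1].end - 1):
            cls = "non_ancestral"
        elif n.parents[0] is n.parents[1]:
            cls = "trivial"
        else:
            cls = "detectable"
        out.append(BreakpointRecord(b, n.height, cls, n.id))
    return out
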